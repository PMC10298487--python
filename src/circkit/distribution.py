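"""Genome-distribution summaries: per-chromosome gene/circRNA counts,
per-gene circRNA multiplicity and host-structure-vs-abundance correlations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, length_exon_ratio
from .catalog import GeneIndex
from .errors import InsufficientDataError
from .expression import spearman_test


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def per_chromosome_counts(
    genes: Iterable[GeneModel],
    catalog: Sequence,
    biotype_filter: str | None = "protein_coding",
) -> pd.DataFrame:
    """Rows of (chromosome, n_genes, n_circ).

    n_genes counts genes passing the biotype filter; n_circ counts all
    catalog records by their own chromosome.  Chromosomes with zero in
    both are omitted.
    """
    gene_counts: Counter = Counter()
    for g in genes:
        if biotype_filter is None or g.biotype == biotype_filter:
            gene_counts[g.chromosome] += 1
    circ_counts: Counter = Counter(r.chrom for r in catalog)
    chroms = sorted(set(gene_counts) | set(circ_counts))
    return pd.DataFrame(
        {
            "chromosome": chroms,
            "n_genes": [gene_counts.get(c, 0) for c in chroms],
            "n_circ": [circ_counts.get(c, 0) for c in chroms],
        }
    )


def chromosome_correlation(table: pd.DataFrame) -> CorrelationResult:
    """Spearman correlation between per-chromosome gene and circRNA counts."""
    if len(table) < 4:
        raise InsufficientDataError(
            f"need >= 4 chromosomes, found {len(table)}"
        )
    rho, p, method = spearman_test(
        table["n_genes"].to_numpy(float), table["n_circ"].to_numpy(float)
    )
    return CorrelationResult(rho=rho, p_value=p, n=len(table), method=method)


def multiplicity_table(catalog: Sequence) -> tuple[pd.DataFrame, list[str]]:
    """Distribution of circRNAs-per-host-gene over hosted records.

    Returns the (k, n_genes) table plus the gene ids at the maximum k.
    """
    per_gene: Counter = Counter(
        r.host_gene_id for r in catalog if r.host_gene_id is not None
    )
    if not per_gene:
        return pd.DataFrame(columns=["k", "n_genes"]).astype(int), []
    dist = Counter(per_gene.values())
    ks = sorted(dist)
    table = pd.DataFrame({"k": ks, "n_genes": [dist[k] for k in ks]})
    kmax = ks[-1]
    max_genes = sorted(g for g, k in per_gene.items() if k == kmax)
    return table, max_genes


def structure_abundance_correlation(
    catalog: Sequence, genes: Iterable[GeneModel] | GeneIndex
) -> dict[str, CorrelationResult]:
    """Spearman tests of circRNA read count against the host gene's exon
    count and genomic length, over hosted records."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    counts, exon_counts, lengths = [], [], []
    for r in catalog:
        if r.host_gene_id is None:
            continue
        g = index.by_id[r.host_gene_id]
        counts.append(r.read_count)
        exon_counts.append(g.exon_count)
        lengths.append(g.genomic_length)
    if len(counts) < 4:
        raise InsufficientDataError(
            f"need >= 4 hosted records, found {len(counts)}"
        )
    out = {}
    for name, values in (("exon_count", exon_counts), ("genomic_length", lengths)):
        rho, p, method = spearman_test(np.asarray(values, float), np.asarray(counts, float))
        out[name] = CorrelationResult(rho=rho, p_value=p, n=len(counts), method=method)
    return out


def spliced_length_histogram(catalog: Sequence, bin_width: int = 500) -> pd.DataFrame:
    """Histogram of spliced lengths (figure-ready TSV data)."""
    lengths = [r.spliced_length for r in catalog if r.spliced_length is not None]
    if not lengths:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"]).astype(int)
    top = (max(lengths) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    hist, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": hist}
    )
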