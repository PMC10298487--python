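"""Length/exon ratio index: classify host genes by genomic-length/exon-count
ratio against the genome-wide average and test overrepresentation of
upregulated circRNAs in the low-ratio class; plus microRNA target-site
overlap counts and recurrent responder detection across conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GeneModel, length_exon_ratio
from .catalog import GeneIndex
from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    ParseError,
    ValidationError,
)

_DE_COLUMN_ALIASES = {
    "circ_id": {"circ_id", "id", "circrna_id"},
    "log2fc": {"log2fc", "log2foldchange", "lfc"},
    "pvalue": {"pvalue", "p_value", "pval"},
    "padj": {"padj", "p_adj", "fdr", "qvalue"},
}


@dataclass
class DETable:
    """Per-circRNA differential-expression results for one condition."""

    condition: str
    frame: pd.DataFrame  # columns: circ_id, log2fc, pvalue, padj

    def __post_init__(self) -> None:
        ids = self.frame["circ_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate circ_id {dup!r} in DE table {self.condition!r}"
            )

    def __len__(self) -> int:
        return len(self.frame)


def load_de_table(path, condition: str) -> DETable:
    """Load a DE result TSV (deseq2-results-compatible headers accepted:
    circ_id, log2FoldChange, pvalue, padj in any case)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty and df.columns.size == 0:
        df = pd.DataFrame(columns=["circ_id", "log2fc", "pvalue", "padj"])
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        for canon, aliases in _DE_COLUMN_ALIASES.items():
            if key in aliases:
                rename[col] = canon
    df = df.rename(columns=rename)
    missing = {"circ_id", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise ParseError(
            f"DE table missing columns {sorted(missing)}", path=path
        )
    if "pvalue" not in df.columns:
        df["pvalue"] = np.nan
    df = df[["circ_id", "log2fc", "pvalue", "padj"]].copy()
    df["circ_id"] = df["circ_id"].astype(str)
    for col in ("log2fc", "pvalue", "padj"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return DETable(condition=condition, frame=df)


def flag_upregulated(
    de: DETable, alpha: float = 0.05, lfc_min: float = 0.0
) -> set[str]:
    """circ_ids with padj < alpha and log2fc > lfc_min (NaN padj excluded)."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    f = de.frame
    mask = (f["padj"] < alpha) & (f["log2fc"] > lfc_min) & f["padj"].notna()
    return set(f.loc[mask, "circ_id"])


def flag_significant(de: DETable, alpha: float = 0.05) -> set[str]:
    """circ_ids with padj < alpha in either direction."""
    f = de.frame
    mask = (f["padj"] < alpha) & f["padj"].notna()
    return set(f.loc[mask, "circ_id"])


def genomewide_average_ratio(
    genes: Iterable[GeneModel] | GeneIndex,
    catalog: Sequence | None = None,
    scope: str = "host_genes",
) -> float:
    """Arithmetic mean length/exon ratio over the scoped genes.

    ``host_genes`` (default) averages over the unique host genes of the
    catalog; ``all_genes`` over the full annotation.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if scope == "host_genes":
        if catalog is None:
            raise ValidationError("host_genes scope requires a catalog")
        ids = sorted({r.host_gene_id for r in catalog if r.host_gene_id})
        pool = [index.by_id[g] for g in ids if g in index.by_id]
    elif scope == "all_genes":
        pool = list(index.by_id.values())
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    if not pool:
        raise InsufficientDataError("no genes in scope for the average ratio")
    return float(np.mean([length_exon_ratio(g) for g in pool]))


def chi_squared_2x2(
    table, continuity: bool = False
) -> tuple[float, float, int]:
    """Pearson chi-squared test on a 2×2 table; optional Yates correction.

    Returns (statistic, two-sided p from the χ²(1) survival function, df=1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValidationError("cell counts must be >= 0")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        which = []
        for i in range(2):
            if rows[i] == 0:
                which.append(f"row {i}")
            if cols[i] == 0:
                which.append(f"column {i}")
        raise DegenerateTableError("zero margin: " + ", ".join(which))
    expected = np.outer(rows, cols) / total
    diff = np.abs(obs - expected)
    if continuity:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(stat, 1))
    return stat, p, 1


@dataclass
class EnrichmentResult:
    condition: str
    avg_ratio_overexpressed: float
    avg_ratio_stable: float
    contingency: list[list[int]]  # rows: ratio low/high, cols: up/stable
    chi2_stat: float
    p_value: float
    genomewide_avg: float
    n_assessable: int
    df: int = 1
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def ratio_enrichment(
    catalog: Sequence,
    genes: Iterable[GeneModel] | GeneIndex,
    de: DETable,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
    continuity: bool = False,
    scope: str = "host_genes",
    n_permutations: int = 0,
    seed: int | None = None,
) -> EnrichmentResult:
    """Cross-classify assessable circRNAs by (host ratio below the
    genome-wide average) × (upregulated) and test the association.

    The assessable set is every catalog record with a host gene and a row
    in the DE table.  ``n_permutations > 0`` adds a seeded label-permutation
    p-value for the same statistic.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    avg = genomewide_average_ratio(index, catalog=catalog, scope=scope)
    up = flag_upregulated(de, alpha=alpha, lfc_min=lfc_min)
    de_ids = set(de.frame["circ_id"])

    low_flags, up_flags, ratios = [], [], []
    for r in catalog:
        if r.host_gene_id is None or r.circ_id not in de_ids:
            continue
        ratio = length_exon_ratio(index.by_id[r.host_gene_id])
        ratios.append(ratio)
        low_flags.append(ratio < avg)
        up_flags.append(r.circ_id in up)
    if not ratios:
        raise InsufficientDataError("no assessable circRNAs (host + DE row)")

    low = np.asarray(low_flags)
    upf = np.asarray(up_flags)
    ratios = np.asarray(ratios)
    cont = np.array(
        [
            [int((low & upf).sum()), int((low & ~upf).sum())],
            [int((~low & upf).sum()), int((~low & ~upf).sum())],
        ]
    )
    if cont[:, 0].sum() == 0:
        raise DegenerateTableError("zero margin: no upregulated circRNAs")
    if cont[:, 1].sum() == 0:
        raise DegenerateTableError("zero margin: no stable circRNAs")
    stat, p, df = chi_squared_2x2(cont, continuity=continuity)

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        labels = upf.copy()
        for _ in range(n_permutations):
            rng.shuffle(labels)
            c = np.array(
                [
                    [int((low & labels).sum()), int((low & ~labels).sum())],
                    [int((~low & labels).sum()), int((~low & ~labels).sum())],
                ]
            )
            s, _, _ = chi_squared_2x2(c, continuity=continuity)
            if s >= stat - 1e-12:
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)

    return EnrichmentResult(
        condition=de.condition,
        avg_ratio_overexpressed=float(ratios[upf].mean()),
        avg_ratio_stable=float(ratios[~upf].mean()),
        contingency=cont.tolist(),
        chi2_stat=stat,
        p_value=p,
        genomewide_avg=avg,
        n_assessable=int(len(ratios)),
        df=df,
        permutation_p=perm_p,
    )


def target_site_overlap(
    de_gene_set: Iterable[str], mir_targets: Iterable[str]
) -> tuple[int, int]:
    """(size of the DE gene set, size of its overlap with the target list)."""
    de_set = set(de_gene_set)
    return len(de_set), len(de_set & set(mir_targets))


def load_gene_list(path) -> list[str]:
    """Plain-text gene list, one id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def recurrent_responders(
    de_tables: Sequence[DETable],
    catalog: Sequence,
    alpha: float = 0.05,
) -> set[str]:
    """Host genes whose circRNAs are significantly altered (either
    direction) in every condition."""
    if len(de_tables) < 2:
        raise ValidationError("need >= 2 conditions")
    host_by_circ = {
        r.circ_id: r.host_gene_id for r in catalog if r.host_gene_id is not None
    }
    per_condition = []
    for de in de_tables:
        sig = flag_significant(de, alpha=alpha)
        per_condition.append(
            {host_by_circ[c] for c in sig if c in host_by_circ}
        )
    return set.intersection(*per_condition)
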