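"""Gene-annotation handling: GTF parsing, union-exon gene models, and the
genomic-length / exon-count ratio.

A :class:`GeneModel` is a transcript-agnostic view of a gene: its span on
the chromosome plus the union of all exon intervals across every annotated
transcript.  All coordinates are 1-based inclusive (GTF convention); BED
inputs elsewhere in the package are converted on load.
"""

from __future__ import annotations

import gzip
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

Interval = tuple[int, int]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge 1-based inclusive intervals into a sorted disjoint union.

    Bookended intervals (``end + 1 == next start``) are merged, so the
    result is also non-adjacent.

    Raises
    ------
    ValidationError
        If any interval has ``start > end``.
    """
    ivs = []
    for s, e in intervals:
        if s > e:
            raise ValidationError(f"interval start {s} > end {e}")
        ivs.append((int(s), int(e)))
    ivs.sort()
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            ps, pe = merged[-1]
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """One gene with union exon structure.

    ``exons`` must be sorted, pairwise disjoint and non-adjacent; they are
    merged and validated on construction.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    gene_name: str = ""
    biotype: str = "unknown"
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if not self.exons:
            self.exons = [(self.start, self.end)]
        else:
            self.exons = merge_intervals(self.exons)
        if self.exons[0][0] < self.start or self.exons[-1][1] > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: exon outside gene span"
            )
        if not self.gene_name:
            self.gene_name = self.gene_id

    @property
    def genomic_length(self) -> int:
        return self.end - self.start + 1

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


def length_exon_ratio(gene: GeneModel) -> float:
    """Genomic length divided by union exon count (nucleotides per exon)."""
    return gene.genomic_length / gene.exon_count


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_gtf(path) -> list[GeneModel]:
    """Parse a GTF file into one :class:`GeneModel` per distinct gene_id.

    Exons of all transcripts of a gene are merged into union intervals.
    Genes that appear only as a ``gene`` feature (no exon lines) get a
    single exon covering the gene span.  Records on unplaced contigs are
    retained with their literal chromosome string.  Genes lacking a
    ``gene_biotype``/``gene_type`` attribute get biotype ``"unknown"``.
    """
    spans: dict[str, dict] = {}
    exons: dict[str, list[Interval]] = defaultdict(list)

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, found {len(fields)}",
                    path=path, line=lineno,
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}",
                    path=path, line=lineno,
                ) from None
            if start > end:
                raise ParseError(
                    f"start {start} > end {end}", path=path, line=lineno
                )
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id")
            if not gid:
                raise ParseError(
                    "missing gene_id attribute", path=path, line=lineno
                )
            info = spans.setdefault(
                gid,
                {"chromosome": chrom, "strand": strand, "start": None,
                 "end": None, "gene_name": "", "biotype": "",
                 "lo": start, "hi": end},
            )
            info["lo"] = min(info["lo"], start)
            info["hi"] = max(info["hi"], end)
            if feature == "gene":
                info["start"], info["end"] = start, end
                info["chromosome"], info["strand"] = chrom, strand
            if feature == "exon":
                exons[gid].append((start, end))
            name = attr.get("gene_name")
            if name and not info["gene_name"]:
                info["gene_name"] = name
            biotype = attr.get("gene_biotype") or attr.get("gene_type")
            if biotype and not info["biotype"]:
                info["biotype"] = biotype

    models = []
    for gid, info in spans.items():
        start = info["start"] if info["start"] is not None else info["lo"]
        end = info["end"] if info["end"] is not None else info["hi"]
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=info["chromosome"],
                start=start,
                end=end,
                strand=info["strand"],
                gene_name=info["gene_name"] or gid,
                biotype=info["biotype"] or "unknown",
                exons=exons.get(gid, []),
            )
        )
    models.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return models


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GTF (one gene feature + one exon line per union
    exon interval); re-parsing yields identical models."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            base = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                "\t".join([g.chromosome, "circkit", "gene", str(g.start),
                           str(g.end), ".", g.strand, ".", base]) + "\n"
            )
            for s, e in g.exons:
                attrs = base + f' transcript_id "{g.gene_id}.t1";'
                fh.write(
                    "\t".join([g.chromosome, "circkit", "exon", str(s),
                               str(e), ".", g.strand, ".", attrs]) + "\n"
                )


def gene_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Tabular export of gene models for inspection."""
    rows = [
        {
            "gene_id": g.gene_id,
            "gene_name": g.gene_name,
            "chromosome": g.chromosome,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "biotype": g.biotype,
            "genomic_length": g.genomic_length,
            "exon_count": g.exon_count,
            "ratio": length_exon_ratio(g),
        }
        for g in genes
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "gene_name", "chromosome", "start", "end",
                 "strand", "biotype", "genomic_length", "exon_count", "ratio"],
    )
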