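"""Back-splice-junction catalog: loading junction calls, host-gene
assignment, spliced length, known-database matching and catalog summaries.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneModel, length_exon_ratio
from .errors import ParseError, ValidationError

EN_DASH = "–"


def make_circ_id(chrom: str, start: int, end: int) -> str:
    """Canonical junction identifier ``chrom:start–end`` (en dash)."""
    return f"{chrom}:{start}{EN_DASH}{end}"


def parse_circ_id(circ_id: str) -> tuple[str, int, int]:
    """Inverse of :func:`make_circ_id`; accepts an ASCII hyphen too."""
    chrom, _, coords = circ_id.rpartition(":")
    sep = EN_DASH if EN_DASH in coords else "-"
    s, _, e = coords.partition(sep)
    try:
        return chrom, int(s), int(e)
    except ValueError:
        raise ValidationError(f"unparseable circ_id {circ_id!r}") from None


@dataclass
class CircRecord:
    """One back-splice junction (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    read_count: int = 0
    host_gene_id: str | None = None
    host_biotype: str | None = None
    spliced_length: int | None = None
    known_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"junction start {self.start} > end {self.end}"
            )
        if self.read_count < 0:
            raise ValidationError(f"negative read count {self.read_count}")

    @property
    def circ_id(self) -> str:
        return make_circ_id(self.chrom, self.start, self.end)

    @property
    def novel(self) -> bool:
        return not self.known_ids


@dataclass
class CatalogSummary:
    n_total: int
    n_known: int
    n_in_protein_coding: int
    n_over_read_threshold: int
    read_threshold: int
    n_more_abundant_than_linear: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# loading


def _collapse(rows: list[tuple[str, int, int, str, int]]) -> list[CircRecord]:
    agg: dict[tuple, int] = {}
    for chrom, start, end, strand, count in rows:
        if count < 0:
            raise ValidationError(f"negative read count {count}")
        if start > end:
            raise ValidationError(f"junction start {start} > end {end}")
        key = (chrom, start, end, strand)
        agg[key] = agg.get(key, 0) + count
    records = [
        CircRecord(chrom=c, start=s, end=e, strand=st, read_count=n)
        for (c, s, e, st), n in agg.items()
    ]
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return records


def _read_table(path, expect_header: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.empty:
        return df
    first = [str(v).lower() for v in df.iloc[0]]
    if first[: len(expect_header)] == list(expect_header):
        df = df.iloc[1:].reset_index(drop=True)
    return df


def load_circ_calls(path, dialect: str = "tsv") -> list[CircRecord]:
    """Load junction calls; duplicates (same chrom/start/end/strand) are
    collapsed by summing read counts and the result is coordinate-sorted.

    dialects
        ``tsv``
            columns chrom/start/end/strand/count, 1-based inclusive,
            optional header.
        ``bed``
            BED6, 0-based half-open (converted); column 5 is the count.
        ``dcc``
            paired ``CircCoordinates``/``CircRNACount`` tab files as
            emitted by the DCC caller (0-based starts, converted; sample
            count columns summed).  ``path`` may be the directory holding
            both files or the ``CircCoordinates`` file itself.
    """
    if dialect == "dcc":
        return _load_dcc(path)
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    rows = []
    if dialect == "tsv":
        df = _read_table(path, ("chrom", "start", "end", "strand", "count"))
        for i, r in df.iterrows():
            if len(r) < 5 or pd.isna(r.iloc[4]):
                raise ParseError("expected 5 columns", path=path, line=i + 1)
            rows.append(
                (str(r.iloc[0]), int(r.iloc[1]), int(r.iloc[2]),
                 str(r.iloc[3]), int(r.iloc[4]))
            )
    elif dialect == "bed":
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        for i, r in df.iterrows():
            if len(r) < 6 or pd.isna(r.iloc[5]):
                raise ParseError("expected BED6", path=path, line=i + 1)
            # BED 0-based half-open -> 1-based inclusive
            rows.append(
                (str(r.iloc[0]), int(r.iloc[1]) + 1, int(r.iloc[2]),
                 str(r.iloc[5]), int(r.iloc[4]))
            )
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    return _collapse(rows)


def _load_dcc(path) -> list[CircRecord]:
    path = Path(path)
    if path.is_dir():
        coords_path = path / "CircCoordinates"
        counts_path = path / "CircRNACount"
    else:
        coords_path = path
        counts_path = path.parent / "CircRNACount"
    for p in (coords_path, counts_path):
        if not p.exists():
            raise ParseError("missing DCC file", path=p)

    coords = _read_table(coords_path, ("chr",))
    counts = _read_table(counts_path, ("chr",))
    count_by_key: dict[tuple, int] = {}
    for i, r in counts.iterrows():
        key = (str(r.iloc[0]), int(r.iloc[1]), int(r.iloc[2]))
        total = sum(int(float(v)) for v in r.iloc[3:] if not pd.isna(v))
        count_by_key[key] = count_by_key.get(key, 0) + total
    rows = []
    for i, r in coords.iterrows():
        key = (str(r.iloc[0]), int(r.iloc[1]), int(r.iloc[2]))
        strand = str(r.iloc[5]) if len(r) > 5 and not pd.isna(r.iloc[5]) else "."
        n = count_by_key.get(key, 0)
        # DCC emits 0-based starts
        rows.append((key[0], key[1] + 1, key[2], strand, n))
    return _collapse(rows)


# ---------------------------------------------------------------------------
# known-circRNA database

KnownEntry = tuple[str, int, int, str, str]  # chrom, start, end, strand, name


def load_known_db(path) -> list[KnownEntry]:
    """Load a known-circRNA BED (0-based half-open, name column = db id)."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    entries = []
    for i, r in df.iterrows():
        if len(r) < 4 or pd.isna(r.iloc[3]):
            raise ParseError("expected >= 4 BED columns", path=path, line=i + 1)
        strand = str(r.iloc[5]) if len(r) > 5 and not pd.isna(r.iloc[5]) else "."
        entries.append(
            (str(r.iloc[0]), int(r.iloc[1]) + 1, int(r.iloc[2]), strand,
             str(r.iloc[3]))
        )
    return entries


def _strand_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def match_known(
    record: CircRecord, db: Iterable[KnownEntry], tolerance: int = 0
) -> list[str]:
    """Database ids whose junction is within ``tolerance`` nt of the record
    at both ends, same chromosome, compatible strand.  Empty ⇒ novel."""
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    hits = [
        name
        for chrom, s, e, strand, name in db
        if chrom == record.chrom
        and abs(s - record.start) <= tolerance
        and abs(e - record.end) <= tolerance
        and _strand_compatible(strand, record.strand)
    ]
    return sorted(hits)


# ---------------------------------------------------------------------------
# host-gene assignment


class GeneIndex:
    """Per-chromosome containment queries over gene spans."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self.by_id: dict[str, GeneModel] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chromosome, []).append(g)
            self.by_id[g.gene_id] = g
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
            self._starts[chrom] = [g.start for g in gs]
            self._max_len[chrom] = max(g.genomic_length for g in gs)

    def containing(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        gs = self._by_chrom.get(chrom)
        if not gs:
            return []
        starts = self._starts[chrom]
        hi = bisect.bisect_right(starts, start)
        lo = bisect.bisect_left(starts, start - self._max_len[chrom])
        return [g for g in gs[lo:hi] if g.start <= start and g.end >= end]


def _exon_overlap(gene: GeneModel, start: int, end: int) -> int:
    total = 0
    for s, e in gene.exons:
        if s > end:
            break
        total += max(0, min(e, end) - max(s, start) + 1)
    return total


def assign_host_gene(record: CircRecord, index: GeneIndex) -> str | None:
    """Pick the gene whose span fully contains the junction interval.

    Strand must match when the record strand is ``+``/``−``; ``.`` matches
    either.  Ties are broken by (1) larger reciprocal overlap of the
    gene's union exons with the circle interval, (2) smaller genomic
    length, (3) lexicographic gene_id.  ``None`` means intergenic.
    """
    candidates = [
        g
        for g in index.containing(record.chrom, record.start, record.end)
        if _strand_compatible(g.strand, record.strand)
    ]
    if not candidates:
        return None
    span = record.end - record.start + 1

    def key(g: GeneModel):
        ov = _exon_overlap(g, record.start, record.end)
        reciprocal = min(ov / span, ov / g.exonic_length)
        return (-reciprocal, g.genomic_length, g.gene_id)

    return min(candidates, key=key).gene_id


def spliced_length(record: CircRecord, host: GeneModel | None) -> int:
    """Total exonic nucleotides inside the junction interval.

    Falls back to the genomic span (``end − start + 1``) for intergenic
    records and circles that lie entirely within an intron.
    """
    span = record.end - record.start + 1
    if host is None:
        return span
    exonic = _exon_overlap(host, record.start, record.end)
    return exonic if exonic > 0 else span


def annotate_catalog(
    records: Sequence[CircRecord],
    genes: Iterable[GeneModel],
    db: Iterable[KnownEntry] | None = None,
    tolerance: int = 0,
) -> list[CircRecord]:
    """Fill host_gene_id, host_biotype, spliced_length and known_ids
    in place for every record; returns the same list."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    db = list(db) if db is not None else []
    for r in records:
        gid = assign_host_gene(r, index)
        r.host_gene_id = gid
        host = index.by_id[gid] if gid is not None else None
        r.host_biotype = host.biotype if host is not None else None
        r.spliced_length = spliced_length(r, host)
        r.known_ids = match_known(r, db, tolerance=tolerance)
    return list(records)


# ---------------------------------------------------------------------------
# summary


def summarize_catalog(
    catalog: Sequence[CircRecord],
    genes,
    linear: Mapping[str, float],
    read_threshold: int = 50,
    fold_window: float = 2.0,
) -> CatalogSummary:
    """Headline catalog counts (assumes host assignment and known matching
    have been performed)."""
    from .expression import classify_circ_vs_linear

    n_higher = 0
    for r in catalog:
        if r.host_gene_id is not None and r.host_gene_id in linear:
            cls = classify_circ_vs_linear(
                r.read_count, linear[r.host_gene_id], fold_window=fold_window
            )
            if cls == "higher":
                n_higher += 1
    return CatalogSummary(
        n_total=len(catalog),
        n_known=sum(1 for r in catalog if r.known_ids),
        n_in_protein_coding=sum(
            1 for r in catalog if r.host_biotype == "protein_coding"
        ),
        n_over_read_threshold=sum(
            1 for r in catalog if r.read_count > read_threshold
        ),
        read_threshold=read_threshold,
        n_more_abundant_than_linear=n_higher,
    )


# ---------------------------------------------------------------------------
# tabular round-trip


def catalog_table(catalog: Sequence[CircRecord]) -> pd.DataFrame:
    rows = [
        {
            "circ_id": r.circ_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "read_count": r.read_count,
            "host_gene_id": r.host_gene_id if r.host_gene_id else "",
            "host_biotype": r.host_biotype if r.host_biotype else "",
            "spliced_length": r.spliced_length,
            "known_ids": ";".join(r.known_ids),
            "novel": int(r.novel),
        }
        for r in catalog
    ]
    return pd.DataFrame(
        rows,
        columns=["circ_id", "chrom", "start", "end", "strand", "read_count",
                 "host_gene_id", "host_biotype", "spliced_length",
                 "known_ids", "novel"],
    )


def write_catalog(catalog: Sequence[CircRecord], path) -> None:
    catalog_table(catalog).to_csv(path, sep="\t", index=False)


def load_catalog_tsv(path) -> list[CircRecord]:
    """Reload a catalog TSV written by :func:`write_catalog`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for _, r in df.iterrows():
        known = (
            str(r["known_ids"]).split(";")
            if isinstance(r["known_ids"], str) and r["known_ids"]
            else []
        )
        records.append(
            CircRecord(
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                strand=str(r["strand"]),
                read_count=int(r["read_count"]),
                host_gene_id=(
                    str(r["host_gene_id"])
                    if isinstance(r["host_gene_id"], str) and r["host_gene_id"]
                    else None
                ),
                host_biotype=(
                    str(r["host_biotype"])
                    if isinstance(r["host_biotype"], str) and r["host_biotype"]
                    else None
                ),
                spliced_length=(
                    int(r["spliced_length"])
                    if not pd.isna(r["spliced_length"])
                    else None
                ),
                known_ids=known,
            )
        )
    return records


def write_summary(summary: CatalogSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
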