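"""Synthetic input bundles with recoverable ground truth.

Generates an internally consistent set of pipeline inputs — gene
annotation (GTF), back-splice-junction calls, linear quantification,
known-circRNA database, per-condition differential-expression tables,
qPCR results and microRNA target lists — from a seeded configuration, and
records everything needed to verify the pipeline's outputs exactly
(:class:`SynthTruth`).

Design notes
------------
* Genes are placed without overlap on each chromosome, so host-gene
  assignment on the generated catalog is unambiguous and recoverable.
* Read counts follow ``1 + NB(mean−1, dispersion)`` (heavy right tail; a
  small minority of junctions exceed 50 reads at the defaults).
* DE tables are generated at the results level (log2fc, padj): planted
  upregulation probability depends on whether the host's length/exon
  ratio falls below the mean ratio of the host-gene pool, which is the
  same threshold the enrichment analysis recomputes.
* Identical (config, seed) ⇒ byte-identical bundle files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, length_exon_ratio, write_gtf
from .catalog import make_circ_id
from .errors import ValidationError
from .expression import classify_circ_vs_linear

_MIN_EXON = 60
_MIN_INTRON = 80
_TABLE_MULTIPLICITY = (587, 126, 32, 12, 4, 2, 3, 2)  # k = 1..8


@dataclass
class SynthConfig:
    seed: int = 0
    n_chromosomes: int = 6
    n_genes: int = 400
    gene_length_median: float = 15000.0
    gene_length_sigma: float = 1.0
    exon_count_p: float = 0.18          # geometric parameter; mean ~ 1/p exons
    max_exons: int = 60
    frac_protein_coding: float = 0.85
    frac_genes_hosting: float = 0.55
    multiplicity_weights: tuple = _TABLE_MULTIPLICITY
    n_circ: int | None = None           # exact hosted-circle count, optional
    frac_intergenic: float = 0.02
    exonic_prob: float = 0.9
    count_mean: float = 8.0
    count_dispersion: float = 3.0
    circ_linear_logratio_mean: float = -3.0
    circ_linear_logratio_sd: float = 1.5
    linear_background_mean: float = 60.0
    known_db_coverage: float = 0.988
    conditions: tuple = ("miR-191", "miR-126", "miR-21")
    enrichment_effect: tuple = (0.30, 0.05)  # P(up | low ratio), P(up | high)
    n_responders: int = 4
    de_alpha: float = 0.05
    qpcr_n: int = 10
    qpcr_intercept: float = 30.0
    qpcr_slope: float = 1.5
    qpcr_noise_sd: float = 0.5
    target_overlap_frac: float = 0.1
    target_list_size: int = 40
    fold_window: float = 2.0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_chromosomes < 1:
            raise ValidationError("n_chromosomes must be >= 1")
        for name in ("frac_protein_coding", "frac_genes_hosting",
                     "frac_intergenic", "exonic_prob", "known_db_coverage",
                     "target_overlap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for p in self.enrichment_effect:
            if not 0.0 <= p <= 1.0:
                raise ValidationError("enrichment_effect probabilities in [0,1]")
        if any(w < 0 for w in self.multiplicity_weights) or sum(self.multiplicity_weights) <= 0:
            raise ValidationError("multiplicity_weights must be non-negative, not all zero")
        if not 0 < self.exon_count_p <= 1:
            raise ValidationError("exon_count_p must be in (0, 1]")
        if self.count_mean <= 1 or self.count_dispersion <= 0:
            raise ValidationError("count model needs mean > 1 and dispersion > 0")

    @classmethod
    def from_file(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValidationError(f"unknown config keys: {sorted(extra)}")
        for key in ("multiplicity_weights", "conditions", "enrichment_effect"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("multiplicity_weights", "conditions", "enrichment_effect"):
            d[key] = list(d[key])
        return d


@dataclass
class SynthTruth:
    """Ground truth of one generated bundle.

    ``genes`` and ``circles`` are DataFrames; ``circles`` carries one
    ``padj_<cond>`` / ``log2fc_<cond>`` / ``status_<cond>`` column triple
    per condition.
    """

    config: dict
    genes: pd.DataFrame
    circles: pd.DataFrame
    genomewide_avg_ratio: float
    planted_responders: list[str]
    targets: dict[str, list[str]] = field(default_factory=dict)
    qpcr_ids: list[str] = field(default_factory=list)

    @property
    def conditions(self) -> list[str]:
        return list(self.config["conditions"])

    # -- truth-side recomputations (used to cross-check the pipeline) ----

    def catalog_summary(self, read_threshold: int = 50,
                        fold_window: float = 2.0) -> dict:
        c = self.circles
        hosted = c["host_gene_id"] != ""
        n_higher = 0
        for _, r in c[hosted].iterrows():
            if classify_circ_vs_linear(r["read_count"], r["linear_abundance"],
                                       fold_window=fold_window) == "higher":
                n_higher += 1
        pc_hosts = set(self.genes.loc[
            self.genes["biotype"] == "protein_coding", "gene_id"])
        return {
            "n_total": int(len(c)),
            "n_known": int(c["in_known_db"].sum()),
            "n_in_protein_coding": int(
                c["host_gene_id"].isin(pc_hosts).sum()),
            "n_over_read_threshold": int((c["read_count"] > read_threshold).sum()),
            "read_threshold": int(read_threshold),
            "n_more_abundant_than_linear": int(n_higher),
        }

    def multiplicity(self) -> dict[int, int]:
        hosted = self.circles[self.circles["host_gene_id"] != ""]
        sizes = hosted.groupby("host_gene_id").size()
        return {int(k): int(v) for k, v in sizes.value_counts().sort_index().items()}

    def chrom_counts(self, biotype: str = "protein_coding") -> pd.DataFrame:
        g = self.genes
        gene_counts = g[g["biotype"] == biotype].groupby("chromosome").size()
        circ_counts = self.circles.groupby("chrom").size()
        chroms = sorted(set(gene_counts.index) | set(circ_counts.index))
        return pd.DataFrame({
            "chromosome": chroms,
            "n_genes": [int(gene_counts.get(c, 0)) for c in chroms],
            "n_circ": [int(circ_counts.get(c, 0)) for c in chroms],
        })

    def recurrent_responders(self, alpha: float = 0.05) -> set[str]:
        c = self.circles
        hosted = c[c["host_gene_id"] != ""]
        sets = []
        for cond in self.conditions:
            sig = hosted[hosted[f"padj_{cond}"] < alpha]
            sets.append(set(sig["host_gene_id"]))
        return set.intersection(*sets) if sets else set()

    # -- (de)serialization ----------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "genes": self.genes.to_dict(orient="list"),
            "circles": self.circles.to_dict(orient="list"),
            "genomewide_avg_ratio": self.genomewide_avg_ratio,
            "planted_responders": self.planted_responders,
            "targets": self.targets,
            "qpcr_ids": self.qpcr_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            config=payload["config"],
            genes=pd.DataFrame(payload["genes"]),
            circles=pd.DataFrame(payload["circles"]),
            genomewide_avg_ratio=payload["genomewide_avg_ratio"],
            planted_responders=payload["planted_responders"],
            targets=payload["targets"],
            qpcr_ids=payload["qpcr_ids"],
        )


@dataclass
class SynthDataset:
    """In-memory view of a generated bundle (before/without file IO)."""

    genes: list  # list[GeneModel]
    circ_calls: pd.DataFrame  # chrom, start, end, strand, count
    known_db: list  # (chrom, start0, end, name, strand) BED-ready
    linear: dict
    de_frames: dict  # condition -> DataFrame(circ_id, log2FoldChange, pvalue, padj)
    qpcr: pd.DataFrame  # circ_id, delta_ct
    targets: dict  # condition -> list[str]
    truth: SynthTruth


# ---------------------------------------------------------------------------
# generation internals


def _exon_layout(rng, length: int, k: int) -> tuple[int, list[tuple[int, int]]]:
    """Offsets (0-based within the gene) of k disjoint, non-adjacent exons;
    first exon starts at 0, last ends at length−1.  Returns the possibly
    enlarged length."""
    if k == 1:
        return length, [(0, length - 1)]
    required = k * _MIN_EXON + (k - 1) * _MIN_INTRON
    if length < required:
        length = required + int(rng.integers(0, 200))
    exonic_frac = float(rng.uniform(0.1, 0.4))
    exonic_total = max(k * _MIN_EXON,
                       min(int(length * exonic_frac),
                           length - (k - 1) * _MIN_INTRON))
    exon_extra = rng.multinomial(exonic_total - k * _MIN_EXON, np.full(k, 1 / k))
    intron_total = length - exonic_total
    intron_extra = rng.multinomial(intron_total - (k - 1) * _MIN_INTRON,
                                   np.full(k - 1, 1 / (k - 1)))
    exons = []
    pos = 0
    for i in range(k):
        e_len = _MIN_EXON + int(exon_extra[i])
        exons.append((pos, pos + e_len - 1))
        pos += e_len
        if i < k - 1:
            pos += _MIN_INTRON + int(intron_extra[i])
    # absorb rounding: stretch the last exon to the gene end
    last_s, _ = exons[-1]
    exons[-1] = (last_s, length - 1)
    return length, exons


def _nb_count(rng, mean: float, dispersion: float) -> int:
    """1 + NB draw with the given mean−1 and dispersion (variance
    m + dispersion·m²)."""
    m = mean - 1.0
    r = 1.0 / dispersion
    p = r / (r + m)
    return 1 + int(rng.negative_binomial(r, p))


def simulate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate a full synthetic dataset in memory (deterministic in
    ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    weights = np.arange(n_chrom, 0, -1, dtype=float)
    weights /= weights.sum()

    # ---- genes --------------------------------------------------------
    chrom_assign = np.sort(rng.choice(n_chrom, size=config.n_genes, p=weights))
    cursors = {c: 10_000 for c in chrom_names}
    genes: list[GeneModel] = []
    mu = math.log(config.gene_length_median)
    for i in range(config.n_genes):
        chrom = chrom_names[int(chrom_assign[i])]
        k = min(int(rng.geometric(config.exon_count_p)), config.max_exons)
        length = max(_MIN_EXON, int(round(rng.lognormal(mu, config.gene_length_sigma))))
        length, offsets = _exon_layout(rng, length, k)
        biotype = ("protein_coding" if rng.random() < config.frac_protein_coding
                   else str(rng.choice(["lncRNA", "processed_pseudogene"])))
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(500, 5_000))
        start = cursors[chrom] + gap
        exons = [(start + s, start + e) for s, e in offsets]
        g = GeneModel(
            gene_id=f"G{i:05d}", gene_name=f"GENE{i:05d}", chromosome=chrom,
            start=start, end=start + length - 1, strand=strand,
            biotype=biotype, exons=exons,
        )
        cursors[chrom] = g.end
        genes.append(g)

    pc_genes = [g for g in genes if g.biotype == "protein_coding"]

    # ---- hosts and multiplicities ------------------------------------
    n_host = int(round(config.frac_genes_hosting * len(pc_genes)))
    n_host = min(n_host, len(pc_genes))
    host_pick = rng.choice(len(pc_genes), size=n_host, replace=False) if n_host else np.array([], dtype=int)
    hosts = [pc_genes[j] for j in sorted(host_pick)]
    wt = np.asarray(config.multiplicity_weights, dtype=float)
    wt /= wt.sum()
    mult = rng.choice(np.arange(1, len(wt) + 1), size=len(hosts), p=wt) if hosts else np.array([], dtype=int)

    host_plan = list(zip(hosts, (int(k) for k in mult)))
    if config.n_circ is not None:
        # queue unused protein-coding genes as k=1 fallbacks so the target
        # is reached even when small hosts can't yield enough unique
        # junctions; generation stops exactly at n_circ
        picked = set(host_pick.tolist())
        host_plan += [(g, 1) for j, g in enumerate(pc_genes) if j not in picked]

    # ---- circles ------------------------------------------------------
    circle_rows = []
    for host, k in host_plan:
        if config.n_circ is not None:
            remaining = config.n_circ - len(circle_rows)
            if remaining <= 0:
                break
            k = min(k, remaining)
        seen = set()
        made = 0
        attempts = 0
        while made < k and attempts < 50 * k:
            attempts += 1
            ne = host.exon_count
            exonic = rng.random() < config.exonic_prob or ne < 2
            if exonic:
                i = int(rng.integers(0, ne))
                j = int(rng.integers(i, ne))
                s, e = host.exons[i][0], host.exons[j][1]
                spl = sum(b - a + 1 for a, b in host.exons[i:j + 1])
            else:
                gi = int(rng.integers(0, ne - 1))
                ilo = host.exons[gi][1] + 1
                ihi = host.exons[gi + 1][0] - 1
                if ihi - ilo + 1 < 40:
                    continue
                s = int(rng.integers(ilo, ihi - 20))
                e = int(rng.integers(s + 10, ihi + 1))
                spl = e - s + 1
            if (s, e) in seen:
                continue
            seen.add((s, e))
            made += 1
            count = _nb_count(rng, config.count_mean, config.count_dispersion)
            circle_rows.append({
                "chrom": host.chromosome, "start": s, "end": e,
                "strand": host.strand, "host_gene_id": host.gene_id,
                "read_count": count, "spliced_length": spl,
            })

    n_inter = int(round(config.frac_intergenic * len(circle_rows)))
    inter_cursor = {c: cursors[c] + 50_000 for c in chrom_names}
    for _ in range(n_inter):
        chrom = chrom_names[int(rng.integers(0, n_chrom))]
        start = inter_cursor[chrom] + int(rng.integers(1_000, 10_000))
        length = int(rng.integers(100, 2_001))
        inter_cursor[chrom] = start + length
        count = _nb_count(rng, config.count_mean, config.count_dispersion)
        circle_rows.append({
            "chrom": chrom, "start": start, "end": start + length - 1,
            "strand": "+" if rng.random() < 0.5 else "-",
            "host_gene_id": "", "read_count": count,
            "spliced_length": length,
        })

    circles = pd.DataFrame(
        circle_rows,
        columns=["chrom", "start", "end", "strand", "host_gene_id",
                 "read_count", "spliced_length"],
    )
    if not circles.empty:
        circles = circles.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        circles["circ_id"] = [
            make_circ_id(c, s, e)
            for c, s, e in zip(circles["chrom"], circles["start"], circles["end"])
        ]
    else:
        circles["circ_id"] = pd.Series(dtype=str)

    # ---- known database ----------------------------------------------
    in_db = rng.random(len(circles)) < config.known_db_coverage
    circles["in_known_db"] = in_db
    known_ids = []
    db_entries = []
    counter = 1
    for idx, row in circles.iterrows():
        if row["in_known_db"]:
            name = f"hsa_circ_{counter:07d}"
            counter += 1
            known_ids.append(name)
            db_entries.append((row["chrom"], int(row["start"]) - 1,
                               int(row["end"]), name, row["strand"]))
        else:
            known_ids.append("")
    circles["known_id"] = known_ids

    # ---- linear quantification ---------------------------------------
    max_count_by_host = (
        circles[circles["host_gene_id"] != ""]
        .groupby("host_gene_id")["read_count"].max().to_dict()
    )
    linear: dict[str, float] = {}
    for g in genes:
        if g.gene_id in max_count_by_host:
            lr = rng.normal(config.circ_linear_logratio_mean,
                            config.circ_linear_logratio_sd)
            linear[g.gene_id] = float(max(
                0, round(max_count_by_host[g.gene_id] * 2.0 ** (-lr))))
        else:
            linear[g.gene_id] = float(rng.poisson(config.linear_background_mean))
    circles["linear_abundance"] = [
        linear.get(h, float("nan")) if h else float("nan")
        for h in circles["host_gene_id"]
    ]

    # ---- ratio classes -----------------------------------------------
    ratio_by_gene = {g.gene_id: length_exon_ratio(g) for g in genes}
    host_ids = sorted({h for h in circles["host_gene_id"] if h})
    gw_avg = float(np.mean([ratio_by_gene[h] for h in host_ids])) if host_ids else float("nan")
    circles["host_ratio"] = [
        ratio_by_gene.get(h, float("nan")) if h else float("nan")
        for h in circles["host_gene_id"]
    ]
    circles["ratio_class"] = [
        ("low" if ratio_by_gene[h] < gw_avg else "high") if h else ""
        for h in circles["host_gene_id"]
    ]

    # ---- responders ---------------------------------------------------
    host_gene_ids = sorted({h for h in circles["host_gene_id"] if h})
    n_resp = min(config.n_responders, len(host_gene_ids))
    responders = sorted(
        rng.choice(host_gene_ids, size=n_resp, replace=False).tolist()
    ) if n_resp else []
    responder_set = set(responders)

    # ---- DE tables ----------------------------------------------------
    p_low, p_high = config.enrichment_effect
    alpha = config.de_alpha
    de_frames: dict[str, pd.DataFrame] = {}
    for cond in config.conditions:
        status, lfc, padj, pval = [], [], [], []
        for _, row in circles.iterrows():
            host = row["host_gene_id"]
            if host and host in responder_set:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                st = "responder_up" if sign > 0 else "responder_down"
                l = sign * float(rng.uniform(0.5, 2.5))
                pa = float(rng.uniform(1e-6, alpha * 0.9))
            elif host:
                p_up = p_low if row["ratio_class"] == "low" else p_high
                if rng.random() < p_up:
                    st = "up"
                    l = float(rng.uniform(0.5, 3.0))
                    pa = float(rng.uniform(1e-6, alpha * 0.9))
                else:
                    st = "stable"
                    l = float(rng.normal(0.0, 0.3))
                    pa = float(rng.uniform(alpha * 1.1, 1.0))
            else:
                st = "stable"
                l = float(rng.normal(0.0, 0.3))
                pa = float(rng.uniform(alpha * 1.1, 1.0))
            status.append(st)
            lfc.append(round(l, 6))
            padj.append(round(pa, 8))
            pval.append(round(pa * float(rng.uniform(0.2, 1.0)), 8))
        circles[f"status_{cond}"] = status
        circles[f"log2fc_{cond}"] = lfc
        circles[f"pvalue_{cond}"] = pval
        circles[f"padj_{cond}"] = padj
        de_frames[cond] = pd.DataFrame({
            "circ_id": circles["circ_id"],
            "log2FoldChange": lfc,
            "pvalue": pval,
            "padj": padj,
        })

    # ---- qPCR ---------------------------------------------------------
    qpcr_ids: list[str] = []
    qpcr_rows = []
    if len(circles) and config.qpcr_n > 0:
        by_count = circles.sort_values(
            ["read_count", "circ_id"], ascending=[False, True]
        ).reset_index(drop=True)
        n_q = min(config.qpcr_n, len(by_count))
        picks = np.unique(np.linspace(0, len(by_count) - 1, n_q).round().astype(int))
        for idx in picks:
            row = by_count.iloc[int(idx)]
            dct = (config.qpcr_intercept
                   - config.qpcr_slope * math.log2(row["read_count"] + 1)
                   + float(rng.normal(0, config.qpcr_noise_sd)))
            qpcr_ids.append(row["circ_id"])
            qpcr_rows.append({"circ_id": row["circ_id"],
                              "delta_ct": round(dct, 4)})
    qpcr = pd.DataFrame(qpcr_rows, columns=["circ_id", "delta_ct"])

    # ---- microRNA target lists ---------------------------------------
    all_gene_ids = [g.gene_id for g in genes]
    targets: dict[str, list[str]] = {}
    for cond in config.conditions:
        up_hosts = sorted({
            h for h, st in zip(circles["host_gene_id"], circles[f"status_{cond}"])
            if h and st in ("up", "responder_up")
        })
        n_hit = int(round(config.target_overlap_frac * len(up_hosts)))
        hits = sorted(rng.choice(up_hosts, size=n_hit, replace=False).tolist()) if n_hit else []
        non_up = [g for g in all_gene_ids if g not in set(up_hosts)]
        n_fill = max(0, config.target_list_size - len(hits))
        fill = sorted(rng.choice(non_up, size=min(n_fill, len(non_up)),
                                 replace=False).tolist())
        targets[cond] = sorted(set(hits) | set(fill))

    # ---- truth / outputs ---------------------------------------------
    gene_rows = pd.DataFrame([{
        "gene_id": g.gene_id, "gene_name": g.gene_name,
        "chromosome": g.chromosome, "start": g.start, "end": g.end,
        "strand": g.strand, "biotype": g.biotype,
        "genomic_length": g.genomic_length, "exon_count": g.exon_count,
        "ratio": length_exon_ratio(g),
        "is_host": g.gene_id in set(host_ids),
    } for g in genes])

    truth = SynthTruth(
        config=config.to_dict(),
        genes=gene_rows,
        circles=circles,
        genomewide_avg_ratio=gw_avg,
        planted_responders=responders,
        targets=targets,
        qpcr_ids=qpcr_ids,
    )

    circ_calls = circles[["chrom", "start", "end", "strand", "read_count"]].rename(
        columns={"read_count": "count"}
    )
    return SynthDataset(
        genes=genes,
        circ_calls=circ_calls.reset_index(drop=True),
        known_db=db_entries,
        linear=linear,
        de_frames=de_frames,
        qpcr=qpcr,
        targets=targets,
        truth=truth,
    )


def _safe_label(label: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-_." else "_" for ch in label)


def generate_bundle(config: SynthConfig, out_dir) -> tuple[dict, SynthTruth]:
    """Generate a bundle and write every file; returns (paths, truth)."""
    ds = simulate_dataset(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "annotation.gtf",
        "circ_calls": out / "circ_calls.tsv",
        "known_db": out / "known_db.bed",
        "linear": out / "linear_quant.tsv",
        "qpcr": out / "qpcr.tsv",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
    }
    write_gtf(ds.genes, paths["gtf"])
    ds.circ_calls.to_csv(paths["circ_calls"], sep="\t", index=False)
    with open(paths["known_db"], "w") as fh:
        for chrom, s0, e, name, strand in ds.known_db:
            fh.write(f"{chrom}\t{s0}\t{e}\t{name}\t0\t{strand}\n")
    with open(paths["linear"], "w") as fh:
        fh.write("gene_id\tabundance\n")
        for gid in sorted(ds.linear):
            fh.write(f"{gid}\t{ds.linear[gid]:g}\n")
    ds.qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    for cond, frame in ds.de_frames.items():
        p = out / f"de_{_safe_label(cond)}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[f"de_{cond}"] = p
    for cond, gene_list in ds.targets.items():
        p = out / f"targets_{_safe_label(cond)}.txt"
        with open(p, "w") as fh:
            for gid in gene_list:
                fh.write(gid + "\n")
        paths[f"targets_{cond}"] = p
    ds.truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}, ds.truth


def planted_enrichment_check(truth: SynthTruth, result) -> dict:
    """Did an enrichment result recover the planted effect?

    Compares the sign of (avg_ratio_overexpressed − avg_ratio_stable)
    with the planted effect direction and reports whether p < alpha.
    """
    if result.condition not in truth.conditions:
        raise ValidationError(
            f"condition {result.condition!r} not in truth "
            f"({truth.conditions})"
        )
    p_low, p_high = truth.config["enrichment_effect"]
    alpha = truth.config["de_alpha"]
    diff = result.avg_ratio_overexpressed - result.avg_ratio_stable
    planted_direction = 0 if p_low == p_high else (-1 if p_low > p_high else 1)
    observed_direction = -1 if diff < 0 else (1 if diff > 0 else 0)
    return {
        "condition": result.condition,
        "planted_direction": planted_direction,
        "observed_direction": observed_direction,
        "sign_matches": planted_direction != 0
        and planted_direction == observed_direction,
        "significant": bool(result.p_value < alpha),
        "p_value": float(result.p_value),
        "mean_ratio_difference": float(diff),
    }
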