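"""Circular-vs-linear abundance comparison and RNA-seq/qPCR concordance.

The Spearman machinery here is shared by the whole package: mid-rank rho,
an exact permutation p-value for small samples (n ≤ 10) and a
t-approximation beyond that.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)

EXACT_N_MAX = 10  # exact permutation p-value up to this sample size


# ---------------------------------------------------------------------------
# circular vs linear classification


def classify_circ_vs_linear(
    circ_count: float,
    linear_count: float,
    fold_window: float = 2.0,
    pseudocount: float = 1.0,
) -> str:
    """Trichotomize a circRNA count against its host's linear abundance.

    With a pseudocount added to both values, the ratio
    ``(circ + pc) / (linear + pc)`` is compared against a symmetric fold
    window: above it → ``"higher"``, below its reciprocal → ``"lower"``,
    otherwise ``"equal"``.
    """
    if circ_count < 0 or linear_count < 0:
        raise ValidationError("counts must be non-negative")
    if fold_window < 1:
        raise ValidationError("fold_window must be >= 1")
    r = (circ_count + pseudocount) / (linear_count + pseudocount)
    if r > fold_window:
        return "higher"
    if r < 1.0 / fold_window:
        return "lower"
    return "equal"


def circ_linear_distribution(
    catalog: Sequence, linear: Mapping[str, float], fold_window: float = 2.0
) -> dict[str, int]:
    """Counts of lower/equal/higher over records with a quantified host
    gene; records without one are tallied as ``unassessed``."""
    out = {"lower": 0, "equal": 0, "higher": 0, "unassessed": 0}
    for r in catalog:
        gid = r.host_gene_id
        if gid is None or gid not in linear:
            out["unassessed"] += 1
            continue
        out[classify_circ_vs_linear(r.read_count, linear[gid], fold_window)] += 1
    return out


# ---------------------------------------------------------------------------
# Spearman correlation


def _ranks(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of mid-ranks (average ranks for ties).

    With no ties this equals ``1 − 6·Σd² / (n(n²−1))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValidationError("need at least 2 observations")
    rx, ry = _ranks(x), _ranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("zero rank variance")
    return float(np.corrcoef(rx, ry)[0, 1])


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    """All n! permutations of 0..n−1 as an (n!, n) int8 array, built by
    inserting each new element at every position (no Python-level n! loop).
    """
    perms = np.zeros((1, 1), dtype=np.int8)
    for k in range(2, n + 1):
        m = perms.shape[0]
        blocks = []
        for i in range(k):
            col = np.full((m, 1), k - 1, dtype=np.int8)
            blocks.append(np.concatenate([perms[:, :i], col, perms[:, i:]], axis=1))
        perms = np.concatenate(blocks, axis=0)
    return perms


@lru_cache(maxsize=4)
def _null_abs_rho_sorted(n: int) -> np.ndarray:
    """Sorted |rho| over all n! permutations of untied ranks."""
    perms = _all_permutations(n).astype(np.int64)
    ident = np.arange(n, dtype=np.int64)
    d2 = ((perms - ident) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    out = np.abs(rho)
    out.sort()
    return out


def exact_permutation_pvalue(rx: Sequence[float], ry: Sequence[float]) -> float:
    """Exact two-sided permutation p-value of the mid-rank correlation,
    enumerating all n! pairings of the given rank vectors (handles ties)."""
    rx = np.asarray(rx, dtype=float)
    ry = np.asarray(ry, dtype=float)
    n = len(rx)
    if n > EXACT_N_MAX:
        raise ValidationError(f"exact enumeration limited to n <= {EXACT_N_MAX}")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    if denom == 0:
        raise UndefinedCorrelationError("zero rank variance")
    obs = abs(float(rxc @ ryc))
    perms = _all_permutations(n)
    total = perms.shape[0]
    hits = 0
    chunk = 500_000
    for lo in range(0, total, chunk):
        stats = np.abs(ryc[perms[lo : lo + chunk].astype(np.intp)] @ rxc)
        hits += int((stats >= obs - 1e-9 * denom).sum())
    return hits / total


def spearman_pvalue(rho: float, n: int, method: str = "auto") -> float:
    """Two-sided p-value for a Spearman rho at sample size n.

    ``exact`` enumerates the permutation distribution of rho over untied
    ranks (used automatically for n ≤ 10); ``t`` uses the
    ``t = rho·sqrt((n−2)/(1−rho²))`` approximation with n−2 df.  A |rho|
    of 1 under the t method returns the probability of the most extreme
    enumerable outcome (2/n!) instead of dividing by zero.
    """
    if n < 4:
        raise ValidationError("need n >= 4 for a p-value")
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "t"
    if method == "exact":
        null = _null_abs_rho_sorted(n)
        idx = np.searchsorted(null, abs(rho) - 1e-12, side="left")
        return float((len(null) - idx) / len(null))
    if method == "t":
        if 1.0 - rho * rho <= 0:
            return min(1.0, 2.0 / math.factorial(n))
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * sps.t.sf(abs(t), n - 2))
    raise ValidationError(f"unknown method {method!r}")


def spearman_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """rho, two-sided p and the method used (exact permutation for
    n ≤ 10 — tie-aware — else t-approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearman_rho(x, y)
    n = len(x)
    if n <= EXACT_N_MAX:
        rx, ry = _ranks(x), _ranks(y)
        has_ties = len(np.unique(rx)) < n or len(np.unique(ry)) < n
        if has_ties:
            return rho, exact_permutation_pvalue(rx, ry), "exact-permutation"
        return rho, spearman_pvalue(rho, n, method="exact"), "exact-permutation"
    return rho, spearman_pvalue(rho, n, method="t"), "t-approximation"


# ---------------------------------------------------------------------------
# qPCR concordance


@dataclass
class ConcordanceResult:
    n: int
    rho: float
    p_value: float
    method: str
    unmatched_catalog: list[str] = field(default_factory=list)
    unmatched_qpcr: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rho": self.rho,
            "p_value": self.p_value,
            "method": self.method,
        }


def load_linear_quant(path) -> dict[str, float]:
    """TSV of gene_id → abundance (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.empty:
        return {}
    if str(df.iloc[0, 0]).lower() in {"gene_id", "gene"}:
        df = df.iloc[1:]
    out = {}
    for _, r in df.iterrows():
        v = float(r.iloc[1])
        if v < 0:
            raise ValidationError(f"negative abundance for {r.iloc[0]}")
        out[str(r.iloc[0])] = v
    return out


def load_qpcr(path) -> dict[str, float]:
    """TSV of circ_id → delta-Ct (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.empty:
        return {}
    if str(df.iloc[0, 0]).lower() in {"circ_id", "id"}:
        df = df.iloc[1:]
    return {str(r.iloc[0]): float(r.iloc[1]) for _, r in df.iterrows()}


def concordance(
    counts: Mapping[str, float] | Iterable,
    qpcr: Mapping[str, float],
) -> ConcordanceResult:
    """Spearman concordance between RNA-seq read counts and qPCR delta-Ct,
    paired by circ_id.  ``counts`` may be a mapping circ_id → count or an
    iterable of catalog records."""
    if not isinstance(counts, Mapping):
        counts = {r.circ_id: r.read_count for r in counts}
    shared = sorted(set(counts) & set(qpcr))
    unmatched_catalog = sorted(set(counts) - set(qpcr))
    unmatched_qpcr = sorted(set(qpcr) - set(counts))
    if unmatched_qpcr:
        warnings.warn(
            f"{len(unmatched_qpcr)} qPCR ids not found in the catalog: "
            + ", ".join(unmatched_qpcr[:5]),
            stacklevel=2,
        )
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared circ_ids, found {len(shared)}"
        )
    x = [float(counts[c]) for c in shared]
    y = [float(qpcr[c]) for c in shared]
    rho, p, method = spearman_test(x, y)
    return ConcordanceResult(
        n=len(shared),
        rho=rho,
        p_value=p,
        method=method,
        unmatched_catalog=unmatched_catalog,
        unmatched_qpcr=unmatched_qpcr,
    )
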