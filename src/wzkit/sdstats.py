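"""Exact association tests, inheritance-model goodness of fit and ANOVA.

Marker-by-sex association in a small case-control cohort calls for exact
conditional tests: Fisher's test for 2x2 tables and its Freeman-Halton
generalisation for r x 2 genotype tables, both summing the probabilities of
every margin-fixed table no more probable than the observed one.  Candidate
inheritance models for a W-like locus (autosomal Hardy-Weinberg, lethal WW
homozygote, obligate female-determining W) are compared against observed
ZZ/WZ/WW counts with Pearson chi-squared goodness of fit.  A one-way ANOVA
rounds out the expression comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

#: relative tolerance for probability ties in the exact tests
TIE_RTOL = 1e-7

MODEL_NAMES = ("autosomal", "lethal_ww", "female_w")


@dataclass
class ContingencyTable:
    """Genotype-by-sex counts with labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(self.counts.shape[1])]


@dataclass
class GofResult:
    """Pearson goodness-of-fit outcome for one inheritance model."""

    chi2: float
    df: int
    p: float
    expected: np.ndarray
    model_name: str = ""

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not 0.0 <= self.p <= 1.0 or self.df < 0:
            raise ValueError("invalid goodness-of-fit result")


@dataclass(frozen=True)
class AlleleFreqs:
    """Z / W allele frequencies (p + q = 1)."""

    p_z: float
    q_w: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_z <= 1.0 and 0.0 <= self.q_w <= 1.0):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if abs(self.p_z + self.q_w - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return np.asarray(table, dtype=int)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method)."""
    t = _as_counts(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("empty margin: association is undefined, returning p = 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def fisher_exact_rxc(table) -> float:
    """Freeman-Halton exact test for an r x 2 table (r <= 8).

    Enumerates every table with both margins fixed and sums the conditional
    (multivariate hypergeometric) probabilities of all tables whose point
    probability does not exceed the observed one, with a relative tie
    tolerance of 1e-7.
    """
    t = _as_counts(table)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("fisher_exact_rxc handles r x 2 tables")
    t = t[t.sum(axis=1) > 0]  # empty rows carry no probability mass
    if t.shape[0] > 8:
        raise ValueError("tables beyond 8 rows are too large to enumerate")
    if t.shape[0] < 2 or np.any(t.sum(axis=0) == 0):
        warnings.warn("degenerate margins: association is undefined, returning p = 1")
        return 1.0
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    const = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1))

    def log_prob(col1_cells: Sequence[int]) -> float:
        cells = np.empty(2 * len(rows))
        cells[0::2] = col1_cells
        cells[1::2] = rows - np.asarray(col1_cells)
        return const - float(gammaln(cells + 1).sum())

    log_obs = log_prob(t[:, 0])
    log_tie = log_obs + np.log1p(TIE_RTOL)
    suffix = np.concatenate([np.cumsum(rows[::-1])[::-1][1:], [0]])
    total = 0.0
    stack = [(0, int(cols[0]), [])]
    while stack:
        i, remaining, acc = stack.pop()
        if i == len(rows) - 1:
            if 0 <= remaining <= rows[i]:
                lp = log_prob(acc + [remaining])
                if lp <= log_tie:
                    total += float(np.exp(lp))
            continue
        lo = max(0, remaining - int(suffix[i]))
        hi = min(int(rows[i]), remaining)
        for a in range(lo, hi + 1):
            stack.append((i + 1, remaining - a, acc + [a]))
    return min(1.0, total)


def hwe_expected(freqs: AlleleFreqs, n: int) -> np.ndarray:
    """Expected (ZZ, WZ, WW) counts under Hardy-Weinberg: n * (p^2, 2pq, q^2)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    p, q = freqs.p_z, freqs.q_w
    return n * np.array([p * p, 2 * p * q, q * q])


def model_expected(model_name: str, freqs: AlleleFreqs, n: int) -> np.ndarray:
    """Expected (ZZ, WZ, WW) counts under a named inheritance model.

    autosomal: Hardy-Weinberg p^2, 2pq, q^2.
    lethal_ww: WW homozygotes eliminated, survivors renormalised by 1 - q^2.
    female_w: every (female) individual is an obligate WZ heterozygote.
    """
    p, q = freqs.p_z, freqs.q_w
    if model_name == "autosomal":
        return hwe_expected(freqs, n)
    if model_name == "lethal_ww":
        if q >= 1.0:
            raise ValueError("lethal_ww is undefined when q = 1")
        denom = 1.0 - q * q
        return n * np.array([p * p / denom, 2 * p * q / denom, 0.0])
    if model_name == "female_w":
        return n * np.array([0.0, 1.0, 0.0])
    raise ValueError(f"unknown inheritance model {model_name!r}; "
                     f"choose from {MODEL_NAMES}")


def gof_pearson(observed, expected, model_name: str = "") -> GofResult:
    """Pearson chi-squared goodness of fit with structural-zero handling.

    Cells with zero expectation contribute no degrees of freedom; an observed
    count in such a cell is impossible under the model, which is rejected
    outright (p = 0).  df = (number of supported cells) - 1; a zero-df exact
    fit has p = 1.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(exp < 0):
        raise ValueError("expected counts must be non-negative")
    support = exp > 0
    df = max(int(support.sum()) - 1, 0)
    if np.any((~support) & (obs > 0)):
        return GofResult(float("inf"), df, 0.0, exp, model_name)
    chi2 = float(np.sum((obs[support] - exp[support]) ** 2 / exp[support]))
    if df == 0:
        p = 1.0 if chi2 <= 1e-12 else 0.0
    else:
        p = float(stats.chi2.sf(chi2, df))
    return GofResult(chi2, df, p, exp, model_name)


def hwe_deviation_test(genotype_counts: Sequence[int]) -> GofResult:
    """Test (ZZ, WZ, WW) counts against Hardy-Weinberg with estimated q.

    The W frequency is estimated from the counts, q = (WZ + 2 WW) / 2N, which
    costs one degree of freedom: df = 3 - 1 - 1 = 1.  A monomorphic sample
    fits trivially (p = 1).
    """
    zz, wz, ww = (int(c) for c in genotype_counts)
    n = zz + wz + ww
    if n <= 0:
        raise ValueError("at least one individual is required")
    q = (wz + 2 * ww) / (2 * n)
    if q in (0.0, 1.0):
        return GofResult(0.0, 0, 1.0, np.array([n * (1 - q), 0.0, n * q]), "hwe")
    freqs = AlleleFreqs(1 - q, q)
    exp = hwe_expected(freqs, n)
    chi2 = float(np.sum((np.array([zz, wz, ww]) - exp) ** 2 / exp))
    return GofResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), exp, "hwe")


@dataclass
class MarkerAssociation:
    marker: str
    position_kbp: float
    table: ContingencyTable
    p: float


@dataclass
class ScanResult:
    """Ranked per-marker association results with the delimited interval."""

    results: list[MarkerAssociation]
    interval_kbp: Optional[tuple[float, float]]
    span_kbp: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"marker": r.marker, "position_kbp": r.position_kbp, "p": r.p}
             for r in self.results]
        )


def association_scan(cohort: pd.DataFrame, markers: Sequence, *,
                     top_factor: float = 1e6) -> ScanResult:
    """Genotype-by-sex exact tests for every marker, plus interval delimitation.

    Dominant markers are collapsed to presence/absence of their dominant
    allele before tabulation.  The maximally associated block comprises the
    markers whose p lies within ``top_factor`` of the minimum; the critical
    interval runs between the nearest flanking weaker markers (or the
    outermost block marker where none flanks), mirroring how a candidate
    region is delimited on a physical map.
    """
    if "sex" not in cohort.columns:
        raise ValueError("cohort must have a 'sex' column")
    sexes = ["F", "M"]
    present = sorted(set(cohort["sex"]))
    if len(present) < 2:
        warnings.warn("single-sex cohort: association is undefined for all markers")
    results = []
    for marker in markers:
        genotypes = cohort[marker.name].astype("object")
        unknown = genotypes.isna()
        if unknown.any():
            warnings.warn(f"{int(unknown.sum())} unknown genotype codes for "
                          f"{marker.name} counted as 'other'")
            genotypes = genotypes.fillna("other")
        if marker.dominant:
            genotypes = genotypes.map(
                lambda g: "P" if marker.dominant_allele in str(g) else "A")
        values = sorted(set(genotypes))
        counts = np.array(
            [[int(((genotypes == g) & (cohort["sex"] == s)).sum()) for s in sexes]
             for g in values]
        )
        ct = ContingencyTable(counts, row_labels=list(values), col_labels=sexes)
        if len(present) < 2 or len(values) < 2:
            p = 1.0
        elif counts.shape[0] == 2:
            p = fisher_exact_2x2(ct)
        else:
            p = fisher_exact_rxc(ct)
        results.append(MarkerAssociation(marker.name, marker.position_kbp, ct, p))
    results.sort(key=lambda r: (r.p, r.position_kbp))
    interval = span = None
    min_p = min((r.p for r in results), default=1.0)
    if min_p < 1.0:
        top = [r for r in results if r.p <= min_p * top_factor]
        weaker = [r for r in results if r not in top]
        lo = min(r.position_kbp for r in top)
        hi = max(r.position_kbp for r in top)
        left = max((r.position_kbp for r in weaker if r.position_kbp < lo),
                   default=lo)
        right = min((r.position_kbp for r in weaker if r.position_kbp > hi),
                    default=hi)
        interval = (left, right)
        span = right - left
    return ScanResult(results, interval, span)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MSB/MSW with an upper-tail F p-value."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    if sum(len(g) for g in groups) - len(groups) < 1:
        raise ValueError("at least one group needs >= 2 values")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        raise ValueError("all values identical: F is undefined (0/0)")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    if np.isnan(f):  # zero within-group variance with non-zero between
        raise ValueError("zero within-group variance: F is undefined")
    return float(f), float(p)
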