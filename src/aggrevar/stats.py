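"""Cohort-comparison statistics: 2x2 chi-square enrichment tests,
Mann-Whitney U comparisons, binned enrichment curves and proportion
estimates with Wilson confidence intervals.

Chi-square is plain Pearson without continuity correction (df = 1); raw
p-values are reported throughout, with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a/b = pathogenic with/without the property, c/d = neutral."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or int(x) != x for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) <= 0:
            raise ValueError("table total must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_flags(
        cls, flags_pathogenic: Sequence[bool], flags_neutral: Sequence[bool]
    ) -> "ContingencyTable2x2":
        fp = np.asarray(flags_pathogenic, dtype=bool)
        fn = np.asarray(flags_neutral, dtype=bool)
        return cls(
            int(fp.sum()), int(len(fp) - fp.sum()),
            int(fn.sum()), int(len(fn) - fn.sum()),
        )


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def chi_square_2x2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    m = table.matrix
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        raise ValueError(
            "zero marginal: chi-square undefined; an exact test is advised"
        )
    stat, p, _, _ = sps.chi2_contingency(m, correction=False)
    return TestResult(
        "chi_square", float(stat), float(p), (int(m[0].sum()), int(m[1].sum()))
    )


#: Largest per-sample size at which the exact Mann-Whitney null is used.
MWU_EXACT_MAX_N = 12


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode``: "exact" (enumerated null; requires no ties), "asymptotic"
    (normal approximation with tie correction), or "auto" — exact when both
    samples have n <= 12 and the pooled data are tie-free, else asymptotic.
    U is reported as min(U_x, U_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        mode = (
            "exact"
            if len(x) <= MWU_EXACT_MAX_N and len(y) <= MWU_EXACT_MAX_N and not has_ties
            else "asymptotic"
        )
    if mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires tie-free data")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if mode == "exact" else "asymptotic",
        use_continuity=False,
    )
    u = min(float(res.statistic), len(x) * len(y) - float(res.statistic))
    return TestResult("mann_whitney_u", u, float(res.pvalue), (len(x), len(y)))


@dataclass(frozen=True)
class EnrichmentBinTable:
    """Per-bin cohort frequencies and their difference (pathogenic - neutral)."""

    edges: np.ndarray
    freq_pathogenic: np.ndarray
    freq_neutral: np.ndarray
    difference: np.ndarray
    n_clamped_pathogenic: int
    n_clamped_neutral: int

    def __post_init__(self) -> None:
        for f in (self.freq_pathogenic, self.freq_neutral):
            if abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("cohort frequencies must sum to 1")


def _bin_counts(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, int]:
    """Half-open [lo, hi) bins, last bin closed; out-of-range values are
    clamped into the end bins (their count is reported)."""
    nbins = len(edges) - 1
    idx = np.searchsorted(edges, values, side="right") - 1
    # values equal to the last edge belong to the last (closed) bin
    idx[values == edges[-1]] = nbins - 1
    clamped = int(((values < edges[0]) | (values > edges[-1])).sum())
    idx = np.clip(idx, 0, nbins - 1)
    return np.bincount(idx, minlength=nbins).astype(float), clamped


def enrichment_by_bin(
    values_pathogenic: Sequence[float],
    values_neutral: Sequence[float],
    edges: Sequence[float],
) -> EnrichmentBinTable:
    """Per-bin relative frequencies of each cohort and their difference.

    A positive difference indicates enrichment of pathogenic variants in
    that bin. Differences sum to zero across bins.
    """
    vp = np.asarray(values_pathogenic, dtype=float)
    vn = np.asarray(values_neutral, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if len(vp) == 0 or len(vn) == 0:
        raise ValueError("both cohorts must be non-empty")
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    cp, clp = _bin_counts(vp, edges)
    cn, cln = _bin_counts(vn, edges)
    fp = cp / cp.sum()
    fn = cn / cn.sum()
    return EnrichmentBinTable(edges, fp, fn, fp - fn, clp, cln)


#: Default ddG bin edges (kcal/mol): width 0.5 over [-5, 10], clamped ends.
DEFAULT_DDG_EDGES = np.arange(-5.0, 10.0 + 0.25, 0.5)
#: Default strongest-APR score bin edges: width 10 over [0, 300].
DEFAULT_APR_SCORE_EDGES = np.arange(0.0, 300.0 + 5.0, 10.0)


@dataclass(frozen=True)
class FractionResult:
    """A proportion with its Wilson 95% score interval."""

    fraction: float
    ci_low: float
    ci_high: float
    n_with_property: int
    n_used: int
    n_na: int


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def fraction_with_property(
    classifications: Sequence,
    prop: str | Callable[[object], bool | None],
    cohort: str | None = None,
    alpha: float = 0.05,
) -> FractionResult:
    """Proportion of a cohort carrying a (possibly NA-valued) property.

    ``prop`` is an attribute/row-key name or a callable returning
    True/False/None; None (NA) records are excluded from the denominator
    and tallied in ``n_na``. ``cohort`` filters on the variant label.
    """
    if callable(prop):
        get = prop
    else:
        def get(c, _name=prop):
            row = c.as_row() if hasattr(c, "as_row") else c
            return row[_name]

    sub = [
        c
        for c in classifications
        if cohort is None
        or (c.variant.label if hasattr(c, "variant") else c["label"]) == cohort
    ]
    if not sub:
        raise ValueError(f"empty cohort {cohort!r}")
    flags = [get(c) for c in sub]
    used = [bool(f) for f in flags if f is not None]
    if not used:
        raise ValueError("no non-NA records in cohort")
    k = sum(used)
    lo, hi = wilson_interval(k, len(used), alpha)
    return FractionResult(
        fraction=k / len(used),
        ci_low=lo,
        ci_high=hi,
        n_with_property=k,
        n_used=len(used),
        n_na=len(flags) - len(used),
    )
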