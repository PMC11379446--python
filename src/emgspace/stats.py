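"""Repeated-measures statistical battery and endurance-time regression.

For each variable measured at T1/T2/T3 over N subjects: Shapiro-Wilk
normality screening per condition, the Friedman rank test with
Kendall's W as effect size (Cohen bands: small < 0.3, moderate < 0.5,
large >= 0.5), Wilcoxon signed-rank post-hoc pairs with a Bonferroni
factor of 3, and per-metric simple linear regression of endurance time
on the segment maxima.

Friedman p-values come from the chi-square(k-1) approximation with the
standard tie correction; for small tie-free tables (k <= 4) an exact
permutation p is computed in addition, by dynamic programming over the
column rank-sum distribution (equivalent to enumerating all (k!)^N
rankings).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

EFFECT_BANDS = ((0.3, "small"), (0.5, "moderate"), (1.0 + 1e-12, "large"))


def effect_label(kendall_w: float) -> str:
    """Cohen interpretation band for Kendall's W."""
    for upper, label in EFFECT_BANDS:
        if kendall_w < upper:
            return label
    return "large"


@dataclass
class RepeatedMeasuresTable:
    """Subjects x conditions matrix for one variable (conditions ordered
    T1, T2, T3).  Rows with missing cells are dropped listwise."""

    data: np.ndarray
    variable: str = ""
    conditions: tuple[str, ...] = ("T1", "T2", "T3")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("table must be 2-D (subjects x conditions)")
        if self.data.shape[1] != len(self.conditions):
            raise ValueError("condition labels do not match table width")
        keep = np.isfinite(self.data).all(axis=1)
        if not keep.all():
            warnings.warn(
                f"{self.variable or 'table'}: dropped {int((~keep).sum())} subjects "
                "with missing cells (listwise deletion)",
                stacklevel=2,
            )
            self.data = self.data[keep]
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 complete subjects")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 conditions")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def k(self) -> int:
        return self.data.shape[1]


def shapiro_wilk(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p; constant samples are undefined (NaN)."""
    x = np.asarray(sample, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return math.nan, math.nan
    res = spstats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _mid_ranks(row: np.ndarray) -> np.ndarray:
    return spstats.rankdata(row)


def friedman_chi2(data: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square statistic."""
    n, k = data.shape
    ranks = np.apply_along_axis(_mid_ranks, 1, data)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # standard tie correction
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        return math.nan
    return float(chi2 / correction)


def friedman_exact_p(data: np.ndarray) -> float | None:
    """Exact permutation p for a tie-free table with k <= 4.

    Under the null every row ranking is uniform over the k! orderings;
    the statistic depends only on the column rank sums, so their joint
    distribution is built by an N-step dynamic program and the p-value
    is the tail mass at or above the observed chi-square.  Returns None
    when ties are present or k > 4.
    """
    n, k = data.shape
    if k > 4 or (k == 3 and n > 30) or (k == 4 and n > 12) or k < 2:
        return None
    for row in data:
        if np.unique(row).size != k:
            return None  # ties: exact enumeration assumes distinct ranks
    perms = [np.array(p) for p in itertools.permutations(range(1, k + 1))]
    states: dict[tuple[int, ...], float] = {tuple([0] * k): 1.0}
    for _ in range(n):
        nxt: dict[tuple[int, ...], float] = {}
        for state, count in states.items():
            for p in perms:
                key = tuple(int(s + r) for s, r in zip(state, p))
                nxt[key] = nxt.get(key, 0.0) + count
        states = nxt
    total = math.factorial(k) ** n
    obs = friedman_chi2(data)
    scale = 12.0 / (n * k * (k + 1))
    shift = 3.0 * n * (k + 1)
    tail = 0.0
    for sums, count in states.items():
        chi2 = scale * sum(s * s for s in sums) - shift
        if chi2 >= obs - 1e-9:
            tail += count
    return tail / total


@dataclass
class FriedmanResult:
    chi2: float
    p: float
    p_exact: float | None
    kendall_w: float
    effect: str
    n_subjects: int
    k: int


def friedman(table: RepeatedMeasuresTable) -> FriedmanResult:
    """Friedman test with Kendall's W effect size.

    W = chi2 / (N (k-1)); perfect concordance over strict rankings gives
    W = 1 and chi2 = N (k-1).  All-constant rows make the statistic
    undefined (NaN).
    """
    data = table.data
    n, k = data.shape
    chi2 = friedman_chi2(data)
    if not np.isfinite(chi2):
        return FriedmanResult(math.nan, math.nan, None, math.nan, "undefined", n, k)
    p = float(spstats.chi2.sf(chi2, k - 1))
    p_exact = friedman_exact_p(data)
    w = float(chi2 / (n * (k - 1)))
    return FriedmanResult(chi2, p, p_exact, w, effect_label(w), n, k)


@dataclass
class PairwiseRow:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    flag: str


def _sig_flag(p: float, alpha: tuple[float, float] = (0.05, 0.01)) -> str:
    if not np.isfinite(p):
        return ""
    if p < alpha[1]:
        return "**"
    if p < alpha[0]:
        return "*"
    return ""


def wilcoxon_pairwise(
    table: RepeatedMeasuresTable,
    correction: str = "bonferroni",
    alpha: tuple[float, float] = (0.05, 0.01),
) -> list[PairwiseRow]:
    """All pairwise Wilcoxon signed-rank tests with Bonferroni adjustment.

    Two-sided; exact signed-rank distribution for n <= 25 without
    ties/zeros (scipy's automatic policy), normal approximation
    otherwise.  Zero differences are dropped (signed-rank convention).
    The adjusted p is min(1, 3 p) for the three T1/T2/T3 pairs.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    pairs = list(itertools.combinations(range(table.k), 2))
    m = len(pairs)
    rows: list[PairwiseRow] = []
    for i, j in pairs:
        x, y = table.data[:, i], table.data[:, j]
        d = x - y
        if np.all(d == 0):
            warnings.warn(
                f"{table.variable or 'table'}: all differences zero for "
                f"{table.conditions[i]}-{table.conditions[j]}; p = 1",
                stacklevel=2,
            )
            stat, p = math.nan, 1.0
        else:
            res = spstats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                                   method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            PairwiseRow(
                pair=(table.conditions[i], table.conditions[j]),
                statistic=stat,
                p_raw=p,
                p_adjusted=min(1.0, m * p),
                flag=_sig_flag(min(1.0, m * p), alpha),
            )
        )
    return rows


@dataclass
class VariableReport:
    variable: str
    shapiro_p: dict[str, float]
    friedman: FriedmanResult
    pairwise: list[PairwiseRow] = field(default_factory=list)


def analyze_variable(
    table: RepeatedMeasuresTable,
    gate_alpha: float | None = 0.05,
) -> VariableReport:
    """Full battery for one variable: normality screen, Friedman, and —
    when the Friedman test clears ``gate_alpha`` — the post-hoc pairs."""
    shapiro = {}
    for j, cond in enumerate(table.conditions):
        try:
            _, p = shapiro_wilk(table.data[:, j])
        except ValueError:
            p = math.nan
        shapiro[cond] = p
    fr = friedman(table)
    pairwise: list[PairwiseRow] = []
    if gate_alpha is None or (np.isfinite(fr.p) and fr.p < gate_alpha):
        pairwise = wilcoxon_pairwise(table)
    return VariableReport(table.variable, shapiro, fr, pairwise)


@dataclass
class RegressionRow:
    metric: str
    r2: float
    p: float
    slope: float
    intercept: float
    n: int


def endurance_regression(
    maxima: dict[str, np.ndarray] | "np.ndarray",
    endurance_s: np.ndarray,
    metric_names: list[str] | None = None,
) -> list[RegressionRow]:
    """Per-metric OLS of endurance time on the subject-wise metric maxima.

    ``maxima`` maps metric name -> per-subject values (or a 2-D array
    with ``metric_names``).  Reports R² and the slope F-test p (which for
    simple regression equals the slope t-test p).  Zero-variance
    predictors are skipped with NaN.
    """
    endurance_s = np.asarray(endurance_s, dtype=float)
    if isinstance(maxima, np.ndarray):
        if metric_names is None:
            raise ValueError("metric_names required with an array input")
        maxima = {name: maxima[:, j] for j, name in enumerate(metric_names)}
    rows: list[RegressionRow] = []
    for name, values in maxima.items():
        x = np.asarray(values, dtype=float)
        keep = np.isfinite(x) & np.isfinite(endurance_s)
        xs, ys = x[keep], endurance_s[keep]
        if xs.size < 3:
            rows.append(RegressionRow(name, math.nan, math.nan, math.nan, math.nan, int(xs.size)))
            continue
        if np.ptp(xs) == 0:
            warnings.warn(f"{name}: zero-variance predictor; regression undefined",
                          stacklevel=2)
            rows.append(RegressionRow(name, math.nan, math.nan, math.nan, math.nan, int(xs.size)))
            continue
        res = spstats.linregress(xs, ys)
        rows.append(
            RegressionRow(name, float(res.rvalue**2), float(res.pvalue),
                          float(res.slope), float(res.intercept), int(xs.size))
        )
    return rows
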