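"""Univariate scores and tests for patient-subgroup detection.

Every statistic here operates on a single variable (a gene or protein)
whose observations are split into a control group ``C`` and a disease
group ``D``.  The working hypothesis is that an interesting variable is
up-regulated only in an (unknown) subgroup of the disease samples, so a
plain location test is not the right tool: the methods below instead
look at the extreme upper tail of the per-variable distribution.

The centerpiece is the FisherSum score: observations above a cutpoint
chosen as the 90%-quantile of the disease group are median-centred
(with the control median) and summed, with exceeding *control*
observations entering as a penalty.  The penalty makes the score
selective for *disease-specific* subgroups — a variable whose upper
tail is inflated in both groups scores near zero.

All scores are wrapped in :class:`MethodScore`, which records the
orientation (higher-is-evidence for scores, lower-is-evidence for
p-values) so that downstream ranking and ROC analysis can treat the
methods uniformly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("fishersum")

HIGHER = "higher_is_evidence"
LOWER = "lower_is_evidence"


def _as_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(
            f"{name} group needs at least 2 observations, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} group contains non-finite values")
    return arr


@dataclass(frozen=True)
class TwoGroupVector:
    """One variable's observations, split into control and disease group.

    Both groups must hold at least two finite values (variance-based
    tests need two observations per group); missing values are rejected
    at construction.
    """

    ctrl: np.ndarray
    dis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ctrl", _as_group(self.ctrl, "control"))
        object.__setattr__(self, "dis", _as_group(self.dis, "disease"))

    @property
    def n_ctrl(self) -> int:
        return self.ctrl.size

    @property
    def n_dis(self) -> int:
        return self.dis.size

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.ctrl, self.dis])


@dataclass(frozen=True)
class MethodScore:
    """A per-variable statistic with its evidence orientation.

    ``evidence`` maps every method onto a common higher-is-better scale
    (p-values are negated), which is what rank-based AUC evaluation
    consumes.  ``warning`` is set when a degenerate input forced a
    documented fallback value (e.g. zero MAD), or when a method failed
    inside :func:`score_all`.
    """

    method: str
    value: float
    orientation: str
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER, LOWER):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def evidence(self) -> float:
        return self.value if self.orientation == HIGHER else -self.value


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exceedance-by-group table: rows (>cut, <=cut), columns (D, C)."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        for cell in (self.n11, self.n12, self.n21, self.n22):
            if int(cell) != cell or cell < 0:
                raise ValueError("table cells must be non-negative integers")

    @property
    def n_dis(self) -> int:
        return self.n11 + self.n21

    @property
    def n_ctrl(self) -> int:
        return self.n12 + self.n22


def fisher_cutpoint(dis, q_frac: float = 0.1) -> float:
    """Upper cutpoint of the disease group: at most a fraction ``q_frac``
    of the disease values lie strictly above it.

    Returns the m-th smallest disease value with ``m = n_D - floor(q_frac*n_D)``
    (equivalently ``ceil((1-q_frac)*n_D)``), i.e. an order statistic rather
    than an interpolated quantile, so "10 percent of the values are larger
    than the cutpoint" holds exactly for distinct values and ties can only
    shrink the exceedance set.
    """
    x = np.sort(np.asarray(dis, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empty disease group")
    if not 0.0 < q_frac < 1.0:
        raise ValueError("q_frac must lie in (0, 1)")
    # n - floor(q*n) == ceil((1-q)*n) but immune to e.g. ceil(0.9*10) -> 10
    m = x.size - int(math.floor(q_frac * x.size + 1e-12))
    m = min(max(m, 1), x.size)
    return float(x[m - 1])


def fisher_sum(
    v: TwoGroupVector,
    q_frac: float = 0.1,
    w_ctrl: float | None = None,
    w_dis: float | None = None,
    clamp: str = "terms",
) -> MethodScore:
    """FisherSum score for a disease-specific up-regulated subgroup.

    With ``cut = fisher_cutpoint(D, q_frac)`` and ``med_C = median(C)``::

        FS = w_D * sum_{x in D, x > cut} max(x - med_C, 0)
           - w_C * sum_{x in C, x > cut} max(x - med_C, 0)

    The subtraction penalises variables whose upper tail is inflated in
    *both* groups (non-disease-specific subgroups).  Default weights are
    ``w_D = 1/n_D`` and ``w_C = 1/n_C``, which keeps scores comparable
    across (unbalanced) designs.

    ``clamp`` selects where negative contributions are zeroed: ``"terms"``
    (default) clamps each median-centred summand, ``"score"`` instead
    clamps the final score at zero.  The score is invariant under adding
    a constant to all observations and scales linearly under positive
    rescaling.
    """
    if clamp not in ("terms", "score"):
        raise ValueError("clamp must be 'terms' or 'score'")
    cut = fisher_cutpoint(v.dis, q_frac)
    med_c = float(np.median(v.ctrl))
    w_d = 1.0 / v.n_dis if w_dis is None else float(w_dis)
    w_c = 1.0 / v.n_ctrl if w_ctrl is None else float(w_ctrl)
    dis_terms = v.dis[v.dis > cut] - med_c
    ctrl_terms = v.ctrl[v.ctrl > cut] - med_c
    if clamp == "terms":
        dis_terms = np.clip(dis_terms, 0.0, None)
        ctrl_terms = np.clip(ctrl_terms, 0.0, None)
    fs = w_d * float(dis_terms.sum()) - w_c * float(ctrl_terms.sum())
    if clamp == "score":
        fs = max(fs, 0.0)
    return MethodScore("fisher_sum", float(fs), HIGHER)


def exceedance_table(v: TwoGroupVector, q_frac: float = 0.1) -> ContingencyTable2x2:
    """2x2 table of cutpoint exceedances versus group membership."""
    cut = fisher_cutpoint(v.dis, q_frac)
    n11 = int(np.sum(v.dis > cut))
    n12 = int(np.sum(v.ctrl > cut))
    return ContingencyTable2x2(n11, n12, v.n_dis - n11, v.n_ctrl - n12)


def fisher_exact_upper_tail(table: ContingencyTable2x2) -> float:
    """One-sided Fisher's exact p-value for over-representation of
    exceedances in the disease column: the hypergeometric upper tail
    P(X >= n11) with population n_C + n_D, n_D "disease" items and
    n11 + n12 draws."""
    pop = table.n_ctrl + table.n_dis
    drawn = table.n11 + table.n12
    p = float(stats.hypergeom.sf(table.n11 - 1, pop, table.n_dis, drawn))
    return min(p, 1.0)


def fisher10_pvalue(v: TwoGroupVector, q_frac: float = 0.1) -> MethodScore:
    """One-sided Fisher's exact test on the exceedance table of the
    disease-group cutpoint (the "Fisher10" test for the default 90%
    cutpoint)."""
    p = fisher_exact_upper_tail(exceedance_table(v, q_frac))
    return MethodScore("fisher10", p, LOWER)


def outlier_sum(v: TwoGroupVector) -> MethodScore:
    """Outlier sum (OS): sum of robustly standardized disease values above
    q75 + IQR of the pooled standardized values.

    Standardization uses the pooled median and the pooled MAD scaled by
    1.4826 (normal-consistent, the R default); quantiles are type-7.
    A pooled MAD of zero yields score 0 with a warning instead of NaN so
    matrix-level scoring stays total.
    """
    pooled = v.pooled
    med = float(np.median(pooled))
    mad = float(stats.median_abs_deviation(pooled, scale="normal"))
    if mad == 0.0:
        logger.warning("outlier_sum: zero pooled MAD, degenerate variable")
        return MethodScore("outlier_sum", 0.0, HIGHER, warning="zero pooled MAD")
    z_pooled = (pooled - med) / mad
    z_dis = (v.dis - med) / mad
    q75, q25 = np.percentile(z_pooled, [75, 25])
    thresh = q75 + (q75 - q25)
    return MethodScore("outlier_sum", float(z_dis[z_dis > thresh].sum()), HIGHER)


def ort(v: TwoGroupVector) -> MethodScore:
    """Outlier-robust t-statistic (ORT).

    The outlier set ``O`` holds disease values above ``q75(C) + IQR(C)``
    — location and spread come from the control group only, so a planted
    subgroup in D cannot inflate its own threshold.  The statistic is::

        ORT = sum_{x in O} (x - med_C)
              / median(|x - med_D| over D  union  |x - med_C| over C)

    Returns 0 for an empty outlier set, and 0 with a warning when the
    denominator vanishes.
    """
    q75, q25 = np.percentile(v.ctrl, [75, 25])
    thresh = q75 + (q75 - q25)
    outliers = v.dis[v.dis > thresh]
    if outliers.size == 0:
        return MethodScore("ort", 0.0, HIGHER)
    med_c = float(np.median(v.ctrl))
    med_d = float(np.median(v.dis))
    denom = float(
        np.median(
            np.concatenate([np.abs(v.dis - med_d), np.abs(v.ctrl - med_c)])
        )
    )
    if denom == 0.0:
        logger.warning("ort: zero pooled absolute deviation, degenerate variable")
        return MethodScore("ort", 0.0, HIGHER, warning="zero pooled absolute deviation")
    return MethodScore("ort", float((outliers - med_c).sum()) / denom, HIGHER)


def padge_score(
    v: TwoGroupVector,
    percentiles: Sequence[float] = (80.0, 85.0, 90.0),
    ratio_floor: float = 0.1,
) -> MethodScore:
    """PADGE-like percentile score.

    For each percentile P the top subsets ``C_P = {x in C : x >= q_P(C)}``
    and ``D_P`` analogous are compared with a one-sided Student t-test
    (alternative: D_P up-regulated); p-values are Bonferroni-corrected for
    the number of percentiles and capped at 1.  Each percentile
    contributes ``(-log10 p~_P) * (r_P / max(r_0, ratio_floor))`` where
    ``r_P = mean(D_P) - mean(C_P)`` and ``r_0`` is the whole-group mean
    difference (a log-scale expression ratio).  Terms with ``r_P <= 0``,
    degenerate subsets (fewer than two members, or zero variance in both)
    contribute 0.
    """
    n_tests = len(percentiles)
    if n_tests == 0:
        raise ValueError("need at least one percentile")
    r0 = float(v.dis.mean() - v.ctrl.mean())
    denom = max(r0, ratio_floor)
    score = 0.0
    for pct in percentiles:
        c_sub = v.ctrl[v.ctrl >= np.percentile(v.ctrl, pct)]
        d_sub = v.dis[v.dis >= np.percentile(v.dis, pct)]
        if c_sub.size < 2 or d_sub.size < 2:
            continue
        r_p = float(d_sub.mean() - c_sub.mean())
        if r_p <= 0.0:
            continue
        if np.ptp(c_sub) == 0.0 and np.ptp(d_sub) == 0.0:
            continue
        p = stats.ttest_ind(d_sub, c_sub, equal_var=True, alternative="greater").pvalue
        if not np.isfinite(p):
            continue
        p_adj = min(1.0, float(p) * n_tests)
        score += -math.log10(p_adj) * (r_p / denom)
    return MethodScore("padge", score, HIGHER)


def excess_kurtosis(v: TwoGroupVector) -> MethodScore:
    """Excess kurtosis b2 - 3 of the pooled observations (plain moment
    estimator).  Small up-regulated subgroups inflate the fourth moment,
    so large positive values flag candidate variables."""
    pooled = v.pooled
    if pooled.size < 4:
        raise ValueError("kurtosis needs at least 4 pooled observations")
    if np.ptp(pooled) == 0.0:
        raise ValueError("kurtosis undefined for zero-variance variable")
    k = float(stats.kurtosis(pooled, fisher=True, bias=True))
    return MethodScore("kurtosis", k, HIGHER)


def bartlett_pvalue(v: TwoGroupVector) -> MethodScore:
    """Two-group Bartlett test for homoscedasticity (chi-square, 1 df).

    A subgroup in D inflates the disease-group variance, so a small
    p-value is evidence.  Degenerate cases: both variances zero -> p = 1
    with warning; exactly one zero variance -> p = 0 (the analytic limit)
    with warning.
    """
    var_c = float(v.ctrl.var(ddof=1))
    var_d = float(v.dis.var(ddof=1))
    if var_c == 0.0 and var_d == 0.0:
        logger.warning("bartlett: both group variances zero")
        return MethodScore("bartlett", 1.0, LOWER, warning="both variances zero")
    if var_c == 0.0 or var_d == 0.0:
        return MethodScore("bartlett", 0.0, LOWER, warning="zero variance in one group")
    p = float(stats.bartlett(v.ctrl, v.dis).pvalue)
    return MethodScore("bartlett", p, LOWER)


def t_test_onesided(v: TwoGroupVector) -> MethodScore:
    """One-sided pooled-variance Student t-test, alternative
    mean(D) > mean(C); df = n_C + n_D - 2."""
    pooled = v.pooled
    if np.ptp(pooled) == 0.0:
        raise ValueError("t-test undefined for zero pooled variance")
    p = float(
        stats.ttest_ind(v.dis, v.ctrl, equal_var=True, alternative="greater").pvalue
    )
    return MethodScore("t_test", p, LOWER)


def permutation_pvalue_fs(
    v: TwoGroupVector,
    n_perm: int = 999,
    seed: int = 0,
    q_frac: float = 0.1,
    **fs_kwargs,
) -> float:
    """Permutation p-value for the FisherSum score.

    Group labels are permuted with fixed group sizes; the add-one
    corrected p-value ``(1 + #{FS_perm >= FS_obs}) / (n_perm + 1)`` is
    always in (0, 1].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    observed = fisher_sum(v, q_frac=q_frac, **fs_kwargs).value
    pooled = v.pooled
    n_c = v.n_ctrl
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        fs = fisher_sum(
            TwoGroupVector(perm[:n_c], perm[n_c:]), q_frac=q_frac, **fs_kwargs
        ).value
        if fs >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


#: Deterministic method ordering used by score_all and the benchmark.
METHOD_ORDER: tuple[str, ...] = (
    "fisher_sum",
    "fisher10",
    "outlier_sum",
    "ort",
    "padge",
    "kurtosis",
    "bartlett",
    "t_test",
)

_METHODS: dict[str, tuple[Callable[[TwoGroupVector], MethodScore], str]] = {
    "fisher_sum": (fisher_sum, HIGHER),
    "fisher10": (fisher10_pvalue, LOWER),
    "outlier_sum": (outlier_sum, HIGHER),
    "ort": (ort, HIGHER),
    "padge": (padge_score, HIGHER),
    "kurtosis": (excess_kurtosis, HIGHER),
    "bartlett": (bartlett_pvalue, LOWER),
    "t_test": (t_test_onesided, LOWER),
}


def method_orientation(method: str) -> str:
    try:
        return _METHODS[method][1]
    except KeyError:
        raise KeyError(f"unknown method {method!r}") from None


def score_all(
    v: TwoGroupVector, methods: Iterable[str] | None = None
) -> list[MethodScore]:
    """Apply the requested methods to one variable, in deterministic order.

    A method that raises on a degenerate input is reported as a
    MethodScore with value NaN and a warning, never as a fatal error.
    """
    requested = set(METHOD_ORDER) if methods is None else set(methods)
    unknown = requested - set(_METHODS)
    if unknown:
        raise KeyError(f"unknown method(s): {sorted(unknown)}")
    out: list[MethodScore] = []
    for name in METHOD_ORDER:
        if name not in requested:
            continue
        func, orientation = _METHODS[name]
        try:
            out.append(func(v))
        except Exception as exc:  # noqa: BLE001 - per-method failure is data
            out.append(MethodScore(name, float("nan"), orientation, warning=str(exc)))
    return out
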