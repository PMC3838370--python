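"""Generative model of the simulation benchmark and the likelihood-ratio oracle.

Background observations follow the standard normal f0 = N(0, 1).  A
contaminated variable replaces a proportion ``p`` of a group with draws
from a scenario-specific subgroup distribution d_s:

* scenario I   — N(delta, 1), a pure mean shift (delta > 0);
* scenario II  — N(0, 1) + U[0, b], simultaneous mean and variance
  increase (b > 0), the convolution has the closed form
  (Phi(x) - Phi(x - b)) / b;
* scenario III — N(0, sigma^2), pure variance inflation (sigma > 1).

The disease-group density is the mixture f1 = (1 - p) f0 + p d_s.  With
all parameters known, the per-variable likelihood ratio between the
disease-specific pattern (C ~ f0, D ~ f1) and the composite null — a
q_b-weighted mixture of "no subgroups" (all f0) and "subgroups in both
groups" (all f1) — is the theoretically optimal detector and upper-bounds
every method in the benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

SCENARIOS = ("I", "II", "III")


@dataclass(frozen=True)
class ScenarioSpec:
    """Subgroup scenario: identifier, deviation parameter z, proportion p.

    ``z`` is delta for scenario I, b for scenario II and sigma for
    scenario III (z > 0 for I/II, z > 1 for III); ``p`` in (0, 1] is the
    subgroup proportion within a contaminated group.
    """

    scenario: str
    z: float
    p: float = 0.1

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.scenario in ("I", "II") and not self.z > 0:
            raise ValueError("scenarios I and II require z > 0")
        if self.scenario == "III" and not self.z > 1:
            raise ValueError("scenario III requires z > 1")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class NullMixSpec:
    """Composition of the composite null: proportion q_b of 'subgroups in
    both groups' variables among the nulls (q_b = 0 is the classical
    simple null)."""

    q_b: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_b <= 1.0:
            raise ValueError("q_b must lie in [0, 1]")


def f0_density(x) -> np.ndarray | float:
    """Standard normal background density."""
    return norm.pdf(x)


def f0_logpdf(x) -> np.ndarray | float:
    return norm.logpdf(x)


def _log_phi_diff(x: np.ndarray, b: float) -> np.ndarray:
    # log(Phi(x) - Phi(x-b)), stable in both tails: work with CDFs on the
    # left of b/2 and with survival functions on the right.
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    left = x <= b / 2.0
    la = log_ndtr(x[left])
    lb = log_ndtr(x[left] - b)
    out[left] = la + np.log1p(-np.exp(lb - la))
    right = ~left
    sa = log_ndtr(b - x[right])  # log sf(x - b)
    sb = log_ndtr(-x[right])  # log sf(x)
    out[right] = sa + np.log1p(-np.exp(sb - sa))
    return out


def subgroup_density(spec: ScenarioSpec, x) -> np.ndarray | float:
    """Density d_s of the subgroup distribution under ``spec``."""
    x = np.asarray(x, dtype=float)
    if spec.scenario == "I":
        return norm.pdf(x - spec.z)
    if spec.scenario == "II":
        return (ndtr(x) - ndtr(x - spec.z)) / spec.z
    return norm.pdf(x / spec.z) / spec.z


def subgroup_logpdf(spec: ScenarioSpec, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if spec.scenario == "I":
        return norm.logpdf(x - spec.z)
    if spec.scenario == "II":
        return _log_phi_diff(x, spec.z) - math.log(spec.z)
    return norm.logpdf(x, scale=spec.z)


def subgroup_rvs(spec: ScenarioSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` iid subgroup observations."""
    if spec.scenario == "I":
        return rng.normal(spec.z, 1.0, size)
    if spec.scenario == "II":
        return rng.normal(0.0, 1.0, size) + rng.uniform(0.0, spec.z, size)
    return rng.normal(0.0, spec.z, size)


def f1_density(spec: ScenarioSpec, x) -> np.ndarray | float:
    """Contaminated-group mixture density (1 - p) f0 + p d_s."""
    return (1.0 - spec.p) * f0_density(x) + spec.p * subgroup_density(spec, x)


def f1_logpdf(spec: ScenarioSpec, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if spec.p == 1.0:
        return subgroup_logpdf(spec, x)
    return np.logaddexp(
        math.log1p(-spec.p) + f0_logpdf(x),
        math.log(spec.p) + subgroup_logpdf(spec, x),
    )


def log_likelihood_ratio(
    ctrl,
    dis,
    spec: ScenarioSpec,
    null_mix: NullMixSpec = NullMixSpec(),
) -> float:
    """Log likelihood ratio of the disease-specific pattern versus the
    composite null, for one variable.

    log L1 = sum_C log f0 + sum_D log f1;  L0 = (1 - q_b) L0a + q_b L0b
    with L0a the all-f0 and L0b the all-f1 likelihood; the null mixture
    is combined by log-sum-exp.  Densities are strictly positive, so the
    result is always finite.
    """
    ctrl = np.asarray(ctrl, dtype=float).ravel()
    dis = np.asarray(dis, dtype=float).ravel()
    lf0_ctrl = float(np.sum(f0_logpdf(ctrl)))
    lf0_dis = float(np.sum(f0_logpdf(dis)))
    lf1_ctrl = float(np.sum(f1_logpdf(spec, ctrl)))
    lf1_dis = float(np.sum(f1_logpdf(spec, dis)))
    log_l1 = lf0_ctrl + lf1_dis
    log_l0a = lf0_ctrl + lf0_dis
    log_l0b = lf1_ctrl + lf1_dis
    q = null_mix.q_b
    if q == 0.0:
        log_l0 = log_l0a
    elif q == 1.0:
        log_l0 = log_l0b
    else:
        log_l0 = np.logaddexp(math.log1p(-q) + log_l0a, math.log(q) + log_l0b)
    return float(log_l1 - log_l0)


def log_likelihood_ratio_matrix(
    values,
    dis_cols,
    spec: ScenarioSpec,
    null_mix: NullMixSpec = NullMixSpec(),
) -> np.ndarray:
    """Vectorized per-row log LR for a variables-by-samples matrix.

    ``dis_cols`` is a boolean mask marking disease columns.
    """
    values = np.asarray(values, dtype=float)
    dis_cols = np.asarray(dis_cols, dtype=bool)
    lf0 = f0_logpdf(values)
    lf1 = f1_logpdf(spec, values)
    lf0_ctrl = lf0[:, ~dis_cols].sum(axis=1)
    lf0_dis = lf0[:, dis_cols].sum(axis=1)
    lf1_ctrl = lf1[:, ~dis_cols].sum(axis=1)
    lf1_dis = lf1[:, dis_cols].sum(axis=1)
    log_l1 = lf0_ctrl + lf1_dis
    log_l0a = lf0_ctrl + lf0_dis
    log_l0b = lf1_ctrl + lf1_dis
    q = null_mix.q_b
    if q == 0.0:
        log_l0 = log_l0a
    elif q == 1.0:
        log_l0 = log_l0b
    else:
        log_l0 = np.logaddexp(math.log1p(-q) + log_l0a, math.log(q) + log_l0b)
    return log_l1 - log_l0
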