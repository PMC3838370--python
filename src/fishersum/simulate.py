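"""Benchmark matrix simulator.

A benchmark matrix holds 1000 variables (rows) over two groups of n
samples each (columns: first n are controls ``C``, last n are disease
``D``).  Rows come in three patterns:

* ``H0a`` — no subgroup anywhere: all 2n observations iid N(0, 1);
* ``H0b`` — a non-disease-specific subgroup: k = round(p*n) observations
  in *each* group replaced by subgroup draws;
* ``H1``  — the pattern of interest: k subgroup observations in D only.

The default composition is 250 / 250 / 500 (a composite null with half
the null variables of type H0b), rows ordered H0a, H0b, then H1.  Each
row has its own counter-derived RNG substream, so a row's content
depends only on (seed, row index) and matrices are reproducible
bit-for-bit.  Planted members occupy the last k columns of their group;
all statistics in this package are permutation-invariant within groups,
so the fixed placement is observationally irrelevant but keeps masks
simple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densities import ScenarioSpec, subgroup_rvs

PATTERNS = ("H0a", "H0b", "H1")


def subgroup_size(p: float, n: int) -> int:
    """Planted subgroup size k = round(p * n)."""
    return int(round(p * n))


def benchmark_counts(q_b: float, n_null: int = 500, n_alt: int = 500) -> tuple[int, int, int]:
    """Pattern counts (H0a, H0b, H1) for a null mixture with proportion q_b
    of H0b among the nulls."""
    if not 0.0 <= q_b <= 1.0:
        raise ValueError("q_b must lie in [0, 1]")
    n_h0b = int(round(q_b * n_null))
    return (n_null - n_h0b, n_h0b, n_alt)


@dataclass(frozen=True)
class SimulationDesign:
    """Design of one benchmark matrix: per-group size n, scenario spec,
    pattern counts (H0a, H0b, H1) and the root seed."""

    n: int
    spec: ScenarioSpec
    counts: tuple[int, int, int] = (250, 250, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 samples per group")
        if len(self.counts) != 3 or any(c < 0 for c in self.counts):
            raise ValueError("counts must be three non-negative integers")
        if sum(self.counts) < 1:
            raise ValueError("design must contain at least one variable")
        if (self.counts[1] > 0 or self.counts[2] > 0) and self.k < 1:
            raise ValueError(
                f"subgroup size round(p*n) = {self.k} but subgroup patterns requested"
            )
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def k(self) -> int:
        return subgroup_size(self.spec.p, self.n)

    @property
    def n_vars(self) -> int:
        return sum(self.counts)


@dataclass
class SimulatedMatrix:
    """A simulated variables-by-samples matrix with ground truth."""

    values: np.ndarray
    group_labels: np.ndarray  # per-column "C"/"D"
    truth: np.ndarray  # per-row "H0a"/"H0b"/"H1"
    subgroup_mask: list[np.ndarray]  # per-row planted column indices
    design: SimulationDesign

    @property
    def dis_cols(self) -> np.ndarray:
        return self.group_labels == "D"

    @property
    def truth01(self) -> np.ndarray:
        """Binary response: 1 for H1 rows, 0 for either null pattern."""
        return (self.truth == "H1").astype(int)

    @property
    def var_ids(self) -> list[str]:
        return [f"v{i + 1:04d}" for i in range(self.values.shape[0])]


def draw_variable(
    pattern: str,
    spec: ScenarioSpec,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one row (2n values, controls first) and its planted-column mask."""
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}")
    row = rng.standard_normal(2 * n)
    positions: list[int] = []
    if pattern != "H0a":
        k = subgroup_size(spec.p, n)
        if k < 1:
            raise ValueError("round(p*n) must be >= 1 for subgroup patterns")
        if pattern == "H0b":
            positions.extend(range(n - k, n))
        positions.extend(range(2 * n - k, 2 * n))
        row[positions] = subgroup_rvs(spec, len(positions), rng)
    return row, np.asarray(positions, dtype=int)


def build_matrix(design: SimulationDesign) -> SimulatedMatrix:
    """Build the full benchmark matrix for ``design``.

    Deterministic for a fixed seed; row i is generated from the substream
    SeedSequence((seed, i)) independently of every other row.
    """
    n = design.n
    patterns = np.repeat(PATTERNS, design.counts)
    values = np.empty((design.n_vars, 2 * n))
    masks: list[np.ndarray] = []
    for i, pattern in enumerate(patterns):
        rng = np.random.default_rng(np.random.SeedSequence((design.seed, i)))
        values[i], mask = draw_variable(pattern, design.spec, n, rng)
        masks.append(mask)
    labels = np.asarray(["C"] * n + ["D"] * n)
    return SimulatedMatrix(values, labels, patterns.copy(), masks, design)
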