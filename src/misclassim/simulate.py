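"""Three-group single-predictor data with systematic, boundary-proximal label noise.

The generator draws a continuous score for each case from one of three ordered
normal populations (groups 1 < 2 < 3, means ``0, d, 2d``, unit variance) and
then corrupts the group labels the way artificial cut-scores do: the closer a
case sits to a cut-point between adjacent groups, the more likely its observed
label is wrong.  The corruption rate is calibrated exactly: each flip-eligible
case is mislabeled with probability ``pi``.

Mechanics
---------
For an eligible case with score ``x`` in group ``g`` a *boundary position*
``p`` is computed from the within-group normal CDF, oriented toward the
boundary across which the group may be confused (doubled-min construction for
the middle group).  By the probability integral transform ``p`` is Uniform(0,1)
within each group, and small exactly for boundary-proximal cases.  The case is
flipped when an independent Uniform(0,1) draw exceeds ``k * p`` where
``k = 1/(2*pi)``, which makes the marginal flip probability equal ``pi``
(``k = 1`` yields 50%).  Flipped cases move to the adjacent group on the
boundary side, so the disallowed extreme confusion (1 <-> 3) never occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

GROUPS = (1, 2, 3)

__all__ = [
    "GROUPS",
    "Topology",
    "SimCondition",
    "LabeledDataset",
    "CalibrationScalar",
    "assign_groups",
    "generate_predictor",
    "boundary_position",
    "calibrate_scalar",
    "inject_misclassification",
    "simulate_condition",
]


@dataclass(frozen=True)
class Topology:
    """Which group confusions the mislabeling process may produce.

    ``BC`` confuses only the two upper groups (2 <-> 3); ``AB_BC`` confuses
    adjacent groups (1 <-> 2 and 2 <-> 3).  The extreme pair {1, 3} is never
    allowed.  In ``strict`` mode a group with no allowed confusion (group 1
    under BC) is never flipped; in ``uniform`` mode every case is eligible and
    a flip moves the case to its nearest adjacent group.
    """

    name: str
    allowed_confusions: frozenset[frozenset[int]]
    eligibility_mode: str = "strict"

    def __post_init__(self) -> None:
        if self.eligibility_mode not in ("strict", "uniform"):
            raise ValueError(f"unknown eligibility_mode {self.eligibility_mode!r}")
        if frozenset({1, 3}) in self.allowed_confusions:
            raise ValueError("confusion between the two extreme groups is never allowed")

    @classmethod
    def bc(cls, eligibility_mode: str = "strict") -> "Topology":
        return cls("BC", frozenset({frozenset({2, 3})}), eligibility_mode)

    @classmethod
    def ab_bc(cls, eligibility_mode: str = "strict") -> "Topology":
        return cls("AB_BC", frozenset({frozenset({1, 2}), frozenset({2, 3})}),
                   eligibility_mode)

    @classmethod
    def from_name(cls, name: str, eligibility_mode: str = "strict") -> "Topology":
        key = name.upper().replace("/", "_").replace("-", "_")
        if key == "BC":
            return cls.bc(eligibility_mode)
        if key in ("AB_BC", "ABBC"):
            return cls.ab_bc(eligibility_mode)
        raise ValueError(f"unknown topology {name!r}")

    def confusion_directions(self, g: int) -> tuple[bool, bool]:
        """(below, above): whether group ``g`` may be confused downward/upward."""
        below = frozenset({g - 1, g}) in self.allowed_confusions
        above = frozenset({g, g + 1}) in self.allowed_confusions
        if not (below or above) and self.eligibility_mode == "uniform":
            # nearest adjacent group: group 1 flips up, group 3 flips down
            below, above = (g == 3), (g == 1)
        return below, above

    def eligible(self, g: int) -> bool:
        return any(self.confusion_directions(g))


@dataclass(frozen=True)
class SimCondition:
    """One cell of the crossed design, plus its RNG seed."""

    topology: Topology
    n_total: int
    ratio: tuple[int, int, int]
    separation_d: float
    pi: float
    seed: object = 0

    def __post_init__(self) -> None:
        if self.separation_d <= 0:
            raise ValueError("separation_d must be positive")
        if not 0 <= self.pi <= 0.5:
            raise ValueError("pi must be in [0, 0.5]")


@dataclass
class LabeledDataset:
    """Predictor scores with parallel true and observed group labels."""

    x: np.ndarray
    true_label: np.ndarray
    observed_label: np.ndarray | None
    group_means: tuple[float, float, float]
    cutpoints: tuple[float, float]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.true_label = np.asarray(self.true_label, dtype=np.int64)
        if self.observed_label is not None:
            self.observed_label = np.asarray(self.observed_label, dtype=np.int64)
            if len(self.observed_label) != len(self.x):
                raise ValueError("observed_label length mismatch")
        if len(self.true_label) != len(self.x):
            raise ValueError("true_label length mismatch")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "case_id": np.arange(len(self)),
            "x": self.x,
            "true_group": self.true_label,
            "observed_group": (self.true_label if self.observed_label is None
                               else self.observed_label),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, group_means=(np.nan, np.nan, np.nan),
                 cutpoints=(np.nan, np.nan)) -> "LabeledDataset":
        df = pd.read_csv(path)
        return cls(df["x"].to_numpy(), df["true_group"].to_numpy(),
                   df["observed_group"].to_numpy(), tuple(group_means),
                   tuple(cutpoints))


@dataclass(frozen=True)
class CalibrationScalar:
    """Multiplier ``k`` applied to the boundary position before the flip test."""

    k: float
    target_pi: float


def assign_groups(n_total: int, ratio: Sequence[int], rng: np.random.Generator
                  ) -> np.ndarray:
    """Randomly ordered label vector with counts proportional to ``ratio``."""
    ratio = tuple(ratio)
    if len(ratio) != 3:
        raise ValueError("ratio must have three entries")
    total = sum(ratio)
    counts = [n_total * r / total for r in ratio]
    if any(abs(c - round(c)) > 1e-9 for c in counts):
        raise ValueError(f"ratio {ratio} does not scale to integers at n={n_total}")
    labels = np.repeat(GROUPS, [int(round(c)) for c in counts])
    return rng.permutation(labels)


def generate_predictor(labels: np.ndarray, d: float, rng: np.random.Generator
                       ) -> LabeledDataset:
    """Draw scores from N(mu_g, 1) with means (0, d, 2d); cutpoints at midpoints."""
    if d <= 0:
        raise ValueError("separation d must be positive")
    labels = np.asarray(labels, dtype=np.int64)
    means = (0.0, d, 2.0 * d)
    x = rng.normal(np.asarray(means)[labels - 1], 1.0)
    return LabeledDataset(x, labels, None, means, (d / 2.0, 3.0 * d / 2.0))


def boundary_position(x, g, topology: Topology, means: Sequence[float]):
    """Scaled within-group cumulative position of each case, small near the
    boundary it may be confused across; Uniform(0,1) within each eligible group.

    Ineligible cases (strict mode) get NaN.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=np.int64)
    scalar_input = x.ndim == 0
    x, g = np.atleast_1d(x), np.atleast_1d(g)
    means = np.asarray(means, dtype=float)
    F = norm.cdf(x - means[g - 1])
    p = np.full_like(F, np.nan)
    for grp in GROUPS:
        below, above = topology.confusion_directions(grp)
        m = g == grp
        if below and above:
            p[m] = 2.0 * np.minimum(F[m], 1.0 - F[m])
        elif above:
            p[m] = 1.0 - F[m]
        elif below:
            p[m] = F[m]
    return float(p[0]) if scalar_input else p


def calibrate_scalar(target_pi: float) -> CalibrationScalar:
    """Scalar ``k`` with ``P(U > k*P) = target_pi`` for U, P ~ Uniform(0,1).

    Closed form ``k = 1/(2*pi)`` for ``0 < pi <= 0.5`` (so ``k = 1`` gives 50%).
    ``pi = 0`` returns the no-injection sentinel ``k = inf``.
    """
    if target_pi < 0 or target_pi > 0.5:
        raise ValueError("target_pi must be in [0, 0.5]")
    if target_pi == 0:
        return CalibrationScalar(math.inf, 0.0)
    return CalibrationScalar(1.0 / (2.0 * target_pi), target_pi)


def _flip_destination(x, g, topology: Topology, means) -> np.ndarray:
    """Adjacent group a flipped case moves to: the one it is next most likely in."""
    g = np.asarray(g)
    x = np.asarray(x, dtype=float)
    dest = np.array(g, copy=True)
    mu_b = means[1]
    for grp in GROUPS:
        below, above = topology.confusion_directions(grp)
        m = g == grp
        if below and above:  # middle group: side of own mean decides
            dest[m] = np.where(x[m] < mu_b, grp - 1, grp + 1)
        elif above:
            dest[m] = grp + 1
        elif below:
            dest[m] = grp - 1
    return dest


def inject_misclassification(ds: LabeledDataset, topology: Topology, pi: float,
                             rng: np.random.Generator) -> LabeledDataset:
    """Fill ``observed_label`` by flipping eligible cases at calibrated rate ``pi``.

    Each case draws u ~ Uniform(0,1) (one draw per case, eligible or not, so
    the stream advances identically across topologies); an eligible case flips
    iff ``u > k * p`` with ``p`` its boundary position and ``k = 1/(2*pi)``.
    """
    u = rng.uniform(size=len(ds))
    observed = ds.true_label.copy()
    if pi > 0:
        cal = calibrate_scalar(pi)
        p = boundary_position(ds.x, ds.true_label, topology, ds.group_means)
        eligible = ~np.isnan(p)
        flip = eligible & (u > cal.k * np.where(np.isnan(p), np.inf, p))
        dest = _flip_destination(ds.x, ds.true_label, topology, ds.group_means)
        observed[flip] = dest[flip]
    return replace(ds, observed_label=observed)


def simulate_condition(cond: SimCondition) -> LabeledDataset:
    """Generate one dataset for a design cell; deterministic given ``cond.seed``."""
    rng = np.random.default_rng(cond.seed)
    labels = assign_groups(cond.n_total, cond.ratio, rng)
    ds = generate_predictor(labels, cond.separation_d, rng)
    return inject_misclassification(ds, cond.topology, cond.pi, rng)
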