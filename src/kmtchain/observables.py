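"""Derived observables: class-probability curves, kMT-number densities,
multi-chromosome synchrony and its half-life.

A cell contains ``k`` chromosome pairs, each an independent copy of the
attachment chain.  Synchrony is the event that all ``k`` pairs are
simultaneously amphitelic; if ``theta_t`` is the single-pair amphitelic
probability at step ``t``, the synchrony probability is ``theta_t ** k``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .chain_model import (
    AttachmentClass,
    ModelParams,
    StateSpace,
    TransitionKernel,
    build_kernel,
)
from .exact_analysis import (
    AnalysisError,
    StationaryDistribution,
    Trajectory,
    stationary_distribution,
)

__all__ = [
    "ClassProbabilityCurve",
    "KmtDensity",
    "SynchronyCurve",
    "class_probabilities",
    "kmt_density",
    "mean_kmt",
    "synchrony_curve",
    "steady_state_synchrony",
    "synchrony_half_life",
]

ALL_CLASSES = frozenset(AttachmentClass)


@dataclasses.dataclass
class ClassProbabilityCurve:
    """Per-step probability of each of the five attachment classes."""

    times: np.ndarray
    prob_by_class: np.ndarray  # shape (T+1, 5); column c-1 = class c

    def probability(self, cls: AttachmentClass | int) -> np.ndarray:
        return self.prob_by_class[:, int(cls) - 1]


@dataclasses.dataclass
class KmtDensity:
    """Joint distribution of total kMT counts per kinetochore.

    ``density[m1, m2]`` is the probability mass on configurations with
    ``i1 + j1 = m1`` and ``i2 + j2 = m2`` whose class lies in
    ``class_filter``.  Left unnormalised: the table sums to the total
    probability of the selected classes (``total_mass``).
    """

    time: int | None
    density: np.ndarray  # (n+1, n+1)
    class_filter: frozenset
    total_mass: float

    def normalized(self) -> np.ndarray:
        if self.total_mass <= 0:
            raise AnalysisError("cannot normalise a zero-mass density")
        return self.density / self.total_mass


@dataclasses.dataclass
class SynchronyCurve:
    """Probability that all ``k`` chromosome pairs are amphitelic."""

    times: np.ndarray
    theta: np.ndarray      # single-pair amphitelic probability
    k: int
    synchrony: np.ndarray  # theta ** k


def class_probabilities(
    trajectory: Trajectory, space: StateSpace | None = None
) -> ClassProbabilityCurve:
    """Aggregate a state-space trajectory into the five class curves."""
    space = space or trajectory.space
    cols = np.stack(
        [
            trajectory.distributions[:, space.indices_of_class(c)].sum(axis=1)
            for c in range(1, 6)
        ],
        axis=1,
    )
    return ClassProbabilityCurve(times=trajectory.times.copy(), prob_by_class=cols)


def _as_class_set(class_filter: Iterable[AttachmentClass | int]) -> frozenset:
    out = frozenset(AttachmentClass(int(c)) for c in class_filter)
    if not out:
        raise AnalysisError("class_filter must name at least one class")
    return out


def kmt_density(
    distribution: np.ndarray,
    space: StateSpace,
    class_filter: Iterable[AttachmentClass | int] = ALL_CLASSES,
    time: int | None = None,
) -> KmtDensity:
    """Accumulate state probabilities on the (i1+j1, i2+j2) grid.

    Only states whose class lies in ``class_filter`` contribute, so the
    table is an unnormalised decomposition: summing the tables for a class
    subset and its complement reproduces the full density cellwise.
    """
    cf = _as_class_set(class_filter)
    distribution = np.asarray(distribution, dtype=float)
    if distribution.shape != (len(space),):
        raise AnalysisError("distribution does not match the state space")
    sel = np.isin(space.class_of, [int(c) for c in cf])
    m1 = space.counts[:, 0] + space.counts[:, 1]
    m2 = space.counts[:, 2] + space.counts[:, 3]
    n = space.n
    density = np.zeros((n + 1, n + 1))
    np.add.at(density, (m1[sel], m2[sel]), distribution[sel])
    return KmtDensity(
        time=time,
        density=density,
        class_filter=cf,
        total_mass=float(distribution[sel].sum()),
    )


def mean_kmt(
    distribution: np.ndarray,
    space: StateSpace,
    class_filter: Iterable[AttachmentClass | int] = ALL_CLASSES,
) -> dict:
    """Conditional mean and sd of the per-kinetochore kMT count.

    Conditions on the class filter; by kinetochore-exchange symmetry the
    two kinetochores give the same answer for symmetric distributions, and
    the returned values average the two (they are asserted to agree for
    exchange-symmetric inputs upstream in the test-suite, not here).
    """
    cf = _as_class_set(class_filter)
    distribution = np.asarray(distribution, dtype=float)
    sel = np.isin(space.class_of, [int(c) for c in cf])
    mass = distribution[sel].sum()
    if mass <= 0:
        raise AnalysisError("zero probability mass in the selected classes")
    w = distribution[sel] / mass
    m1 = (space.counts[sel, 0] + space.counts[sel, 1]).astype(float)
    m2 = (space.counts[sel, 2] + space.counts[sel, 3]).astype(float)
    means = np.array([w @ m1, w @ m2])
    variances = np.array([w @ m1**2, w @ m2**2]) - means**2
    sds = np.sqrt(np.clip(variances, 0.0, None))
    return {
        "mean": float(means.mean()),
        "sd": float(sds.mean()),
        "mean_by_kinetochore": (float(means[0]), float(means[1])),
        "mass": float(mass),
    }


def synchrony_curve(
    theta: Sequence[float] | np.ndarray,
    k: int,
    times: np.ndarray | None = None,
) -> SynchronyCurve:
    """Raise the single-pair amphitelic curve to the ``k`` independent pairs."""
    if k < 1:
        raise AnalysisError(f"chromosome count k must be >= 1, got {k}")
    theta = np.asarray(theta, dtype=float)
    if theta.min() < -1e-12 or theta.max() > 1 + 1e-12:
        raise AnalysisError("theta values must lie in [0, 1]")
    theta = np.clip(theta, 0.0, 1.0)
    if times is None:
        times = np.arange(len(theta))
    return SynchronyCurve(
        times=np.asarray(times), theta=theta, k=int(k), synchrony=theta ** int(k)
    )


def steady_state_synchrony(
    params: ModelParams,
    k: int,
    kernel: TransitionKernel | None = None,
) -> float:
    """Long-run probability that all ``k`` pairs are amphitelic at once.

    For ``beta > 0`` (ergodic regime) this is the stationary amphitelic
    probability to the ``k``-th power.  For ``beta = 0`` every chain is
    eventually trapped in the amphitelic class, so the limit is 1
    regardless of ``alpha`` and ``k``.
    """
    if k < 1:
        raise AnalysisError(f"chromosome count k must be >= 1, got {k}")
    if params.beta == 0.0:
        return 1.0
    if kernel is None:
        kernel = build_kernel(params)
    pi = stationary_distribution(kernel)
    return float(pi.class_probability(AttachmentClass.AMPHITELIC) ** k)


def synchrony_half_life(
    params: ModelParams,
    k: int,
    kernel: TransitionKernel | None = None,
    max_steps: int = 1_000_000,
) -> float:
    """Half-life of an established synchrony, in steps.

    Starts each of the ``k`` chains from the stationary distribution
    conditioned on the amphitelic class and measures the survival
    probability of remaining continuously amphitelic, using the
    substochastic restriction of the kernel to amphitelic states.  Returns
    the (linearly interpolated) duration at which the joint survival
    drops to 1/2.  With ``alpha = beta = 0`` the amphitelic class cannot
    be exited and the half-life is infinite.
    """
    if k < 1:
        raise AnalysisError(f"chromosome count k must be >= 1, got {k}")
    if params.beta == 0.0:
        # the t -> infinity law concentrates on the fully occupied
        # amphitelic states, which can be exited neither by detachment
        # (beta = 0) nor by attachment (capacity-blocked)
        return math.inf
    if kernel is None:
        kernel = build_kernel(params)
    space = kernel.space
    amph = space.indices_of_class(AttachmentClass.AMPHITELIC)
    pi = stationary_distribution(kernel)
    mass = pi.probabilities[amph].sum()
    if mass <= 0:
        raise AnalysisError("stationary amphitelic probability is zero")
    v = pi.probabilities[amph] / mass
    K55 = kernel.matrix[amph][:, amph].tocsr()
    target = 0.5 ** (1.0 / k)  # per-chain survival at the joint half-life
    prev_s, prev_t = 1.0, 0
    for t in range(1, max_steps + 1):
        v = v @ K55
        s = float(v.sum())
        if s <= target:
            # linear interpolation on the joint survival probability
            joint_prev, joint = prev_s**k, s**k
            return prev_t + (joint_prev - 0.5) / (joint_prev - joint)
        prev_s, prev_t = s, t
    raise AnalysisError(
        f"synchrony survival did not reach 1/2 within {max_steps} steps"
    )
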