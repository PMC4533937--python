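"""Exact linear-algebra analyses of the attachment/detachment chain.

All quantities here are computed from the sparse one-step kernel by direct
linear solves -- transient propagation, mean first passage times via the
absorbing-chain fundamental matrix, stationary distributions from the
balance equations, and expected transition counts before absorption.
Stochastic simulation lives in :mod:`kmtchain.montecarlo` and serves only
as a cross-check.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu, spsolve

from .chain_model import (
    AttachmentClass,
    AttachmentState,
    ModelParams,
    StateSpace,
    TransitionKernel,
    build_kernel,
)

__all__ = [
    "Trajectory",
    "StationaryDistribution",
    "FirstPassageResult",
    "AbsorptionStatistics",
    "point_mass",
    "propagate",
    "first_passage_times",
    "mean_first_passage_time",
    "stationary_distribution",
    "absorption_statistics",
    "biorientation_attempts",
]

_ROWSUM_TOL = 1e-10


class AnalysisError(RuntimeError):
    """The requested quantity is undefined for this kernel."""


@dataclasses.dataclass
class Trajectory:
    """Time-indexed probability distributions over the state space."""

    times: np.ndarray          # shape (T+1,)
    distributions: np.ndarray  # shape (T+1, S)
    space: StateSpace

    def __post_init__(self) -> None:
        sums = self.distributions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _ROWSUM_TOL):
            raise AnalysisError("trajectory distribution does not sum to 1")

    @property
    def horizon(self) -> int:
        return int(self.times[-1])


@dataclasses.dataclass
class StationaryDistribution:
    probabilities: np.ndarray
    is_unique: bool
    space: StateSpace

    def class_probability(self, cls: AttachmentClass | int) -> float:
        return float(self.probabilities[self.space.indices_of_class(cls)].sum())

    def class_probabilities(self) -> np.ndarray:
        """Stationary mass of classes 1..5 (index 0 = class 1)."""
        return np.array([self.class_probability(c) for c in range(1, 6)])


@dataclasses.dataclass
class FirstPassageResult:
    """Expected steps to first reach ``target_class`` from every state."""

    mfpt_by_start_state: np.ndarray  # shape (S,), 0 on target states
    target_class: AttachmentClass
    space: StateSpace

    def __getitem__(self, state: AttachmentState) -> float:
        return float(self.mfpt_by_start_state[self.space.index(state)])


@dataclasses.dataclass
class AbsorptionStatistics:
    """Absorbing-chain statistics from one start state.

    ``expected_visits[u]`` is the expected number of visits to transient
    state ``u`` before absorption (0 on absorbing states);
    ``hit_probability[a]`` the probability of being absorbed in ``a``
    (0 on transient states).
    """

    start: AttachmentState
    absorbing_indices: np.ndarray
    expected_visits: np.ndarray   # shape (S,)
    hit_probability: np.ndarray   # shape (S,)
    space: StateSpace


def point_mass(space: StateSpace, state: AttachmentState) -> np.ndarray:
    """Probability vector concentrated on ``state``."""
    v = np.zeros(len(space))
    v[space.index(AttachmentState(*state).validate(space.n))] = 1.0
    return v


def propagate(
    kernel: TransitionKernel, init: np.ndarray, T: int
) -> Trajectory:
    """Evolve ``init`` for ``T`` steps by repeated vector-kernel products."""
    init = np.asarray(init, dtype=float)
    if init.shape != (kernel.n_states,):
        raise AnalysisError(
            f"initial vector has shape {init.shape}, expected ({kernel.n_states},)"
        )
    if abs(init.sum() - 1.0) > _ROWSUM_TOL or init.min() < 0:
        raise AnalysisError("initial vector is not a probability distribution")
    if T < 0:
        raise AnalysisError("horizon T must be >= 0")
    out = np.empty((T + 1, kernel.n_states))
    out[0] = init
    v = init
    K = kernel.matrix
    for t in range(1, T + 1):
        v = v @ K
        out[t] = v
    return Trajectory(times=np.arange(T + 1), distributions=out, space=kernel.space)


def _transient_solve(kernel: TransitionKernel, target_mask: np.ndarray):
    """(I - Q) factorisation on the complement of ``target_mask``."""
    transient = np.flatnonzero(~target_mask)
    Q = kernel.matrix[transient][:, transient]
    A = (sparse.identity(len(transient), format="csc") - Q.tocsc())
    return transient, A


def first_passage_times(
    kernel: TransitionKernel, target_class: AttachmentClass | int
) -> FirstPassageResult:
    """Mean first passage time to ``target_class`` from every state.

    All states of the target class are made absorbing and the expected
    absorption times solve ``(I - Q) t = 1`` on the transient block.
    """
    target_class = AttachmentClass(int(target_class))
    mask = kernel.space.class_of == int(target_class)
    if not mask.any():
        raise AnalysisError(f"no state belongs to class {target_class}")
    transient, A = _transient_solve(kernel, mask)
    try:
        with warnings.catch_warnings():
            # singularity is detected below via the finiteness check
            warnings.simplefilter("ignore", sparse.linalg.MatrixRankWarning)
            t = spsolve(A, np.ones(len(transient)))
    except RuntimeError as exc:  # singular factorisation
        raise AnalysisError(
            f"class {target_class} unreachable from part of the chain"
        ) from exc
    if not np.all(np.isfinite(t)) or t.min() < -1e-9:
        raise AnalysisError(
            f"class {target_class} unreachable from part of the chain "
            "(singular first-passage system)"
        )
    full = np.zeros(kernel.n_states)
    full[transient] = t
    return FirstPassageResult(
        mfpt_by_start_state=full, target_class=target_class, space=kernel.space
    )


def mean_first_passage_time(
    kernel: TransitionKernel,
    target_class: AttachmentClass | int,
    start: AttachmentState,
) -> float:
    """Expected number of steps to first hit ``target_class`` from ``start``."""
    return first_passage_times(kernel, target_class)[AttachmentState(*start)]


def _closed_recurrent_classes(kernel: TransitionKernel) -> list[np.ndarray]:
    """Strongly connected components with no outgoing edges."""
    ncomp, labels = csgraph.connected_components(
        kernel.matrix, directed=True, connection="strong"
    )
    coo = kernel.matrix.tocoo()
    has_exit = np.zeros(ncomp, dtype=bool)
    cross = labels[coo.row] != labels[coo.col]
    has_exit[np.unique(labels[coo.row[cross]])] = True
    return [np.flatnonzero(labels == c) for c in range(ncomp) if not has_exit[c]]


def stationary_distribution(kernel: TransitionKernel) -> StationaryDistribution:
    """Unique stationary distribution ``pi`` with ``pi K = pi``.

    Solves the balance equations with one equation replaced by the
    normalisation constraint.  Refuses kernels with more than one closed
    recurrent class (for example ``alpha = beta = 0``, where the fully
    occupied amphitelic states are separate absorbing states): their
    long-run behaviour depends on the start state, so use
    :func:`absorption_statistics` instead.
    """
    closed = _closed_recurrent_classes(kernel)
    if len(closed) != 1:
        raise AnalysisError(
            f"kernel has {len(closed)} closed recurrent classes; the "
            "stationary distribution is not unique -- use absorption analysis"
        )
    S = kernel.n_states
    A = (kernel.matrix.T - sparse.identity(S, format="csr")).tocsr()
    A = sparse.vstack(
        [A[:-1], sparse.csr_matrix(np.ones((1, S)))], format="csc"
    )
    b = np.zeros(S)
    b[-1] = 1.0
    pi = spsolve(A, b)
    if not np.all(np.isfinite(pi)):
        raise AnalysisError("singular balance system: stationary solve failed")
    if np.any(pi < -1e-12):
        raise AnalysisError(
            f"stationary solve produced negative mass (min {pi.min():.3e})"
        )
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(pi @ kernel.matrix - pi).max()
    if resid > 1e-10:
        raise AnalysisError(f"stationary residual {resid:.3e} exceeds 1e-10")
    return StationaryDistribution(probabilities=pi, is_unique=True, space=kernel.space)


def absorption_statistics(
    kernel: TransitionKernel, start: AttachmentState
) -> AbsorptionStatistics:
    """Expected visit counts and absorption probabilities from ``start``.

    Requires at least one absorbing state; expected visits are the start
    row of the fundamental matrix ``N = (I - Q)^{-1}`` and the absorption
    probabilities are ``N R`` over the absorbing columns.
    """
    start = AttachmentState(*start).validate(kernel.space.n)
    absorbing = kernel.absorbing_indices()
    if len(absorbing) == 0:
        raise AnalysisError("kernel has no absorbing state")
    mask = np.zeros(kernel.n_states, dtype=bool)
    mask[absorbing] = True
    start_idx = kernel.space.index(start)
    visits = np.zeros(kernel.n_states)
    hit = np.zeros(kernel.n_states)
    if mask[start_idx]:
        hit[start_idx] = 1.0
        return AbsorptionStatistics(start, absorbing, visits, hit, kernel.space)
    transient, A = _transient_solve(kernel, mask)
    e = np.zeros(len(transient))
    e[np.flatnonzero(transient == start_idx)[0]] = 1.0
    # visits from start = e_start @ (I - Q)^{-1}  <=>  (I - Q)^T x = e_start
    x = spsolve(A.T.tocsc(), e)
    if not np.all(np.isfinite(x)):
        raise AnalysisError("absorption from start is not certain")
    visits[transient] = x
    R = kernel.matrix[transient][:, absorbing]
    h = x @ R
    if abs(h.sum() - 1.0) > 1e-10:
        raise AnalysisError(
            f"absorption probabilities sum to {h.sum():.12f}, not 1"
        )
    hit[absorbing] = h
    return AbsorptionStatistics(start, absorbing, visits, hit, kernel.space)


def biorientation_attempts(
    params: ModelParams,
    start: AttachmentState = AttachmentState(0, 0, 0, 0),
    kernel: TransitionKernel | None = None,
) -> float:
    """Expected entries into the amphitelic class before full occupancy.

    Counts the expected number of traversals of monotelic/merotelic ->
    amphitelic transitions before the chain is absorbed at the fully
    occupied amphitelic states (``beta = 0`` regime, where those are the
    only absorbing states).  Each such traversal is one bi-orientation
    attempt; with ``alpha = 0`` the amphitelic class is never exited and
    the count is exactly 1.
    """
    if params.beta != 0.0:
        raise AnalysisError(
            "bi-orientation attempts are defined for beta = 0 (absorbing chain)"
        )
    if kernel is None:
        kernel = build_kernel(params)
    stats = absorption_statistics(kernel, start)
    cls = kernel.space.class_of
    sources = np.flatnonzero(
        np.isin(cls, (AttachmentClass.MONOTELIC, AttachmentClass.MEROTELIC))
    )
    into5 = kernel.matrix[sources][:, cls == AttachmentClass.AMPHITELIC]
    per_source = np.asarray(into5.sum(axis=1)).ravel()
    return float(stats.expected_visits[sources] @ per_source)
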