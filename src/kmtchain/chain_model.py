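"""State space, attachment-class taxonomy and one-step transition kernel.

The model tracks a pair of kinetochores (on sister chromatids in mitosis,
or on a bivalent in meiosis I) interacting with microtubules emanating from
the left (L) and right (R) spindle poles.  A configuration is the 4-tuple of
kinetochore-microtubule (kMT) counts

    r_n(i1, j1, i2, j2)

where ``i_m``/``j_m`` count L-pole/R-pole kMTs on kinetochore ``m`` and each
kinetochore accommodates at most ``n`` kMTs.  One discrete time step performs
at most one elementary event: a single attachment or a single detachment on
one kinetochore from one pole.  Base event probabilities are

* attach on kinetochore m (either pole):  ``p * (n - i_m - j_m) / n``
  (association is proportional to the free binding surface),
* detach one L kMT on kinetochore m:      ``i_m * q``  (R: ``j_m * q``),

and class-dependent factors ``alpha``, ``beta``, ``gamma`` in [0, 1] rescale
transitions that biology disfavours (see :func:`scaling_factor`).  Residual
probability stays on the diagonal, so every row of the kernel is stochastic
by construction; the admissible parameter ranges ``p <= 1/4``,
``q <= 1/(2n)`` guarantee a non-negative diagonal.
"""

from __future__ import annotations

import dataclasses
from enum import IntEnum
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "AttachmentClass",
    "AttachmentState",
    "ModelParams",
    "StateSpace",
    "TransitionKernel",
    "Event",
    "EVENT_ORDER",
    "enumerate_states",
    "classify",
    "classify_counts",
    "event_probability",
    "apply_event",
    "scaling_factor",
    "build_kernel",
]


class ParameterError(ValueError):
    """A model parameter violates its admissible range."""


class AttachmentClass(IntEnum):
    """The five-way taxonomy of attachment configurations.

    FREE        no kMT on either kinetochore.
    MONOTELIC   exactly one kinetochore attached, to a single pole.
    SYNTELIC    both kinetochores attached, both to the same pole.
    MEROTELIC   at least one kinetochore attached to both poles at once.
    AMPHITELIC  the two kinetochores attached exclusively to opposite
                poles -- the correct, bi-oriented configuration.
    """

    FREE = 1
    MONOTELIC = 2
    SYNTELIC = 3
    MEROTELIC = 4
    AMPHITELIC = 5


class AttachmentState(NamedTuple):
    """kMT counts ``(i1, j1, i2, j2)`` -- L/R pole counts per kinetochore."""

    i1: int
    j1: int
    i2: int
    j2: int

    def validate(self, n: int) -> "AttachmentState":
        if min(self) < 0:
            raise ParameterError(f"negative kMT count in {self}")
        if self.i1 + self.j1 > n or self.i2 + self.j2 > n:
            raise ParameterError(
                f"state {self} exceeds kinetochore capacity n={n}"
            )
        return self

    def mirror(self) -> "AttachmentState":
        """Swap the two spindle poles (L <-> R)."""
        return AttachmentState(self.j1, self.i1, self.j2, self.i2)

    def swap_kinetochores(self) -> "AttachmentState":
        return AttachmentState(self.i2, self.j2, self.i1, self.j1)


MODES = ("meiosis_I", "mitosis")


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """The six model parameters plus the division mode.

    Parameters
    ----------
    n
        Maximal number of kMTs per kinetochore (proportional to
        kinetochore size), ``n >= 2``.
    p
        Per-step association probability parameter; ``2p`` is the
        probability that a single microtubule associates with a fully free
        kinetochore in one step.  ``0 <= p <= 1/4``.
    q
        Per-step dissociation probability of one kMT.  ``0 <= q <= 1/(2n)``.
    alpha
        Scaling of amphitelic -> merotelic attachments (the physical
        constraint of the bi-oriented geometry).  Fixed to 0 in mitosis.
    beta
        Scaling of every detachment out of an amphitelic state
        (kMT stabilisation by inter-kinetochore tension).
    gamma
        Scaling of monotelic -> syntelic/merotelic attachments (the biased
        back-to-back orientation of sister kinetochores).  Fixed to 1 in
        meiosis I where sister kinetochores act as one unit.
    mode
        ``"meiosis_I"`` or ``"mitosis"``.
    """

    n: int
    p: float
    q: float
    alpha: float
    beta: float
    gamma: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 2):
            raise ParameterError(f"n must be an integer >= 2, got {self.n!r}")
        if not 0.0 <= self.p <= 0.25:
            raise ParameterError(f"p={self.p} outside [0, 1/4]")
        if not 0.0 <= self.q <= 1.0 / (2 * self.n):
            raise ParameterError(f"q={self.q} outside [0, 1/(2n)] = [0, {1/(2*self.n)}]")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.mode == "mitosis" and self.alpha != 0.0:
            raise ParameterError("mitosis requires alpha = 0")
        if self.mode == "meiosis_I" and self.gamma != 1.0:
            raise ParameterError("meiosis_I requires gamma = 1")

    @classmethod
    def meiosis_I(
        cls, n: int = 10, p: float = 0.05, q: float = 0.05,
        alpha: float = 0.0, beta: float = 0.0,
    ) -> "ModelParams":
        return cls(n=n, p=p, q=q, alpha=alpha, beta=beta, gamma=1.0,
                   mode="meiosis_I")

    @classmethod
    def mitosis(
        cls, n: int = 10, p: float = 0.05, q: float = 0.05,
        beta: float = 0.0, gamma: float = 0.1,
    ) -> "ModelParams":
        return cls(n=n, p=p, q=q, alpha=0.0, beta=beta, gamma=gamma,
                   mode="mitosis")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


def classify_counts(i1, j1, i2, j2):
    """Vectorised classification of count arrays into the five classes.

    Accepts scalars or broadcastable integer arrays; returns an int array
    of class values (1..5).  Precedence: merotelic is tested before
    syntelic/amphitelic, so a doubly-attached kinetochore always yields
    class 4 regardless of the partner.
    """
    i1, j1, i2, j2 = np.broadcast_arrays(
        np.atleast_1d(i1), np.atleast_1d(j1), np.atleast_1d(i2), np.atleast_1d(j2)
    )
    out = np.empty(i1.shape, dtype=np.int8)
    a1 = (i1 > 0) | (j1 > 0)  # kinetochore 1 attached at all
    a2 = (i2 > 0) | (j2 > 0)
    mero = ((i1 > 0) & (j1 > 0)) | ((i2 > 0) & (j2 > 0))
    amph = (((i1 > 0) & (j1 == 0) & (i2 == 0) & (j2 > 0))
            | ((i1 == 0) & (j1 > 0) & (i2 > 0) & (j2 == 0)))
    syn = (((i1 > 0) & (j1 == 0) & (i2 > 0) & (j2 == 0))
           | ((i1 == 0) & (j1 > 0) & (i2 == 0) & (j2 > 0)))
    mono = a1 ^ a2
    out[:] = AttachmentClass.FREE
    out[mono] = AttachmentClass.MONOTELIC
    out[syn] = AttachmentClass.SYNTELIC
    out[amph] = AttachmentClass.AMPHITELIC
    out[mero] = AttachmentClass.MEROTELIC  # last: overrides mono/syn/amph
    return out


def classify(state: AttachmentState) -> AttachmentClass:
    """Classify a single configuration into one of the five classes."""
    return AttachmentClass(classify_counts(*state).item())


class StateSpace:
    """Enumeration of all configurations for a given capacity ``n``.

    States are ordered lexicographically in ``(i1, j1, i2, j2)``; the order
    is stable across runs so serialised matrices are reproducible.  The
    number of states is ``((n+1)(n+2)/2)**2``.
    """

    def __init__(self, n: int):
        if not (isinstance(n, (int, np.integer)) and n >= 2):
            raise ParameterError(f"n must be an integer >= 2, got {n!r}")
        self.n = int(n)
        states = [
            AttachmentState(i1, j1, i2, j2)
            for i1 in range(n + 1)
            for j1 in range(n + 1 - i1)
            for i2 in range(n + 1)
            for j2 in range(n + 1 - i2)
        ]
        self.states: Sequence[AttachmentState] = tuple(states)
        self.counts = np.array(states, dtype=np.int64)  # (S, 4)
        self._index = {s: k for k, s in enumerate(states)}
        # dense lookup from the packed tuple code to the state index
        m = self.n + 1
        codes = (((self.counts[:, 0] * m + self.counts[:, 1]) * m
                  + self.counts[:, 2]) * m + self.counts[:, 3])
        self._code_to_index = np.full(m ** 4, -1, dtype=np.int64)
        self._code_to_index[codes] = np.arange(len(states))
        self.class_of = classify_counts(*self.counts.T)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[AttachmentState]:
        return iter(self.states)

    def index(self, state: AttachmentState) -> int:
        return self._index[AttachmentState(*state)]

    def state(self, idx: int) -> AttachmentState:
        return self.states[idx]

    def indices_of_class(self, cls: AttachmentClass | int) -> np.ndarray:
        return np.flatnonzero(self.class_of == int(cls))

    def index_of_counts(self, i1, j1, i2, j2) -> np.ndarray:
        """Vectorised index lookup; -1 marks tuples outside the space."""
        m = self.n + 1
        ok = ((i1 >= 0) & (j1 >= 0) & (i2 >= 0) & (j2 >= 0)
              & (i1 + j1 <= self.n) & (i2 + j2 <= self.n))
        code = (((i1 * m + j1) * m + i2) * m + j2)
        out = np.where(ok, self._code_to_index[np.where(ok, code, 0)], -1)
        return out


def enumerate_states(n: int) -> StateSpace:
    """Enumerate all states ``(i1, j1, i2, j2)`` with per-kinetochore sums
    at most ``n``, in lexicographic order."""
    return StateSpace(n)


class Event(NamedTuple):
    """One elementary event: (de)attachment of one kMT on one kinetochore."""

    kind: str          # "attach" | "detach"
    kinetochore: int   # 1 | 2
    pole: str          # "left" | "right"


#: Canonical ordering of the eight elementary events.  The Monte Carlo
#: simulator partitions a single uniform draw over this order (followed by
#: the self-loop), so the order is part of the reproducibility contract.
EVENT_ORDER: tuple[Event, ...] = (
    Event("attach", 1, "left"),
    Event("attach", 1, "right"),
    Event("attach", 2, "left"),
    Event("attach", 2, "right"),
    Event("detach", 1, "left"),
    Event("detach", 1, "right"),
    Event("detach", 2, "left"),
    Event("detach", 2, "right"),
)

# displacement of (i1, j1, i2, j2) per event, same order as EVENT_ORDER
_EVENT_DELTA = np.array(
    [
        [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1],
        [-1, 0, 0, 0], [0, -1, 0, 0], [0, 0, -1, 0], [0, 0, 0, -1],
    ],
    dtype=np.int64,
)


def apply_event(state: AttachmentState, event: Event) -> AttachmentState | None:
    """Resulting state, or None when the event is infeasible."""
    k = EVENT_ORDER.index(event)
    new = tuple(np.asarray(state) + _EVENT_DELTA[k])
    i1, j1, i2, j2 = new
    if min(new) < 0:
        return None
    return AttachmentState(i1, j1, i2, j2)


def event_probability(
    state: AttachmentState, event: Event, params: ModelParams
) -> float:
    """Base (unscaled) probability of one elementary event in one step.

    Attachment on kinetochore m from either pole carries probability
    ``p * (n - i_m - j_m) / n``; detachment of one L (R) kMT carries
    ``i_m * q`` (``j_m * q``).  Infeasible events return 0.
    """
    i1, j1, i2, j2 = state
    n = params.n
    if event.kinetochore == 1:
        i, j = i1, j1
    else:
        i, j = i2, j2
    if event.kind == "attach":
        free = n - i - j
        if free <= 0:
            return 0.0
        return params.p * free / n
    count = i if event.pole == "left" else j
    if count <= 0:
        return 0.0
    return count * params.q


def scaling_factor(
    from_state: AttachmentState,
    to_state: AttachmentState,
    params: ModelParams,
) -> float:
    """Class-dependent factor applied on top of the base event probability.

    * ``alpha``  -- amphitelic state, attachment landing in a merotelic
      state (the wrong-pole capture blocked by bi-oriented geometry);
    * ``beta``   -- amphitelic state, any detachment (tension-stabilised
      kMTs), including detachments that stay amphitelic;
    * ``gamma``  -- monotelic state, attachment landing in a syntelic or
      merotelic state (hindered by sister-kinetochore co-orientation);
    * 1 otherwise.
    """
    delta = np.asarray(to_state, dtype=int) - np.asarray(from_state, dtype=int)
    nz = np.flatnonzero(delta)
    if len(nz) != 1 or abs(delta[nz[0]]) != 1:
        raise ValueError(
            f"{from_state} -> {to_state} is not a single attach/detach event"
        )
    is_attach = delta[nz[0]] == 1
    cls_from = classify(from_state)
    if cls_from == AttachmentClass.AMPHITELIC:
        if not is_attach:
            return params.beta
        if classify(to_state) == AttachmentClass.MEROTELIC:
            return params.alpha
        return 1.0
    if cls_from == AttachmentClass.MONOTELIC and is_attach:
        cls_to = classify(to_state)
        if cls_to in (AttachmentClass.SYNTELIC, AttachmentClass.MEROTELIC):
            return params.gamma
        return 1.0
    return 1.0


@dataclasses.dataclass
class TransitionKernel:
    """Row-stochastic one-step transition matrix over a :class:`StateSpace`.

    ``matrix`` is sparse CSR; row ``u`` holds the scaled probabilities of
    the at most eight elementary events out of state ``u``, with the
    residual mass on the diagonal.
    """

    matrix: sparse.csr_matrix
    params: ModelParams
    space: StateSpace

    @property
    def n_states(self) -> int:
        return len(self.space)

    def row(self, state: AttachmentState) -> np.ndarray:
        return np.asarray(
            self.matrix[self.space.index(state)].todense()
        ).ravel()

    def absorbing_indices(self, tol: float = 1e-14) -> np.ndarray:
        """Indices whose off-diagonal mass is below ``tol``."""
        off = np.asarray(
            (self.matrix - sparse.diags(self.matrix.diagonal())).sum(axis=1)
        ).ravel()
        return np.flatnonzero(off <= tol)

    def write_coo(self, path) -> None:
        """Export as text triplets (row, col, probability) with a header."""
        coo = self.matrix.tocoo()
        with open(path, "w") as fh:
            fh.write(
                f"# kmtchain kernel n={self.space.n} states={len(self.space)} "
                "order=lexicographic(i1,j1,i2,j2)\n"
            )
            fh.write("row\tcol\tprobability\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r}\t{c}\t{float(v)!r}\n")


def _scaled_event_matrix(params: ModelParams, space: StateSpace):
    """(targets, probabilities) arrays of shape (S, 8) for the eight events.

    Entry ``[u, k]`` is the target index (or -1) and the scaled probability
    of event ``EVENT_ORDER[k]`` out of state ``u``.  Shared by the kernel
    assembly; the Monte Carlo simulator recomputes probabilities on the fly
    instead of reading this table.
    """
    n = params.n
    c = space.counts
    i1, j1, i2, j2 = c.T
    cls = space.class_of
    free1 = (n - i1 - j1) / n
    free2 = (n - i2 - j2) / n
    base = np.stack(
        [
            params.p * free1,
            params.p * free1,
            params.p * free2,
            params.p * free2,
            i1 * params.q,
            j1 * params.q,
            i2 * params.q,
            j2 * params.q,
        ],
        axis=1,
    )
    targets = np.empty((len(space), 8), dtype=np.int64)
    scale = np.ones((len(space), 8))
    amph = cls == AttachmentClass.AMPHITELIC
    mono = cls == AttachmentClass.MONOTELIC
    for k in range(8):
        d = _EVENT_DELTA[k]
        tgt = space.index_of_counts(i1 + d[0], j1 + d[1], i2 + d[2], j2 + d[3])
        targets[:, k] = tgt
        valid = tgt >= 0
        tcls = np.where(valid, space.class_of[np.where(valid, tgt, 0)], 0)
        if k < 4:  # attachments
            s = np.ones(len(space))
            s[amph & (tcls == AttachmentClass.MEROTELIC)] = params.alpha
            s[mono & np.isin(tcls, (AttachmentClass.SYNTELIC,
                                    AttachmentClass.MEROTELIC))] = params.gamma
            scale[:, k] = s
        else:      # detachments
            scale[amph, k] = params.beta
    probs = base * scale
    probs[targets < 0] = 0.0
    return targets, probs


def build_kernel(params: ModelParams, space: StateSpace | None = None) -> TransitionKernel:
    """Assemble the sparse one-step transition kernel for ``params``.

    Off-diagonal entries are base event probability times the class scaling
    factor; the diagonal carries ``1 - (row sum)``, which the parameter
    ranges keep non-negative.
    """
    if space is None:
        space = StateSpace(params.n)
    elif space.n != params.n:
        raise ParameterError(
            f"state space built for n={space.n}, parameters have n={params.n}"
        )
    S = len(space)
    targets, probs = _scaled_event_matrix(params, space)
    feasible = targets >= 0
    rows = np.repeat(np.arange(S), 8)[feasible.ravel()]
    cols = targets.ravel()[feasible.ravel()]
    vals = probs.ravel()[feasible.ravel()]
    diag = 1.0 - probs.sum(axis=1)
    if diag.min() < -1e-12:
        raise ParameterError(
            f"row exit probability exceeds 1 (min diagonal {diag.min():.3e})"
        )
    rows = np.concatenate([rows, np.arange(S)])
    cols = np.concatenate([cols, np.arange(S)])
    vals = np.concatenate([vals, np.clip(diag, 0.0, None)])
    keep = vals != 0.0
    matrix = sparse.csr_matrix(
        (vals[keep], (rows[keep], cols[keep])), shape=(S, S)
    )
    return TransitionKernel(matrix=matrix, params=params, space=space)
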