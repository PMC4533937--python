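"""Seeded Monte Carlo simulator for the attachment/detachment chain.

The simulator is deliberately independent of the assembled transition
matrix: each step recomputes the eight scaled event probabilities directly
from the current counts and partitions a single uniform draw over the
canonical event order (:data:`kmtchain.chain_model.EVENT_ORDER`, followed
by the self-loop).  Replicate ``r`` of a run seeded with ``seed`` consumes
the dedicated stream ``SeedSequence(seed, spawn_key=(r,))``, so individual
replicates are reproducible in isolation and identical across platforms.

Sampling is vectorised across replicates for speed; the per-replicate
uniform streams make the result identical to stepping each replicate on
its own.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .chain_model import (
    AttachmentClass,
    AttachmentState,
    ModelParams,
    classify_counts,
)

__all__ = ["SimulationRun", "simulate", "empirical_class_curve",
           "empirical_first_passage"]


@dataclasses.dataclass
class SimulationRun:
    """Replicated sample paths of the attachment chain."""

    seed: int
    n_replicates: int
    horizon: int
    paths: np.ndarray  # (n_replicates, horizon+1, 4), kMT counts
    params: ModelParams

    @property
    def classes(self) -> np.ndarray:
        """Class label of every visited state, shape (replicates, T+1)."""
        return classify_counts(
            self.paths[..., 0], self.paths[..., 1],
            self.paths[..., 2], self.paths[..., 3],
        )


def _replicate_uniforms(seed: int, n_replicates: int, n_steps: int) -> np.ndarray:
    """(n_replicates, n_steps) uniforms; row r from stream (seed, r)."""
    out = np.empty((n_replicates, n_steps))
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        out[r] = rng.random(n_steps)
    return out


def _event_probabilities(counts: np.ndarray, params: ModelParams) -> np.ndarray:
    """Scaled probabilities of the 8 events for each row of ``counts``.

    Recomputed from first principles (association proportional to free
    capacity, per-kMT dissociation, class-dependent alpha/beta/gamma
    scaling) rather than read from an assembled kernel.
    """
    n = params.n
    i1, j1, i2, j2 = counts.T
    cls = classify_counts(i1, j1, i2, j2)
    amph = cls == AttachmentClass.AMPHITELIC
    mono = cls == AttachmentClass.MONOTELIC
    probs = np.empty((len(counts), 8))
    # base attachment probabilities (zero when at capacity)
    probs[:, 0] = probs[:, 1] = params.p * (n - i1 - j1) / n
    probs[:, 2] = probs[:, 3] = params.p * (n - i2 - j2) / n
    # base detachments
    probs[:, 4] = i1 * params.q
    probs[:, 5] = j1 * params.q
    probs[:, 6] = i2 * params.q
    probs[:, 7] = j2 * params.q
    # scaling out of amphitelic states: wrong-pole attachment -> alpha,
    # any detachment -> beta.  In an amphitelic state the attached pole of
    # kinetochore 1 is left iff i1 > 0; an attachment is "wrong pole" when
    # it targets the opposite side of either kinetochore.
    k1_left = i1 > 0
    wrong = np.zeros((len(counts), 4), dtype=bool)
    wrong[:, 0] = ~k1_left  # attach L on k1 while k1 holds R
    wrong[:, 1] = k1_left
    wrong[:, 2] = k1_left   # k2 holds the pole opposite to k1
    wrong[:, 3] = ~k1_left
    scale = np.ones((len(counts), 8))
    scale[:, :4][amph[:, None] & wrong] = params.alpha
    scale[:, 4:][amph] = params.beta
    # scaling out of monotelic states: attachments creating syntelic or
    # merotelic configurations -> gamma.  With kinetochore m attached to a
    # single pole, same-pole attachment on m keeps class 2 (factor 1);
    # opposite-pole on m makes it merotelic; on the free kinetochore the
    # same pole as m gives syntelic, the opposite gives amphitelic.
    att1 = (i1 > 0) | (j1 > 0)
    left_pole = (i1 > 0) | (i2 > 0)  # pole of the single attached kinetochore
    gam = np.zeros((len(counts), 4), dtype=bool)
    gam[:, 0] = np.where(att1, ~left_pole, left_pole)    # attach L on k1
    gam[:, 1] = np.where(att1, left_pole, ~left_pole)    # attach R on k1
    gam[:, 2] = np.where(att1, left_pole, ~left_pole)    # attach L on k2
    gam[:, 3] = np.where(att1, ~left_pole, left_pole)    # attach R on k2
    scale[:, :4][mono[:, None] & gam] = params.gamma
    return probs * scale


def simulate(
    params: ModelParams,
    init: AttachmentState = AttachmentState(0, 0, 0, 0),
    horizon: int = 100,
    n_replicates: int = 1,
    seed: int = 0,
) -> SimulationRun:
    """Sample ``n_replicates`` paths of ``horizon`` steps from ``init``."""
    init = AttachmentState(*init).validate(params.n)
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    paths = np.empty((n_replicates, horizon + 1, 4), dtype=np.int16)
    paths[:, 0] = np.asarray(init, dtype=np.int16)
    if horizon == 0:
        return SimulationRun(seed, n_replicates, horizon, paths, params)
    u = _replicate_uniforms(seed, n_replicates, horizon)
    counts = np.repeat(np.asarray([init], dtype=np.int64), n_replicates, axis=0)
    deltas = np.array(
        [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1],
         [-1, 0, 0, 0], [0, -1, 0, 0], [0, 0, -1, 0], [0, 0, 0, -1],
         [0, 0, 0, 0]],
        dtype=np.int64,
    )
    for t in range(horizon):
        cum = np.cumsum(_event_probabilities(counts, params), axis=1)
        # event index = count of cumulative cells below the draw; 8 = self-loop
        ev = (u[:, t, None] >= cum).sum(axis=1)
        counts += deltas[ev]
        paths[:, t + 1] = counts
    return SimulationRun(seed, n_replicates, horizon, paths, params)


def empirical_class_curve(run: SimulationRun):
    """Per-time empirical class frequencies with binomial standard errors.

    Returns a :class:`kmtchain.observables.ClassProbabilityCurve` whose
    frequencies carry an extra ``stderr`` attribute of the same shape.
    """
    from .observables import ClassProbabilityCurve

    cls = run.classes
    R = run.n_replicates
    freq = np.stack(
        [(cls == c).mean(axis=0) for c in range(1, 6)], axis=1
    )
    curve = ClassProbabilityCurve(
        times=np.arange(run.horizon + 1), prob_by_class=freq
    )
    curve.stderr = np.sqrt(freq * (1.0 - freq) / R)
    return curve


def empirical_first_passage(
    params: ModelParams,
    target_class: AttachmentClass | int = AttachmentClass.AMPHITELIC,
    init: AttachmentState = AttachmentState(0, 0, 0, 0),
    n_replicates: int = 1000,
    seed: int = 0,
    max_steps: int = 100_000,
    chunk: int = 256,
) -> dict:
    """Empirical mean first passage time to ``target_class``.

    The target class is made absorbing (replicates stop evolving once they
    hit it) and hitting times are averaged.  Raises if any replicate fails
    to arrive within ``max_steps``.
    """
    target = int(target_class)
    init = AttachmentState(*init).validate(params.n)
    counts = np.repeat(np.asarray([init], dtype=np.int64), n_replicates, axis=0)
    hit_time = np.full(n_replicates, -1, dtype=np.int64)
    already = classify_counts(*counts.T) == target
    hit_time[already] = 0
    rngs = [
        np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        for r in range(n_replicates)
    ]
    deltas = np.array(
        [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1],
         [-1, 0, 0, 0], [0, -1, 0, 0], [0, 0, -1, 0], [0, 0, 0, -1],
         [0, 0, 0, 0]],
        dtype=np.int64,
    )
    t = 0
    while t < max_steps and (hit_time < 0).any():
        steps = min(chunk, max_steps - t)
        active = np.flatnonzero(hit_time < 0)
        u = np.stack([rngs[r].random(steps) for r in active])
        sub = counts[active]
        sub_hit = np.full(len(active), -1, dtype=np.int64)
        for s in range(steps):
            live = sub_hit < 0
            if not live.any():
                break
            cum = np.cumsum(_event_probabilities(sub[live], params), axis=1)
            ev = (u[live, s, None] >= cum).sum(axis=1)
            sub[live] += deltas[ev]
            arrived = classify_counts(*sub[live].T) == target
            idx = np.flatnonzero(live)[arrived]
            sub_hit[idx] = t + s + 1
        counts[active] = sub
        hit_time[active] = sub_hit
        t += steps
    if (hit_time < 0).any():
        raise RuntimeError(
            f"{(hit_time < 0).sum()} of {n_replicates} replicates did not "
            f"reach class {target} within {max_steps} steps"
        )
    return {
        "mean": float(hit_time.mean()),
        "stderr": float(hit_time.std(ddof=1) / np.sqrt(n_replicates)),
        "hitting_times": hit_time,
    }
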