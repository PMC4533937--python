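"""Independent brute-force reference implementation for small n.

Everything here is written from first principles and deliberately avoids
the production code path: states are enumerated with explicit loops,
classification is a chain of if-statements over the count pattern, the
dense kernel is assembled by scanning all state pairs for single-count
differences, and the linear-algebra analyses use dense numpy solves.
Only plain Python tuples and numpy are used.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_states(n):
    """All (i1, j1, i2, j2) with per-kinetochore sums <= n, lexicographic."""
    out = []
    for i1, j1, i2, j2 in itertools.product(range(n + 1), repeat=4):
        if i1 + j1 <= n and i2 + j2 <= n:
            out.append((i1, j1, i2, j2))
    return out


def oracle_classify(state):
    """Five-class taxonomy, written as an explicit decision chain."""
    i1, j1, i2, j2 = state
    if (i1 > 0 and j1 > 0) or (i2 > 0 and j2 > 0):
        return 4  # merotelic: some kinetochore holds both poles
    k1 = "L" if i1 > 0 else ("R" if j1 > 0 else "-")
    k2 = "L" if i2 > 0 else ("R" if j2 > 0 else "-")
    if k1 == "-" and k2 == "-":
        return 1  # free
    if k1 == "-" or k2 == "-":
        return 2  # monotelic
    if k1 == k2:
        return 3  # syntelic
    return 5      # amphitelic: opposite single poles


def _single_event(u, v):
    """('attach'|'detach', position) if v differs from u by one +-1, else None."""
    diffs = [(k, v[k] - u[k]) for k in range(4) if u[k] != v[k]]
    if len(diffs) != 1 or abs(diffs[0][1]) != 1:
        return None
    pos, d = diffs[0]
    return ("attach" if d == 1 else "detach", pos)


def oracle_kernel(n, p, q, alpha, beta, gamma):
    """Dense one-step matrix assembled by scanning all state pairs."""
    states = oracle_states(n)
    S = len(states)
    K = np.zeros((S, S))
    for a, u in enumerate(states):
        cls_u = oracle_classify(u)
        for b, v in enumerate(states):
            ev = _single_event(u, v)
            if ev is None:
                continue
            kind, pos = ev
            kinet = 0 if pos < 2 else 1
            occ = u[0] + u[1] if kinet == 0 else u[2] + u[3]
            if kind == "attach":
                prob = p * (n - occ) / n
            else:
                prob = u[pos] * q
            cls_v = oracle_classify(v)
            scale = 1.0
            if cls_u == 5 and kind == "detach":
                scale = beta
            elif cls_u == 5 and kind == "attach" and cls_v == 4:
                scale = alpha
            elif cls_u == 2 and kind == "attach" and cls_v in (3, 4):
                scale = gamma
            K[a, b] = prob * scale
    for a in range(S):
        K[a, a] = 1.0 - K[a].sum()
    return states, K


def oracle_propagate(K, init, T):
    """init @ K^t for t = 0..T, dense."""
    out = [np.asarray(init, dtype=float)]
    for _ in range(T):
        out.append(out[-1] @ K)
    return np.array(out)


def oracle_mfpt(states, K, target_class, start):
    """Dense absorbing-chain solve of the expected hitting time."""
    classes = [oracle_classify(s) for s in states]
    transient = [k for k, c in enumerate(classes) if c != target_class]
    Q = K[np.ix_(transient, transient)]
    t = np.linalg.solve(np.eye(len(transient)) - Q, np.ones(len(transient)))
    full = np.zeros(len(states))
    for row, k in enumerate(transient):
        full[k] = t[row]
    return full[states.index(tuple(start))]


def oracle_stationary(K):
    """Left Perron eigenvector via dense eigendecomposition."""
    w, V = np.linalg.eig(K.T)
    k = np.argmin(np.abs(w - 1.0))
    pi = np.real(V[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def oracle_absorption(states, K, start):
    """Expected visits and absorbing-state hit probabilities, dense."""
    S = len(states)
    absorbing = [k for k in range(S) if np.isclose(K[k, k], 1.0)
                 and np.isclose(K[k].sum() - K[k, k], 0.0)]
    transient = [k for k in range(S) if k not in absorbing]
    N = np.linalg.inv(np.eye(len(transient)) - K[np.ix_(transient, transient)])
    srow = transient.index(states.index(tuple(start)))
    visits = np.zeros(S)
    for col, k in enumerate(transient):
        visits[k] = N[srow, col]
    R = K[np.ix_(transient, absorbing)]
    hits = N[srow] @ R
    return absorbing, visits, dict(zip(absorbing, hits))
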