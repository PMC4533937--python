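# Methods

## Model

The chain tracks the kMT occupancy of a kinetochore pair as
rₙ(i₁, j₁, i₂, j₂): left/right-pole counts per kinetochore, each
kinetochore holding at most *n* kMTs. kMTs of the same pole on the same
kinetochore are indistinguishable — the state is the count tuple, not a
labelled set. The two kinetochores interact with the poles independently;
all coupling between them enters only through the class-dependent scaling
factors below.

One discrete step performs at most one elementary event (single-event
semantics). The eight candidate events and their base probabilities are

| event | probability |
|---|---|
| attach on kinetochore m, pole L or R | p·(n − i_m − j_m)/n |
| detach one L kMT on kinetochore m | i_m·q |
| detach one R kMT on kinetochore m | j_m·q |

Association is proportional to the remaining free binding surface;
dissociation is per-kMT and surface-independent. The residual probability
stays on the diagonal (self-loop). With p ≤ 1/4 and q ≤ 1/(2n) the total
exit probability per kinetochore is a convex combination of 2p and nq,
both ≤ 1/2, so rows are stochastic with a non-negative diagonal — this is
why those bounds are enforced at construction and the single-event reading
is internally consistent.

### Classes and scaling

States partition into five classes: free (no kMT), monotelic (one
kinetochore attached, single pole), syntelic (both attached, same pole),
merotelic (some kinetochore attached to both poles), amphitelic (opposite
single poles — correct bi-orientation). Classification tests merotelic
first, so a doubly-attached kinetochore dominates the label.

Scaling of event probabilities by class of the *source* state:

- **α** multiplies amphitelic attachments that land in the merotelic
  class only; correct-pole attachments within the amphitelic class stay
  unscaled. Biologically: the bi-oriented geometry blocks wrong-pole
  capture but not further correct-pole capture.
- **β** multiplies *every* detachment out of an amphitelic state,
  including those that remain amphitelic; tension stabilises all kMTs of
  a bi-oriented pair, not only the last one.
- **γ** multiplies monotelic attachments landing in the syntelic or
  merotelic class; the monotelic → amphitelic capture and same-pole
  growth are unscaled.

Division modes: mitosis fixes α = 0 (back-to-back sister geometry makes
amphitelic → merotelic capture negligible); meiosis I fixes γ = 1 (sister
kinetochores act as one unit, no orientation bias of the free
kinetochore). The CLI defaults mirror the reference setting: n = 10,
p = q = 0.05; γ = 0.1 for mitosis.

### Parameters that matter

All parameters are dimensionless; time is measured in chain steps. The
dynamics is governed largely by the ratio q/p (relative detachment rate):
with q ≈ p, errors resolve quickly; q ≪ p stabilises whatever is attached,
including merotelic errors. α and β control the stability of established
bi-orientation and never affect the first-passage time to it (they only
scale transitions *out of* the amphitelic class — asserted as a property
test to 1e-9 relative).

## Exact analyses

- **Transient dynamics**: init·Kᵗ by repeated sparse vector–matrix
  products; never dense matrix powers. S = ((n+1)(n+2)/2)² is 4356 at
  n = 10, so hundreds of steps cost milliseconds.
- **Mean first passage time**: all target-class states are made
  absorbing; (I − Q)t = 1 is solved on the transient block with a sparse
  LU factorisation. A singular system (unreachable target) is detected
  via non-finite solutions and reported as an error.
- **Stationary distribution**: one balance equation is replaced by the
  normalisation row and the system solved sparsely. Uniqueness is checked
  structurally first: the strongly connected components with no outgoing
  edge are enumerated, and more than one closed recurrent class (e.g.
  β = 0, where rₙ(n,0,0,n) and rₙ(0,n,n,0) are separate absorbing states)
  raises an error directing the caller to absorption analysis. Entries in
  (−1e-12, 0) from round-off are clipped to 0 and the vector renormalised;
  the residual ‖πK − π‖∞ must be below 1e-10.
- **Absorption statistics**: expected visits are the start row of the
  fundamental matrix N = (I − Q)⁻¹, obtained from one solve of the
  transposed system; absorption probabilities are N·R and must sum to 1
  within 1e-10.
- **Bi-orientation attempts** (β = 0 regime): the expected number of
  traversals of {monotelic, merotelic} → amphitelic edges before
  absorption, Σ_u visits(u)·Σ_v K[u,v]. With α = 0 the amphitelic class is
  never exited and the count is exactly 1.

## Synchrony of k chromosomes

The cell's k chromosome pairs are modelled as independent copies of the
chain (no inter-chromosome coupling, no explicit checkpoint signal), so
the probability that all are simultaneously amphitelic at step t is
θₜᵏ. Steady-state synchrony is the stationary amphitelic probability to
the k-th power; for β = 0 every chain is eventually trapped in the
amphitelic class and the limit is 1.

**Half-life of synchrony** is a dwell time: each chain starts from the
stationary distribution conditioned on the amphitelic class, and survival
is the probability of remaining continuously amphitelic, computed by
iterating the substochastic restriction of the kernel to amphitelic
states. The half-life is the duration (linearly interpolated between
integer steps on the joint survival) at which the k-chain survival drops
to 1/2. In the near-exponential decay regime this scales as 1/k. A
relaxation-time reading of "half-life" would be a defensible alternative;
the dwell-time definition is the one exposed because it directly measures
how long an established synchrony persists. Because the definition
conditions on a stationary law, any β = 0 chain (whose long-run mass sits
on the two fully occupied amphitelic absorbing states, which neither
detachment nor capacity-blocked attachment can exit) gets an infinite
half-life, not only α = β = 0.

## Closed forms

At α = β = γ = 1 the kinetochores decouple and detailed balance gives a
trinomial stationary law per kinetochore: each of the n slots is
left-attached / right-attached / free with odds p/(nq) : p/(nq) : 1. The
mean occupancy is N̄ = nρ/(n+ρ), ρ = 2p/q (5/3 at p = q, n = 10); both the
law (total-variation < 1e-10) and the mean (1e-10) are verified against
the exact solver. The amphitelic-conditional approximation for α = 0,

    N̄₅ = ρ̄ (ρ̄/n + 2)^(n−1) / ((ρ̄/n + 2)ⁿ − 2ⁿ),   ρ̄ = 2p/(βq),

is evaluated through the equivalent form (ρ̄/2)·y^(n−1)/(yⁿ − 1) with
y = 1 + ρ̄/(2n) using `log1p`/`expm1`, switching to the asymptotic branch
when n·log y exceeds 700, so large n or small βq neither overflow nor
cancel; its β → 0⁺ limit is n. It is an approximation: at n = 10,
p = q = 0.05, β = 1 it gives 1.4795 against an exact conditional mean
within a few percent (characterised, not asserted to a fixed bound).

## Monte Carlo cross-check

The simulator recomputes the eight scaled event probabilities from the
current counts in an independent vectorised code path (it never reads the
assembled kernel), partitions one uniform draw per step over the canonical
event order (attach L/R on k₁, attach L/R on k₂, detach L/R on k₁, detach
L/R on k₂, self-loop), and gives replicate r its own
`SeedSequence(seed, spawn_key=(r,))` stream. Runs are therefore bit-wise
reproducible, replicates individually so, and a prefix of replicates of a
larger run equals a smaller run. Agreement with the exact propagation
(3 binomial standard errors at 10⁴ replicates), one-step χ² goodness of
fit against a kernel row, and the empirical first-passage mean are all
exercised in the test suite.

## Numerical conventions

- Row sums and stationary residuals: 1e-12 / 1e-10 absolute.
- State ordering: lexicographic in (i₁, j₁, i₂, j₂), stable, so exported
  coordinate-triplet matrices are reproducible byte for byte.
- Degenerate inputs: attach at capacity and detach at zero count have
  probability 0 rather than raising; conditional statistics on an empty
  class raise.
- Problem sizes in the test suite are chosen small where exhaustive or
  dense-oracle comparison is the point (n = 2: 36 states; n = 4–6 for
  grids) and n = 10 (4356 states) for every headline quantity.

## What the tests do and do not show

All inputs are model parameters — there is no synthetic data beyond the
simulator's sample paths, so the usual caveat reduces to: the model
itself abstracts away spatial search-and-capture geometry, microtubule
dynamic instability, explicit spindle-assembly-checkpoint biochemistry
and inter-chromosome coupling. Conclusions about those mechanisms are
outside what any test here can support. Within the model, the exact
analyses are validated against independent brute-force constructions at
small n and against closed forms, and the simulator against the exact
analyses.
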