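# Methods

## The model

`mdmc` decomposes the stationary random walk on a network into a mixture of
community-localized random walks.  Let `A = (A_nm)` be the (weighted,
possibly directed) adjacency matrix with `A_nm` the weight of the link
`m -> n`, and `T_nm = A_nm / sum_n' A_n'm` the column-stochastic transition
rates.  The walker's stationary occupation `p(n)` is modelled as

    p(n) = sum_k pi(k) p(n|k),          sum_n p(n|k) = 1,  sum_k pi(k) = 1,

where `p(n|k)` is the *relative membership* of node `n` in community `k`
(the profile of a random walk localized to that community) and `pi(k)` the
community's relative size.  Communities in this representation are
*pervasive*: every node carries some membership in every community, and
there is no inside/outside boundary.

Observations are walker transits over directed links, weighted by the
stationary link probabilities `p_st(l)` (for undirected networks
`p_st(l) = A_l / 2L_w`).  Each localized walk is tied to its own one-step
Markov propagation through a Dirichlet prior with concentration `alpha`,
which acts as the resolution parameter.  One EM iteration:

* **E-step** — responsibility of each link:
  `r(k|l) ∝ pi(k) p(from_l|k) p(to_l|k)`, normalized over `k`;
  an all-zero numerator falls back to the uniform `1/K`.
* **M-step** — `pi(k) = sum_l p_st(l) r(k|l)` and

      p(n|k) = alpha/(alpha+pi(k)) * [T p(.|k)]_n
             + 1/(alpha+pi(k)) * (1/2) sum_l p_st(l) r(k|l) (d_{n,from_l} + d_{n,to_l}).

Everything is computed over the link list, so an iteration costs `O(KL)`.
A fused single-pass kernel (numba) implements the same update as the
separate `e_step`/`m_step` functions to machine precision; both paths are
kept and cross-checked in the tests.

Redundant communities see `pi(k)` decay to zero, which selects the
effective number of communities automatically.  A community with
`pi(k) < 1e-4 / K` is reported as vanished (results are insensitive to this
threshold within a few orders of magnitude).  Vanished communities stay in
the arrays so the community index is stable over a run.

At `alpha = 0` the update is exactly the Ball–Karrer–Newman (BKN) Poisson
block-model EM under the mapping `theta_nk = sqrt(2L pi(k)) p(n|k)`; this
equivalence (to 1e-8 per iteration on random multigraphs) is the main
correctness oracle of the test suite.  Note the BKN M-step denominator is
`sqrt(sum_{n,m} A_nm q_nm(k))` — the double sum — which is what the mapping
produces.

## Objective and restart selection

The per-observation EM lower bound Q̃ combines the responsibility-weighted
log-joint over links with the alpha-weighted cross-entropy between the
propagated previous memberships and the current ones (0·log 0 = 0).  Two
facts matter for its use:

* Each (E, M) update maximizes Q̃ *for the current prior centre* `p_{t-1}`;
  the bound evaluated at that centre never decreases (asserted to 1e-9).
  Across iterations the centre itself moves, so the recorded Q̃ series can
  dip by ~1e-4; this is a property of the algorithm, not an implementation
  artifact.
* Consensus fitting runs several random starts at fixed alpha and keeps the
  fit with the largest converged Q̃.  At convergence Jensen's bound is
  tight, so the converged Q̃ equals the directly computed objective
  (verified numerically).

Initialization draws `pi_0` and every `p_0(.|k)` as independent U(0,1)
variates normalized to their simplices; `r` is then set by one E-step.
Identical seeds give bit-identical runs.

## Fixed points worth knowing about

Two non-obvious features of the EM landscape showed up during development
and are reproduced by the tests rather than hidden:

* **Local optima with extra communities.**  On Zachary's karate club at
  `alpha = 0.5` a *stable* 3-community optimum exists alongside the usual
  2-community solution, is reached from a few percent of random starts, and
  has the *higher* Q̃.  Community-count claims on this network are
  therefore statements about typical runs, not guarantees.
* **The symmetric degenerate state.**  Above a network-dependent critical
  alpha, all memberships converge to the stationary distribution, the
  responsibilities equal `pi`, and `pi` freezes at its initial value.  In
  this regime "number of surviving communities" is vacuous (it equals K).
  On the karate club the collapse sets in around `alpha ≈ 1–2`; on the
  dense planted benchmarks below, already around `alpha ≈ 0.05`.  Sweeps
  and resolution-monotonicity checks are run below this threshold.

## Hierarchy by quasi-static annealing

Starting from a consensus fit at a small `alpha_ini`, alpha is increased
geometrically, `alpha(t) = alpha_ini (alpha_fin/alpha_ini)^{t/T}`, with one
EM iteration per step; the annealing phase contains no randomness.  Layers
of the hierarchy appear as intervals where the `pi` trajectory is stable,
separated by transitions where small communities merge.

Layer detection segments the trajectory where the change rate
`max_k |Δpi(k)|` *per unit log alpha* stays below 0.05 and the surviving
count is constant, for at least 0.1 in log alpha (rates per log alpha make
the criterion independent of the schedule's step count; runs belonging to
the same state are merged across brief blips).  Adjacent layers are split
at the geometric midpoint of the transition interval; each layer's
belongings `p(k|n)` are evaluated at the step closest to the centre of its
alpha range (clamped into the stable run) by deterministically replaying
the annealing from a stored checkpoint.

Parent–child structure: per node, belonging mass lost by shrinking
communities is distributed over growing ones proportionally to their gains;
marginalizing with weight `p(n)` gives the community-to-community flow
matrix (conserving mass per node to 1e-10), serialized as Sankey JSON.

Practical annealing rates: the EM relaxation time on networks with
non-cohesive modules is thousands of iterations, so "quasi-static" requires
schedules of tens of thousands of steps; the trajectory lags the fixed-alpha
equilibria badly on 2000-step schedules.  The default protocols used in the
acceptance runs are 12 000 steps for the block toy and 40 000 for the ring
toy, with K well above the finest planted layer (40 and 50) so the initial
decomposition is strictly finer than the first layer of interest.

## Baselines

All baselines require symmetric adjacency and share the readout
`p(n|k) = W_nk / W_k`, `pi(k) = W_k^2 / sum W_k^2`.

* **BKN EM** on the propensities theta, with the corrected M-step
  denominator noted above; the Poisson log-likelihood (up to the constant
  factorial term) is tracked and non-decreasing.
* **NMF** under the generalized Kullback–Leibler divergence with exact
  alternating Lee–Seung updates.  The symmetric tie is applied at readout,
  `(W + Hᵀ)/2`, rather than after every sweep: per-update monotonicity of
  the objective is then guaranteed, and from a symmetric init on symmetric
  input the factors stay numerically near-symmetric anyway.
* **Bayesian NMF** (Psorakis-style) with half-normal priors on the factors
  and gamma hyper-priors on the per-community precisions
  `beta_k <- (N + a - 1) / (0.5 [sum W^2 + sum H^2] + b)`, damped
  multiplicative updates, and survival by column mass.  The rate `b` is
  kept in the denominator — dropping it would remove `b` from the algorithm
  entirely, contradicting its documented strong effect on the number of
  surviving communities (small `b` lets precisions grow and kill redundant
  communities; large `b` disables the shrinkage).  Defaults: `a = 5`.

## Synthetic data

* **Planted pervasive communities** (the comparative-study benchmark):
  membership profiles `p*(n|k*)` are N i.i.d. draws from a truncated Pareto
  with tail exponent `gamma = 3` and max/min ratio cap 100, normalized;
  sizes `pi*(k*)` likewise with `beta = 2` and cap 20.  Networks are
  Poisson multigraphs with pairwise rate `2 L sum_k pi* p*(n) p*(m)` applied
  once per unordered pair, no self-loops; the realized total weight then
  matches the target L to within Poisson noise (checked by Monte Carlo).
  Base setting: N = 1000, K* = 10, L = 20 000 (density 20); the five class
  settings (N, L) = (1000, 20k), (500, 20k), (2000, 20k), (1000, 10k),
  (1000, 40k) are tabulated in `benchmarks.BENCHMARK_CLASSES`.
  What this emulates: heavy-tailed community sizes and node participation
  with full overlap.  What it does not: degree assortativity, clustering,
  or any crisp boundaries — partitions derived from these communities are
  weakly determined by construction, so NMI values on them are small even
  for good fits.
* **Block-of-blocks-of-blocks**: 5 top blocks × 5 leaves × 40 nodes of
  nested Erdős–Rényi communities with edge probabilities 0.25 / 0.05 /
  0.005 (within leaf / within top / across top).  These densities are a
  package choice, exposed as parameters; they give a clear three-scale
  separation, and the annealed pipeline's fine/coarse phases then sit at
  alpha ≈ 0.01–0.03 and 0.1–0.5.
* **Ring-of-rings-of-rings**: 25 forty-node cycles joined into five rings
  of rings by single seam links, themselves joined into a ring; fully
  deterministic, all degrees in {2, 3}.  Single-link coupling keeps each
  cycle a strong diffusion trap, which is what lets annealing recover the
  25-ring layer essentially exactly.  The flip side, found empirically and
  documented deliberately: the 25 -> 5 merge transition then lies at very
  large alpha and is not clean (mergers stall in mis-paired intermediate
  states), while couplings strong enough to merge cleanly blur the ring
  boundaries so the fine layer is never recovered exactly.  With this
  generator the coarse layer of the ring toy is therefore *not* reliably
  extracted — a known limitation stated here rather than papered over.

## Evaluation

* `Sim(k*, k) = sum_n min(p*(n|k*), p(n|k))`; MaxSim matches every planted
  community to its most similar detected one (over survivors), with the
  relative size penalty `1 - |pi* - pi_hat| / (pi* + pi_hat)`, weighted by
  `pi*`.  MaxSim = 1 exactly at perfect recovery.  Caveat observed in the
  degenerate regime: near-uniform detected profiles score substantial
  MaxSim on near-uniform planted profiles, so MaxSim sweeps should be read
  together with the surviving-community counts.
* NMI uses natural logs and the arithmetic-mean normalization
  `2 I / (H_a + H_b)` — the unique standard normalization for which 25
  equal nested blocks against their 5 parents score exactly 2/3.  Two
  zero-entropy partitions score 1 by convention.  Cross-checked against
  scikit-learn to 1e-10.
* Hard partitions take `argmax_k pi(k) p(n|k)` over surviving communities,
  ties to the lowest index.

## Numerical choices

* Stationary states: closed form (degree / total weight) for undirected
  networks without teleportation; otherwise lazy power iteration
  (`p <- (Tp + p)/2`, same fixed point, robust to near-periodic chains) to
  L1 residual 1e-12, cap 10 000 steps.
* Teleportation (PageRank prescription, default rho = 0.15 when used)
  restores ergodicity for directed networks with dangling nodes; teleport
  moves are unobservable, so link probabilities are renormalized over
  original links only.
* Early stopping requires *both* `max|Δpi|` and `max|Δp(n|k)|` below 1e-10:
  pi can freeze long before the memberships stop moving.
* Multiplicative-update denominators are floored at 1e-12; Bayesian-NMF
  precisions are capped at 1e12.
* Node indices are 0-based internally, 1-based in files.

## Known limitations

* EM multistability is real on small networks (karate's 3-community
  optimum) and the symmetric collapse bounds the usable alpha range from
  above; neither is removed by more iterations.
* The ring toy's coarse layer is not recovered by the shipped pipeline
  (see above).
* Baselines accept only undirected networks; MDMC itself handles directed
  networks through teleportation.
* MaxSim is a heuristic score; its behaviour under degenerate fits makes
  peak-value comparisons meaningful only alongside community counts.
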