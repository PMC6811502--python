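# Methods

## Model

`balnet` simulates a network of `N = N_E + N_I` binary threshold neurons
(4:1 E:I by default).  Neuron *i* has state `sigma_i(t) ∈ {0, 1}` and total
synaptic drive

    mu_i(t) = Σ_j R_ij sigma_j(t) + (F p)_i,

with `R` the sparse recurrent connectivity (rows postsynaptic, excitatory
columns first), `F = diag(f_E, …, f_I, …)` the external scaling, and `p` a
static external input.  At asynchronous update times neuron *i* sets
`sigma_i = H(mu_i − theta_i)` with the fires-at-threshold convention
`H(0) = 1` (the tie has probability zero under continuous random drive; a
fixed convention keeps runs reproducible).

Connectivity is block Erdős–Rényi: entry `(i, j)` is present with
probability `K/N_l` (`l` = population of the presynaptic neuron `j`) and
then equals `R_kl / K^alpha` (`k` = population of `i`).  Autapses are
excluded — the estimator still estimates full rows and should return ≈ 0 on
the diagonal.  Each neuron receives on average `K` excitatory and `K`
inhibitory inputs; total density is `2K/N` (0.048 at the defaults, i.e. the
usual "0.05" figure).  External drives are i.i.d. uniform on
`[0, m0·sqrt(K))` per neuron per trial so the applied input `f_k p_i` is of
the same `sqrt(K)` order as each population's recurrent drive; `m0 = 1` is
the simplest scale for which both population rates sit in (0, 1) without
saturation (mean-field rates `m_E ≈ 0.4·m0`, `m_I ≈ 0.5·m0` at the default
strengths).  With `alpha = 1/2` the classical balance condition

    f_E/f_I > R_EI/R_II > 1

admits a regime in which the `O(sqrt(K))` excitatory and inhibitory inputs
cancel to `O(1)` and firing is fluctuation-driven.

Default parameters: `N_E=800, N_I=200, K=24, R_EE=R_IE=1, R_EI=-2,
R_II=-1.8, f_E=1.2, f_I=1, theta_E=1, theta_I=0.7, tau_E=10 ms, tau_I=9 ms,
alpha=0.5, m0=1, d=0` (`d` is the width of an optional uniform per-neuron
threshold inhomogeneity `theta_i = theta_k + U[0, d)`).

## Simulation

Each neuron carries an independent Poisson update clock of rate `1/tau_k`.
The event loop draws from the superposed process (rate
`N_E/tau_E + N_I/tau_I`) and assigns each event to a uniform neuron of the
selected population — equivalent in law to per-neuron clocks, and cheap.  A
state flip updates the drives of the flipping neuron's postsynaptic targets
only (one CSC column, `O(2K)`), which keeps the full-scale default
(≈ 3 × 10^5 events/trial, 2.8 × 10^8 events over 900 trials) at roughly
20 ms/trial in the compiled kernel.

Time averages are exact integrals of the piecewise-constant trajectories:
each accumulator is flushed lazily at the moments its integrand actually
changes, never on a sampling grid.  Consequently the linear identity

    mu_bar = R x_bar + F p

holds on every trial to accumulation round-off (≲ 1e−15 relative in
practice); it is the simulator's primary correctness oracle.  Trials are
freshly initialized (`sigma_i ~ Bernoulli(0.1)`) with independent
seed-derived streams, and a 500 ms burn-in is discarded before averaging;
the standard 2.5 s observation window is counted after the burn-in.

One master seed is split (`numpy.random.SeedSequence` spawn keys) into
independent named streams for connectivity, thresholds, inputs, and each
trial's dynamics, so any component can be regenerated in isolation and
trial results are independent of execution order.

## Reconstruction

Stacking the per-trial identity over `r` trials gives, for each row `i`,

    A v = b,   A = X^T,   b_t = U[i, t] − f_i P[i, t],

an `r × N` underdetermined system whose sparsest consistent solution is
sought by L1 minimization, with no sign constraints.  The `N` rows share
`A`, so the Gram matrix `A^T A` and all products `A^T b_i` are computed once;
rows are then solved independently (order-irrelevant, embarrassingly
parallel).

Solvers: equality basis pursuit (split-variable LP, HiGHS) for small or
exact-data systems; coordinate-descent lasso (scikit-learn, Gram-precomputed)
as the full-scale default; BPDN via bisection on the lasso penalty; OMP as a
greedy baseline.  The default lasso penalty is `lambda_rel = 1e-3` of the
per-row `alpha_max = ||A^T b||_inf / r`: because the stored averages satisfy
the linear identity exactly, the systems carry no measurement noise and the
penalty's role is numerical (speed and stability of the descent), not noise
rejection — smaller penalties give still-smaller error at higher cost.  The
duality-gap convergence warning emitted at such small penalties is expected
and harmless; the iteration cap is the effective stopping rule.

## Diagnostics

Reconstruction quality is the relative Frobenius error
`||R − R_recon||_F / ||R||_F`.  The regime diagnostic is the per-neuron
ratio of time-averaged excitatory input (recurrent excitatory **plus** the
excitatory external drive) to time-averaged inhibitory input; only with the
drive included does balance imply a ratio near −1.  Neurons whose
`|i_bar|` falls below `1e-6 ×` the network median are excluded from ratio
statistics (they would blow up the quotient in near-quiescent regimes) and
counted separately.  Occupancy cutoffs `q_low = 0.01`, `q_high = 0.99`
classify quiescent/saturated neurons.  Support metrics (precision, recall,
sign accuracy at a magnitude threshold, default half the smallest true
magnitude) are provided for ground-truth-known synthetic tests only.

## What the generator emulates — and what exactness implies

The synthetic stack reproduces the study conditions: block-random sparse
connectivity, population-uniform strengths, static uniform random drives
resampled per trial, Poisson asynchronous updates.  It does not emulate
features of real recordings: measurement noise, subsampled observation,
unknown external inputs, structured topology, or synaptic dynamics.

One consequence deserves emphasis.  Because `x_bar` and `mu_bar` are exact
window averages of the same trajectory, each row system is **exactly
consistent with the true row at every window length and in every dynamical
regime** — the true row always satisfies `A v = b` to round-off.  Recovery
error therefore comes only from underdeterminacy (L1 selecting a different
solution when `r` measurements are too few for the sensing matrix `X`) plus
the small penalty bias.  Empirically this makes the error:

- strongly decreasing in `r` (the compressive axis), as expected;
- essentially flat in observation time, since shorter exact windows change
  `X`'s statistics but not the system's consistency;
- only weakly regime-dependent at moderate imbalance: fresh random drives
  diversify `X` even when many neurons pin at 0 or 1.  Degradation off
  balance is reproducible at the full-scale in-degree `K = 24` (e.g.
  `f_E/f_I = 1.0` vs the balanced 1.2 raises the full-scale error from
  0.076 to 0.093) and grows at strong imbalance, but it vanishes at small
  `K`, where the balance margin (which scales with `sqrt(K)`) is weak;
- asymmetric in `alpha`: the strong-synapse side (`alpha < 1/2`, wild or
  frozen dynamics) clearly degrades recovery, while the weak-synapse side
  (`alpha -> 1`) does not — relative error normalizes by `||R||`, so weak
  synapses only hurt when measurements carry an absolute noise floor.

A measurement pipeline that estimates the averages noisily (e.g. sampling
states on a grid, or observing spikes rather than exact occupancies) would
re-introduce a noise floor that shrinks with observation time and is
amplified off balance; under such a pipeline the observation-time and
regime effects are expected to be much stronger.  This package deliberately
measures exactly, keeping the averaging identity as a machine-precision
oracle, and documents the regime/time flatness as a property of that
choice.  Likewise the per-neuron E/I ratio at the default `K = 24` carries
a finite-K offset of order `theta/|i_bar| ≈ 0.2` below −1 with an
across-neuron spread of ≈ 0.6 (quenched drive and in-degree heterogeneity);
the ratio approaches −1 tightly only as `K` grows.

## Problem sizes

Full scale (N=1000, K=24, r=900, 2.5 s) runs in roughly 7 minutes on one
core: ~25 s of simulation and the rest row-wise lasso.  Sweeps and the test
suite use reduced instances chosen to stay in the compressive regime
(`r < N`, `r` within a factor ~2 of the `2·2K·ln N` sparse-recovery scale):
the alpha sweep uses N=320 (256E/64I), K=8, r=240, 3 seeds; trend tests use
N=250 (200E/50I), K=12 with r up to 250; the regime comparison keeps the
full-scale K=24 (the balance margin scales with `sqrt(K)` and the effect
vanishes at small K) at N=500, r=450.  The reduced variant N=250, K=12,
r=300 — overdetermined, long averages — is used where near-exact recovery
at small cost is the point.

## Known limitations

- No estimation of `F` or `P`: the reconstructor assumes the injected
  drives and their scalings are known (the in-silico setting).
- Lasso at very small penalties trips scikit-learn's duality-gap heuristic;
  results are insensitive but the warning is filtered, not resolved.
- The BPDN bisection solves O(log) lasso problems per row; it is provided
  for completeness, not speed.
- Degenerate sensing systems (non-unique L1 minimizers) return the solver's
  vertex; tests use generic instances only.
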