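# Methods

## Model

Each cortical region is a Wilson–Cowan pair of mean-field rates,
excitatory `E` and inhibitory `I`, both confined to [0, 1]:

    tau_e dE/dt = -E + (1 - E) S(a_e w_ee E - w_ei I - B_e + J_e)
    tau_i dI/dt = -I + (1 - I) S(a_i w_ie E - w_ii I - B_i)

with `S(v) = h / (1 + exp(-v))` and `h = 1`. The `(1 - x)` shunting
factors make the unit box forward-invariant for the deterministic flow:
at `E = 1` the derivative is exactly `-1/tau_e`, at `E = 0` it is
non-negative. The gain parameters `a_e`, `a_i` scale the recurrent
excitatory term of each equation; an alternative convention applies the
gain to the whole sigmoid argument, which this package deliberately does
not use — with the convention here, the decoupled node
(`w_ee = w_ei = 0`) has the closed-form equilibrium
`E* = S(J_tot) / (1 + S(J_tot))`, which anchors several tests.

Regions couple through excitatory projections only:
`J_e^(a) = G * sum_b A_ab E^(b)` with `A` binary and directed (rows are
receivers, so row sums are in-degrees). The net input
`J_tot = J_e - B_e` is the coordinate in which all single-node analysis
is done, because `B_e` and `G` then act transparently: `B_e` shifts every
region's operating range left, `G` stretches it.

Internal units are mV and ms. Parameter values quoted in SI units
(s, V, V·s, V^-1) can be converted with `params_from_si` (times ×1000,
voltages ×1000, gains ÷1000).

### Heterogeneity

Regional heterogeneity scales the outputs of each population by the
relative local density of its cells: `w_ee, w_ie -> w * (1 + R_e)` and
`w_ii, w_ei -> w * (1 + R_i)`, with `R_e = sigma * e_z`,
`R_i = sigma * i_z`, where `e_z`, `i_z` are z-scored (sample SD,
`ddof=1`; the convention that maps (1,2,3) to (−1,0,1), switchable)
excitatory/inhibitory density maps and `sigma >= 0` is a single scale.
A perturbation that would drive any `1 + R` non-positive is a hard
error, not a clamp: clamping would silently change the mapping.
`sigma = 0` rebuilds the homogeneous model with bit-identical weights,
and the pipeline preserves this identity through simulation and scoring
(tested bit-for-bit).

## Nominal regimes

The package ships three nominal parameter sets (tau in ms, weights and
thresholds in mV-scaled units), each validated by the topology of its
bifurcation diagram rather than by matching any published table:

| regime | tau_e | tau_i | w_ee | w_ei | w_ie | w_ii | B_e | B_i | topology over its J range |
|---|---|---|---|---|---|---|---|---|---|
| fixed_point | 10 | 10 | 4 | 6 | 10 | 6 | 3.3 | 3.5 | single stable branch |
| hysteresis | 10 | 10 | 16 | 4 | 12 | 11 | 3.7 | 3.7 | 2 folds, bistable window ≈ 1.44 mV wide |
| limit_cycle | 10 | 20 | 16 | 12 | 15 | 3 | 1.5 | 3.7 | 2 Hopfs, oscillatory window ≈ 1.62 mV wide |

The fixed-point set uses weak recurrent excitation so the E-nullcline is
single-valued everywhere. The hysteresis set pairs strong recurrent
excitation with weak inhibitory feedback onto E, producing an S-shaped
branch. The limit-cycle set uses the classic oscillatory coupling
constants (16, 12, 15, 3) with inhibition twice as slow as excitation
(tau_i = 2 tau_e); the slower inhibitory feedback is what converts the
excitation into a stable oscillation between two Hopf points. A
candidate descended from the original 1972 oscillator constants
(20.8, 15.6, 30, 6 after folding its gains into the weights) was
rejected: it carries a small fold window next to the lower Hopf and is
correctly classified "composite" by the regime classifier.

The `B_e` column is only a per-regime default working point; `B_e` and
`G` are the sweep parameters.

## Bifurcation analysis

The single-node system is planar with at most three equilibria, which
permits a deliberately simple and robust continuation strategy instead
of pseudo-arclength continuation:

- **Equilibria.** For fixed `E` the inhibitory nullcline equation is
  strictly decreasing in `I`, so `I*(E)` is unique and found by
  bisection; all equilibria are sign changes of the excitatory residual
  along that curve, bracketed on an 801-point `E` grid and polished by
  Brent's method. Residuals are checked against 1e-9.
- **Stability** from the analytic 2×2 Jacobian
  (`S' = S(h - S)/h`), classified stable / unstable-saddle /
  unstable-focus.
- **Branches** are stitched across a uniform `J_tot` grid by
  nearest-neighbour matching in `E` (jump tolerance 0.2 per step).
- **Folds** are changes in the equilibrium count between adjacent grid
  points, refined by bisection on the count to 1e-6 mV.
- **Hopf points** are zero crossings of the real part of a complex
  eigenvalue pair along a branch, refined by bisection to 1e-6 mV.
- **Limit-cycle envelope** by direct integration (adaptive RK via
  `solve_ivp`, rtol 1e-8): from a 1e-3 displacement off the most
  unstable equilibrium, discard max(500 ms, 10 linear periods), record
  min/max of `E` over the following 500 ms; peak-to-peak amplitude below
  1e-4 counts as no oscillation.

Classification: ≥2 folds → hysteresis; ≥1 Hopf with non-degenerate
envelope → limit cycle; both → "composite" (never forced into one
class); neither → fixed point.

Tolerances (root residual 1e-9, bisection 1e-6 mV, duplicate-root merge
1e-5, oscillation amplitude 1e-4) are surfaced in the run-config schema.

## Stochastic simulation

Euler–Maruyama with fixed step:
`x_{k+1} = x_k + f(x_k) dt + s sqrt(dt) xi_k`, `xi_k ~ N(0,1)` i.i.d.
per state variable and step. Defaults: `dt = 0.1` ms, total length
1.2e5 ms, transient 1000 ms (10,000 steps at the default dt) removed
before any analysis, noise SD `s = 1.3e-5`. `s` multiplies `sqrt(dt)`,
i.e. it is a noise intensity in per-sqrt-ms units, not the SD of the
increment. Noise drives both `E` and `I` by default (configurable to
E-only). After each step the state is clipped to [0, 1]; with the
default noise the clip essentially never fires (tested < 1e-6 of state
updates) and every clip is counted. Initial conditions default to
`E = I = 0.25` plus seed-controlled 1e-3 jitter; presets "low", "high",
"random" and explicit arrays are accepted.

The integration loop is a numba kernel fed with pre-drawn Gaussian
chunks from `numpy.random.default_rng(seed)`, so a seed fully determines
the trajectory (bit-identical re-runs) while memory stays bounded for
long runs; `store_every` thins the stored time base without changing the
integration.

Verified numerical properties: zero-noise runs started on a stable
equilibrium stay within 1e-9 over 1e4 steps; deterministic trajectories
converge at first order in `dt` (log–log slope ≈ 1.1 on dt-halving); for
a single stable node with small noise the stationary variance of `E`
matches the Lyapunov-equation solution of the linearised SDE within 20%;
near the Hopf point the simulated oscillation period matches
`2*pi/Im(lambda)` within 10%.

## Evaluation

FC is the Pearson correlation matrix of the retained excitatory time
series (no windowing; static FC only). `rho_FCFC` is the Spearman
correlation over the N(N−1)/2 strictly-upper-triangle FC pairs — rank
based, hence invariant to monotone distortion of either matrix. Ties get
average ranks, which matters for `rho_SCFC`, where the binary
structural vector is tie-heavy; the directed adjacency is reduced to
pairs by `max(A_ab, A_ba)` by default ("connected in either direction";
`mean` is available) since FC is undirected.

Replicates run with consecutive seeds `seed_base .. seed_base+n_rep-1`
and report mean ± SD (SD = 0 by convention for a single replicate);
failed replicates are recorded with their seed, never dropped silently.
Sweeps evaluate replicate scores on a (G, B_e) grid (B_e set uniformly
across regions) or on a sigma grid, where the sigma = 0 cell is
bit-identical to the homogeneous run with the same seeds and infeasible
sigmas are marked NaN, not clamped. Desk-scale default is n_rep = 5;
40 repeats is the documented full setting. The default sweep axes
(G: 21 points over [0, 1] mV·ms; B_e: 41 points over [1, 5] mV) contain
all the standard printed working points.

The permutation test jointly permutes the (e_z, i_z) pair across regions
(preserving each region's e–i match), rebuilds the model at the given
sigma, and scores it with the same replicate seed set as the observed
model, so null variation reflects only the density assignment. The
one-sided p-value is `(1 + #{null >= observed}) / (n_valid + 1)` with
`n_valid` the feasible permutations (infeasible ones counted and
reported); default 199 permutations, minimum 19.

## Synthetic study inputs

The generators emulate the statistical structure of the real inputs the
pipeline was designed for, so every stage is testable without downloads:

- **Connectome**: binary directed graph, default 37 regions at expected
  edge density 0.7, with lognormal in-degree propensities
  (sigma_log = 0.8) so high in-degree hub regions exist — the driver of
  inter-regional differences in `J_e`. Every region is guaranteed at
  least one input. Six anatomical group labels are assigned in blocks.
- **Densities**: correlated lognormal maps (default e–i correlation 0.5,
  CV 0.25, means 6e4 and 1.2e4 cells/mm^3 for excitatory ~5× inhibitory),
  built from a shared latent Gaussian factor, so raw values are positive
  and at correlation 1 the z-scored maps coincide exactly.
- **Target FC**: one ground-truth simulation of the same model family,
  its FC jittered in Fisher-z space by N(0, sd), re-symmetrised, diagonal
  reset, clipped. Generating targets from the same model family is a
  deliberate self-consistency choice: it makes parameter-recovery
  properties well-posed (the planted optimum exists by construction).
- **Fixture suite**: a complete miniature study (N = 12, limit-cycle
  regime, planted working point G = 0.7 mV·ms, B_e = 1.5 mV, 11 s
  simulations, observation noise 0.02) written as CSV/TSV/YAML with a
  SHA-256 manifest; byte-identical for a given seed.

What the synthetic data does **not** emulate: the degree sequence or
community structure of a real tracer-based connectome, spatial
autocorrelation of density maps, hemodynamics (no BOLD forward model —
scores are computed on neural rates), subject-level variability behind a
group-average FC, or measurement confounds of fMRI. Passing recovery
tests therefore demonstrates that the pipeline is correct and sensitive
under its own assumptions, not that the model fits real mouse data.

## Problem sizes

Tests and the acceptance script run the miniature study: 12 regions,
10–11 s simulations (10 s retained), 3 replicates per sweep cell on a
7×7 grid, 99 permutations with 5 s simulations and 2 replicates. These
sizes keep the full suite fast while leaving every recovery property
sharply resolved (the planted working point is recovered exactly, and
planted heterogeneity is detected at p = 0.01). Full-scale settings
(37 regions, 120 s simulations, 40 replicates, sigma grid over [0, 1])
remain the documented defaults of the run-config schema.

## Known limitations

- No conduction delays, no distinct synaptic receptor kinetics, one
  inhibitory population per region.
- No BOLD/hemodynamic forward model; FC is computed on `E` directly.
- No codim-2 continuation or Floquet analysis; cycle stability is
  assessed by simulation only.
- Bit-level equivariance under region relabelling holds for the scoring
  chain and short trajectories; long oscillatory runs diverge at the
  floating-point level because summation order changes.
- The permutation null is exchangeable assignment of density pairs to
  regions; spatially autocorrelated nulls are out of scope.
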