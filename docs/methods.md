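# Methods

## Model and assumptions

Stage-one transport is modeled as a GKSL (Lindblad) master equation on the
node basis of a fixed weighted graph, augmented with one absorbing basis
state per sink.  The model is mechanistically neutral: it is a linear wave
proxy with tunable phase randomization, not a claim that neural tissue
sustains microscopic quantum coherence.  Its assumptions are:

* the graph is fixed for the duration of a run (no plasticity, no weight
  learning);
* dynamics are Markovian and linear — no gain nonlinearity, no memory
  kernels, no dendritic compartments;
* sinks are instantaneous absorbers: mass that reaches an attachment node
  leaks irreversibly into the sink's absorber at rate η, and cumulative
  absorber mass is the readout;
* disorder is quenched per run: one energy vector `E ~ U[−ε, +ε]^N` is
  drawn per trial and held fixed during propagation.  Disorder is drawn
  for *all* graph nodes, including sink-attachment nodes — nothing in the
  model motivates exempting them, and the choice is symmetric across
  target and distractor sinks.

The coherent generator is `H = −γ·L_sym + diag(E)`.  For directed graphs
the coupling matrix is the symmetrization of the row-normalized transition
matrix (`p(u→v) = w_uv / Σ_v w_uv`, zero rows left zero, then
`(P + Pᵀ)/2`); for undirected graphs it is `(W + Wᵀ)/2` directly.
Self-loop weights are dropped before Laplacian construction: the diagonal
of W cancels in `L = D − W` transport, so they carry no dynamical content.
Row normalization makes couplings relative routing preferences rather than
absolute synapse counts, which keeps the spectral scale of H comparable
across substrates.

Limiting behavior anchors the model between two classical baselines.  At
κ = 0 the graph block evolves unitarily (up to the non-Hermitian sink
drain) and a pure state stays pure; as κ grows, coherences are damped and
site populations obey an effective classical master equation with
Lorentzian hopping rates `2|H_uv|² κ/(κ² + Δ_uv²)` where `Δ_uv` is the
site-energy detuning.  Both limits are verified against closed forms in
the test suite (Rabi oscillation, one-state exponential decay, exact
`e^{−κt}` coherence decay, and the Lorentzian-rate fit at κ = 50).

## Numerical scheme

The generator is assembled as a sparse superoperator on the
column-stacking vectorization of the augmented density matrix; the state
at each sampled time is the exact action of the matrix exponential
(`scipy.sparse.linalg.expm_multiply`).  `dt` is therefore purely an
*output sampling grid* — accuracy is governed by the exponential-action
algorithm (effectively machine precision for these dimensions), not by
the grid, and coarse grids are legitimate whenever only the
horizon readout is needed.  Trace conservation is checked at every sample
at 1e−6 and violations raise a propagation error naming the offending
time.  Absorbers never develop coherences (the jump operators feed only
their diagonal), so restricting the dephasing projectors to graph nodes is
observationally equivalent to including absorber projectors.

Classical baselines (CRW, Metropolis thermal, Lorentzian-rate) use
column-stochastic rate matrices on the same augmented space and the same
exponential-action propagator, so mass conservation is exact to 1e−10 and
the comparison with the open-system engine differs only in dynamics.

## Parameters

| Parameter | Symbol | Default | Meaning (all dimensionless) |
|---|---|---|---|
| coupling strength | γ | 1.0 | scale of the coherent generator |
| sink coupling | η | 1.0 | strong-absorption drain rate |
| output step | dt | 0.05 | reporting grid only |
| horizon | T_end | 10.0 | finite readout window |
| dephasing | κ | swept 0.001–10 | wave-like → diffusive interpolation |
| disorder | ε | swept 0–5 | node-energy heterogeneity amplitude |
| baseline temperature | T_env | 0.1 | Metropolis suppression scale |
| ratio guard | δ | 1e−12 | keeps selectivity defined at P_D = 0 |
| distractor penalty | λ | 1.0 | Utility weighting |
| cost guard | χ | 0.01 | keeps InfoPerCost defined at zero coverage |
| good-run thresholds | S_thr, pT_min | 2.0, 0.005 | P_good criterion |

Ensemble defaults follow the benchmark design: 20 independent disorder
draws per (κ, ε) cell on the native graph; 20 surrogate graphs × 20 draws
(400 runs per cell) for rewired and lesioned variants; disorder seeds are
shared across variants at equal (κ, ε, trial) so contrasts are paired.
The default ε grid is {0, 1, 2, 3, 5}: the endpoints and the
5-level count are fixed by the benchmark design (the pre-specified
contrast is ε = 3 vs ε = 0 and the disorder factor carries 4 degrees of
freedom); the interior levels 1 and 2 are this package's choice of an
approximately even fill of the swept range.

The initial state is a classical mixture with mass 1/|sources| on each
source node.  An equal-phase coherent superposition over sources is
available (`coherent=True`) as a sensitivity switch; the mixture is the
default because nothing in the benchmark definition fixes source phases,
and a phase-free mixture makes the κ → ∞ classical comparison exact at
t = 0.

## Surrogates

"Type-aware" rewiring conserves each edge's (source class, destination
class) pair: double-edge swaps `(u→v, x→y) ⇒ (u→y, x→v)` are accepted
only when both new edges are absent, no self-loop arises, and
`class(v) = class(y)`.  This is the strongest reading of class
preservation that still permits degree-preserving randomization — every
node keeps its exact in/out degree *and* the class-pair weight strata are
unchanged, so surviving differences from the native graph are attributable
to wiring specificity alone.  Swap effort is counted in attempts (10× the
edge count by default), the standard convention.  Weights travel with the
retargeted edge (the edge from `u` keeps its weight when its target
changes); reassigning weights independently would be an additional
randomization not implied by degree-preserving rewiring.

Lesioning removes `round_half_even(drop · m)` of the `m` edges in a named
class pathway (default: half of KC→MBON), touching nothing else.

## Statistics

* **Bootstrap**: percentile CIs over runs, B = 5000, resampling paired
  samples jointly by run index.
* **Permutation contrast**: difference of group means between the ε = 3
  and ε = 0 groups, Monte-Carlo label permutation (default 10 000), with
  the +1 correction so sampled permutations never report p = 0.  The
  default is one-sided ("greater"): the disorder-enhanced-selectivity
  hypothesis predicts an *increase* at intermediate disorder, making the
  pre-specified contrast directional; a two-sided flag is provided.
* **ANOVA**: each reported effect is its own cell-means fit — one-way on
  VARIANT, one-way on EPSILON, and the full VARIANT × EPSILON cell
  structure (14 numerator df for 3 × 5 cells) — rather than a Type-III
  factorial split.  This matches the benchmark's reported degrees of
  freedom (2/4097, 4/4095, 14/4085 at 4100 runs) and keeps each F
  interpretable as "cells of this factor vs pooled residual".  Partial η²
  is SS_eff/(SS_eff + SS_res) per fit.  Selectivity is right-skewed and
  heteroscedastic, so the ANOVA is an omnibus summary; the directional
  claim rests on the distribution-free permutation contrast.
* **Between-variant DES**: per-trial paired deltas Δ = sel(ε=3) − sel(ε=0)
  are bootstrapped independently per variant (surrogate index included in
  the resampling unit for surrogate variants) and compared as a
  difference of means, with a bootstrap sign-crossing p.

Seeding is counter-based throughout (`SeedSequence` over integer tuples):
every disorder draw, surrogate, and resampling stream is a pure function
of (base seed, role tag, indices), so results are independent of execution
order and any single cell can be re-run in isolation bit-for-bit.

## Synthetic substrates and what they do and do not show

The motif generator emulates the *structural class* of the insect
mushroom-body benchmark — sparse divergent expansion (PN→KC) followed by
convergent readout (KC→MBON) with a target/distractor split of the
readout layer.  Defaults: 10 PN sources (fixed by the benchmark design),
a 4:1 KC expansion with each KC sampling ≈3 of 10 PNs (claw-like sparse
connectivity), 10 MBONs each receiving 20 KC inputs, split 5 targets /
5 distractors, unit weights (log-normal optional).  The KC count and
densities are this package's choice of a compact realistic instance; the
archived benchmark graph is an order of magnitude larger (243 nodes).

The stochastic-block-model proxy provides a modular large-substrate class;
its block structure is configuration, not a constant.

What passing tests on these fixtures show: the machinery — propagation,
metrics, surrogates, inference — is correct and the full protocol runs end
to end.  What they do not show: the published benchmark magnitudes.  The
disorder-enhanced-selectivity contrast is topology- and sink-placement-
specific; synthetic realizations can show strong, weak, absent, or
reversed contrasts.  The acceptance script therefore reports the contrast
computed on one fixed reference realization, and runs on real connectome
exports should use the archived graphs through the CSV ingest path.

## Problem sizes in the shipped analyses

The test suite and the acceptance script scale the ensembles to compact
instances as the package's own reporting choice: the design-shape
factorial runs the full 4100-record design with the thermal engine (the
count and ANOVA dfs are engine-independent); the open-system contrast
analysis uses the default 60-node motif with 20 trials, 10 surrogates and
a coarse output grid (dt = 2.5), which leaves the horizon readout exact.

## Known limitations

* Markovian, linear, instantaneous-sink dynamics only; no non-Markovian
  memory, nonlinear gain, or spiking.
* The commitment-cost accounting (`1/P_T` expected cycles,
  ΔE = (N − N')·E_II − E_I, spike/local cost ratio r ≈ 35) is a toy model
  exposed for exploration; the package does not simulate a commitment
  stage.
* No figure rendering; envelopes (max over κ at each ε) can mask
  multi-modal κ dependence — full grids are always available in the sweep
  table.
* The CRW rate convention (`γ·W_sym`, not degree-normalized) is a design
  choice; it keeps the baseline's topology identical to the Hamiltonian's
  and is flagged for sensitivity testing.
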