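# desnet

Open-system transport benchmarks on connectome graphs: dephasing-assisted
routing, disorder-enhanced selectivity (DES), surrogate controls, and the
resampling inference that goes with them.

## The problem

Structural connectomes are candidates for a cheap "pre-selection" stage of
decision making: a low-amplitude, wave-like flow over the fixed wiring
graph could concentrate probability mass on useful downstream readouts
before any expensive spiking commitment happens.  Whether that works
depends jointly on *coherence* (how wave-like the flow is) and *topology*
(whether the native wiring supports constructive routing).  `desnet`
simulates this regime with a mechanistically neutral open-system proxy and
asks a concrete question: does moderate node-energy heterogeneity
(disorder) *improve* the selectivity with which mass reaches target
readouts over distractor readouts — and does that improvement survive when
the native topology is destroyed?

The package is for computational/systems neuroscientists and network
scientists who want to run these benchmarks on their own weighted graphs
(node/edge CSV), or to study the phenomenon on synthetic substrates.

## The model

Transport is a GKSL (Lindblad) master equation for a density matrix ρ(t)
over the graph nodes plus one absorbing state per sink:

    dρ/dt = −i[H, ρ] + κ Σ_k (Π_k ρ Π_k − ½{Π_k, ρ})
            + Σ_s η_s (J_s ρ J_s† − ½{J_s†J_s, ρ})

* `H = −γ·L_sym + diag(E)` with `L_sym = D_sym − W_sym` the symmetrized
  weighted Laplacian (directed graphs are first row-normalized to
  transition probabilities, then symmetrized), and node energies
  `E_i ~ Uniform[−ε, +ε]` — diagonal disorder with amplitude ε.
* `Π_k = |k⟩⟨k|` are site projectors: pure dephasing at rate κ damps
  inter-node coherences, interpolating from wave-like (κ→0) to classical
  diffusive (κ→∞) transport.
* `J_s = |absorber_s⟩⟨a_s|` drains attachment node `a_s` into sink `s` at
  rate η_s.  Cumulative absorber mass at the horizon `T_end` gives the
  target and distractor captures `P_T` and `P_D`.

Readout metrics: `Selectivity_end = P_T/(P_D + δ)`, `coverage_end = P_T + P_D`,
`Utility(λ) = P_T − λ·P_D`, `InfoPerCost = Utility/(coverage_end + χ)`, and
`P_good = Pr(Selectivity_end > S_thr and P_T > pT_min)`.  Ensembles are
aggregated both as the run-level mean of ratios and as the conservative
ratio of means `SelRoM = ⟨P_T⟩/(⟨P_D⟩ + δ)`.

Controls: a continuous-time random walk (CRW) and a Metropolis thermal
walk on the same coupling matrix (dynamics-only baselines), type-aware
degree-preserving Maslov–Sneppen rewiring and class-pathway lesioning
(topology controls).  Inference: percentile bootstrap CIs (B = 5000),
a pre-specified one-sided permutation contrast ε = 3 vs ε = 0, and
cell-means ANOVA with partial η² over the variant × disorder factorial.

## Worked example

```python
from desnet import (MotifSpec, RunParams, SweepConfig, analyze_des,
                    make_mb_motif, run_benchmark_sweep)

graph, roles = make_mb_motif(MotifSpec())   # 10 PN -> 40 KC -> 10 MBON motif
cfg = SweepConfig(
    kappa_grid=(0.001, 10.0), epsilon_grid=(0.0, 1.0, 2.0, 3.0, 5.0),
    variants=("original",), n_trials=20, engine="gksl", base_seed=1,
    run_params=RunParams(dt=2.5, t_end=10.0),
)
table = run_benchmark_sweep(graph, roles, cfg)
summary = table.summary(ci_resamples=500)
cols = ["kappa", "epsilon", "selectivity_mean", "sel_rom", "coverage_mean"]
print(summary[cols].round(3).to_string(index=False))

report = analyze_des(table.records, eps_hi=1.0, eps_lo=0.0, kappa=0.001, seed=1)
res = report.permutation["original"]
print(f"\ndisorder contrast eps=1 vs 0 at kappa=0.001: "
      f"delta = {res.delta_obs:.3f}, p_perm = {res.p_perm:.4g}")
```

The run prints

```
 kappa  epsilon  selectivity_mean  sel_rom  coverage_mean
 0.001      0.0             1.067    1.067          0.082
 0.001      1.0             1.204    1.143          0.057
 0.001      2.0             0.994    0.951          0.042
 0.001      3.0             0.956    0.915          0.025
 0.001      5.0             1.092    0.961          0.011
10.000      0.0             0.910    0.910          0.002
10.000      1.0             0.913    0.913          0.002
10.000      2.0             0.914    0.914          0.002
10.000      3.0             0.904    0.903          0.002
10.000      5.0             0.901    0.900          0.002

disorder contrast eps=1 vs 0 at kappa=0.001: delta = 0.136, p_perm = 0.05509
```

Reading the table: at low dephasing (κ = 0.001) this motif realization
shows an intermediate-disorder selectivity enhancement — mean selectivity
rises from 1.07 at ε = 0 to a peak of 1.20 at ε = 1 and falls back at
larger ε — while at strong dephasing (κ = 10) the curve is flat and the
disorder response is suppressed.  Coverage (total absorbed mass) declines
with ε as disorder localizes transport.  The peak location and size are
topology- and sink-placement-specific: other motif realizations peak at
other ε or show no enhancement, which is exactly why the benchmark
protocol pairs native graphs against rewired surrogates before drawing
conclusions.

A CLI mirrors the library (`desnet fixtures / run / sweep / surrogate /
stats`); run `desnet --help`.

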