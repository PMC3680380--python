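# planarpore

Analysis toolkit for single-channel recordings from planar lipid bilayers,
built around the situation where a bilayer contains **several identical,
independently gating channels** and closings are often too brief to be
fully resolved. It bundles:

- a **synthetic recording generator**: N independent channels gating by a
  continuous-time Markov scheme with voltage-dependent rates
  k(V) = k₀·exp(V/vₑ), optional open-channel block, unitary current
  i = g·(V − E_rev), a 4-pole low-pass filter and additive Gaussian noise;
- **trace idealization** by a Gaussian-emission hidden Markov model over
  occupancy levels 0..N fitted with the Baum–Welch EM algorithm and decoded
  by Viterbi, plus the conventional 50 %-threshold comparator;
- **open-probability estimation** for multi-channel bilayers: with N
  independent identical channels the collective open probability is
  binomial, Po(N) = Po^N, so the single-channel open probability is
  recovered as **Po = Po(N)^(1/N)** from the time spent with all N channels
  simultaneously open. The occupancy-weighted threshold estimate
  Σₖ k·Tₖ/(N·T) is provided for comparison, along with dwell-time tables,
  Po–V curves and Welch tests for blocker effects;
- **permeation analysis**: Nernst and Goldman–Hodgkin–Katz reversal
  potentials, closed-form inversion of the monovalent GHK equation for
  cation:anion permeability ratios, the numeric zero-current root of the
  GHK flux sum for divalent mixtures, and concentration/Davies/tabulated
  activity models;
- **conductance analysis**: unitary-amplitude extraction from fitted level
  means, slope-conductance i–V regression, and the single-site binding
  hyperbola g(a) = g_max·a/(K_a + a) for conductance saturation.

Potentials follow the bilayer convention V = V_cis − V_trans (trans
grounded). Units at every interface: mV, pA, pS, mM; event tables in ms.

## Worked example

Invert the monovalent GHK equation for the measured reversal potential of a
K⁺-selective-ish pore in an 810 mM cis / 210 mM trans KCl gradient at 22 °C:

```python
from planarpore.iontransport import IonSpecies, SolutionPair, permeability_ratio_from_erev

pair = SolutionPair(
    species=(IonSpecies("K", 1, 810.0, 210.0), IonSpecies("Cl", -1, 810.0, 210.0)),
    temperature=295.15,
)
res = permeability_ratio_from_erev(-15.3, pair)
print(f"P_K/P_Cl = {res.ratio:.2f}")
```

```
P_K/P_Cl = 2.97
```

A reversal potential of −15.3 mV between the Nernst extremes (±34.3 mV)
means the pore passes both ions but prefers the cation about 3:1.

Simulate a 3-channel bilayer, idealize it, and estimate the single-channel
open probability both ways:

```python
from planarpore.gatingsim import EnsembleConfig, GatingScheme, RecordingConfig, simulate_experiment
from planarpore.idealization import hmm_idealize
from planarpore.gatingstats import estimate_po

ens = EnsembleConfig(scheme=GatingScheme.two_state(k_co=40, k_oc=10),  # Po = 0.8
                     n_channels=3, conductance=395.0)
rec = RecordingConfig(holding_potential=-40.0, duration=30.0)
trace, truth = simulate_experiment(ens, rec, seed=1)
record, fit = hmm_idealize(trace, n_levels=3)
est = estimate_po(record, n=3)
print(f"Po(N) = {est.po_collective:.3f}  ->  Po = {est.po:.3f}")
```

```
Po(N) = 0.527  ->  Po = 0.808
```

The bilayer spends 52.7 % of the record with all three channels open;
the binomial model converts that into a single-channel open probability of
0.808, close to the configured 0.8.

A complete simulate → idealize → Po/i–V/GHK/block run is driven by a config
file; see `examples/demo_pipeline.yaml`:

```sh
planarpore pipeline --config examples/demo_pipeline.yaml --out demo_out
```

Other CLI subcommands (`simulate`, `idealize`, `po`, `iv`, `saturation`,
`ghk`, `block`) wrap the corresponding library calls; all tables are
tab-delimited text and every trace carries a JSON metadata sidecar.

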