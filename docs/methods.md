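# Methods

## Scope and model

`planarpore` analyses voltage-clamp current recordings from planar lipid
bilayers that contain N identical, independently gating channels. All
potentials are V = V_cis − V_trans with the trans chamber grounded;
positive unitary current is carried cis → trans. Internally durations are
seconds; interfaces use mV, pA, pS, mM, and event tables use ms.

## Gating model and simulator

Each channel is a continuous-time Markov chain over states C (closed),
O (open) and B (open-channel blocked; electrically identical to C, i.e.
full occlusion). Rates take the Eyring-like form

    k(V) = k0 · exp(V / v_e)

with k0 in s⁻¹ and v_e the e-fold voltage in mV (±∞ = voltage
independent). This is the minimal form able to produce both a Po that
falls at large negative potentials and a block whose entry rate grows
e-fold per v_e mV. Blocker entry uses k0 = k_on·[blocker], k_on in
s⁻¹µM⁻¹, making the entry rate linear in blocker concentration. B is
reachable only from O (open-channel block); schemes must be irreducible
over the states touched by nonzero rates.

Trajectories are exact-time Gillespie realizations; the initial state is
drawn from the stationary distribution of the generator at the holding
potential unless a start state is forced. Per-channel dwell sequences
partition the record exactly, and the ensemble "aggregate" is the
piecewise-constant sum of open indicators over channels.

Rendering: the ideal waveform level(t)·g·(V − E_rev) is sampled at the
configured rate, passed through a causal digital 4-pole Bessel low-pass
(chosen for its flat group delay; the tests depend only on its measured
step response), and Gaussian noise of SD `noise_sd` is added *after*
filtering so that `noise_sd` is the observed baseline SD. Closures shorter
than roughly 0.33/f_c are visibly attenuated, reproducing the
"incompletely resolved closing" morphology of real bilayer records. The
causal filter delays every event by a nearly constant group delay
(`filter_delay_samples`); comparisons against ground truth should align
for it.

Defaults — sample rate 10 kHz, filter corner 1 kHz, noise SD 1 pA — are
typical bilayer acquisition values. Simulations are reproducible: one
`SeedSequence` spawns independent child streams per channel and for the
noise, so a config plus a seed regenerates every output bitwise.

What the generator does *not* emulate: baseline drift, capacitance
transients, 1/f and flicker noise, subconductance states, cooperative
gating. Tests passing on this generator therefore demonstrate estimator
and pipeline correctness under ideal stationarity, not robustness to
those artefacts.

## Idealization

The HMM route models the sampled current as a hidden Markov chain over
occupancy levels 0..L with Gaussian emissions sharing one noise SD
(homoscedastic; floored at 10⁻³ pA to prevent variance collapse).
Initialization finds the modes of the amplitude histogram smoothed at a
robust noise scale (median absolute first difference). Because an
ensemble of identical channels has equispaced level amplitudes through
the baseline, the initializer scores the hypotheses "extreme mode =
level j" and keeps the spacing that explains the most modes; rungs with
no resolved mode are filled in on that ladder and the model is flagged as
a fallback. Traces with a baseline offset should be offset-corrected
first — the ladder is anchored at 0 pA.

Fitting is Baum–Welch EM with scaled forward–backward recursions; the
log-likelihood trajectory is recorded and is non-decreasing (asserted in
the tests). The M-step re-estimates initial distribution, transition
matrix, level means (free by default; an optional `linear` constraint
ties mean_k = k·i_unit for low-data traces) and the shared variance.
Decoding is the Viterbi MAP path (per-sample posterior argmax available
behind a flag), with ties broken toward the lower level — conservative
for open probability. The inner loops are numba-compiled; a 30-s 10-kHz
trace fits in about a second.

The conventional comparator assigns each sample the level whose band
(k ± ½)·i_unit contains it — 50 % thresholds — and run-length encodes
the result.

## Open probability

With N independent identical channels, the probability that all N are
open simultaneously is binomial: Po(N) = Po^N. `po_collective` measures
Po(N) as the fraction of the record spent at level N; `po_binomial`
inverts the binomial model, Po = Po(N)^(1/N). The equation is the unique
inverse consistent with the binomial statement and the definitions of
Po(N) and N. N itself is estimated as the maximum number of coincidentally
open channels observed — an estimator that can only undercount; a
user-supplied larger N overrides it with a logged warning.

The conventional estimate Σₖ k·Tₖ/(N·T) (occupancy-weighted mean open
fraction) is implemented as `po_threshold_method`, applicable to any
idealized record. Dwell-time summaries exclude the first and last
segments, whose durations are censored by the record boundaries. Blocker
comparisons use Welch's unequal-variance t test (the variance of Po
estimates differs between blocked and unblocked groups by construction)
at α = 0.005 by default.

### Estimator comparison under incomplete resolution

On records whose closures are mostly shorter than the filter rise time,
both idealization routes mis-time events: the 50 %-threshold route misses
every excursion that stays above half amplitude, while the HMM route
detects nearly all of them (its EM-adapted sub-level mean sits at the
attenuated excursion amplitude) but assigns each the duration of its
filter-spread excursion, overcounting closed time. Holding the idealized
record fixed, the binomial estimate has absolute bias at most that of the
occupancy-weighted estimate — the occupancy weighting is additionally
exposed to mis-timed occupancy at every level below N, whereas Po(N) uses
only the level-N dwell time — and the acceptance suite verifies this
paired over 50 seeds. Correcting the duration overcount itself would
require missed-event (time-interval-omission) correction, which is out of
scope here.

## Permeation

Physical constants R and F live in `iontransport`; the thermal voltage
RT/F is derived from them (25.43 mV at the 295.15 K default — 22 °C).

- `nernst`: E = (RT/zF)·ln(a_trans/a_cis).
- `ghk_voltage_monovalent`: the GHK voltage equation over monovalent
  cations and anions; reduces to Nernst when one permeability is nonzero.
- `permeability_ratio_from_erev`: closed-form inversion for a two-ion
  cation/anion pair. With x = exp(E_rev·F/RT), P_cat/P_an =
  (a_an,cis − x·a_an,trans)/(x·a_cat,cis − a_cat,trans); feasible iff
  E_rev lies strictly between the two Nernst potentials. Round-trips with
  the forward equation to 1e-9 relative. The user-supplied junction
  potential is subtracted from the measured E_rev before inversion.
- `ghk_current_reversal`: for mixtures with divalents no closed form is
  assumed; the unique root of the summed GHK constant-field fluxes
  I_i ∝ P_i z_i² V (a_cis − a_trans e^(−z_i VF/RT))/(1 − e^(−z_i VF/RT))
  is bracketed in ±200 mV and refined by Brent's method to ≤1e-6 mV,
  with the removable V = 0 singularity handled by series expansion.

Activity models: `concentration` (identity; the default, since measured
ratios are conventionally quoted either way), `debye_huckel` (Davies
equation with a temperature-dependent A coefficient), and `table`
(interpolated measured mean activity coefficients for KCl and CaCl₂,
25 °C values; no extrapolation beyond the tabulated range). The Davies
approximation tracks the measured KCl coefficient to within about 5 % at
0.2 M, which is the scale of the concentration-vs-activity ambiguity in
any quoted permeability ratio.

## Conductance fitting

Unitary current is extracted by regressing the fitted level means on the
level index over the levels actually visited (identical to the mean
adjacent-level spacing when levels are equidistant). The i–V relation is
fitted by ordinary least squares (optional 1/SEM² weighting); the slope
in pA/mV × 1000 is the conductance in pS and the zero crossing the
reversal potential, with delta-method standard errors. The
conductance–activity relation is fitted by the single-site binding
hyperbola g(a) = g_max·a/(K_a + a) via bounded least squares from three
deterministic starts (the likelihood is nearly flat in g_max/K_a for
non-saturating data, where K_a lands far above the tested range —
reported as fitted, with its standard error).

## Problem sizes

The acceptance suite and `scripts/acceptance.py` use the protocol sizes
the analyses were designed around: i–V arms of eight voltages (±10 to
±40 mV) × 30 s × 5 seeds; estimator validation on 50 × 60-s records;
blocker comparisons of 6 recordings × 10 s per group, replicated over 10
seed sets. These sizes give Monte-Carlo standard errors well inside each
check's tolerance.

## Known limitations

- No missed-event or dwell-time–omission correction; dwell statistics
  near the filter dead time are biased accordingly.
- The HMM assumes homoscedastic Gaussian noise and a stationary chain;
  drifting baselines must be corrected upstream.
- `estimate_n` is downward-biased for low-Po ensembles (a channel that
  never opens is invisible).
- The activity tables stop at 1 M salt; stronger solutions raise an error
  rather than extrapolate.
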