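# Methods

## The measurement problem

Two fluorescence channels are recorded per region of interest (ROI): a
cytosolic calcium indicator and a mitochondrially targeted one, sampled at
2 Hz (layer-1 dendrites) or 1 Hz (layer-2/3 somas). Cytosolic transients
are frequent, bright (tens of % ΔF/F) and short (seconds); mitochondrial
transients are roughly ten-fold rarer, rise within 2–3 s, and last tens of
seconds to minutes. The scientific quantity of interest is the *coupling*
between them: which cytosolic transients trigger a mitochondrial response,
with what latency, and how that coupling probability depends on behavioural
state and on the recent history of cytosolic activity.

## Trace processing

ΔF/F₀ = (F − F₀)/F₀ × 100, in percent throughout. Two baseline estimators:

- **fixed_window** — F₀ is the mean of a 2-s window (default the first 2 s).
  Exact when that window is event-free; the pipeline uses it for records up
  to 60 s (short in vitro trials).
- **running_percentile** — F₀ is a centred rolling 10th percentile
  (window shrinking at the edges), recentred upward by z₀.₉·σ̂ where σ̂ is a
  robust raw-noise SD from median absolute first differences. Without the
  recentring a low percentile sits ~1.28 σ below the quiescent mean and the
  detection threshold would effectively drop to ~1.7 σ. The σ̂-based offset
  (rather than, say, the median trace-minus-percentile gap) stays correct
  even when long mitochondrial plateaus cover most of the record.

The pipeline uses per-channel windows: 60 s for the cytosolic channel and
600 s for the mitochondrial one. A single 60-s window sits *inside* a
median-length (90 s) mitochondrial transient, absorbs its pedestal into the
baseline, and fragments the event; the mitochondrial window must be a few
times the typical event duration.

Baseline noise σ is estimated as 1.4826·median(|ΔF/F first differences|)/√2:
unbiased for white Gaussian noise, insensitive to slow trends and to sparse
event pedestals (events occupying ≲20 % of samples bias it ≤10 %).

## Detection

A candidate transient is a maximal run of samples with ΔF/F > 3 σ. Its
offset is extended forward while the trace stays above 1 σ (hysteresis:
long mitochondrial decays hover near threshold and would otherwise
fragment). Candidates whose subthreshold interlude is shorter than a merge
gap fuse (0.5 s for the cytosolic channel; 5 s for the mitochondrial one,
where true inter-event intervals are minutes and sub-5-s dips are noise
dropouts). A candidate is accepted iff duration = offset − onset is
*strictly* greater than 1 s, with onset/offset the first/last suprathreshold
sample times. σ is floored at 0.1 % ΔF/F so noiseless synthetic traces do
not yield a degenerate zero threshold. Events touching the final sample are
flagged truncated but kept.

Consequences worth knowing: at 1 Hz the duration rule requires three
suprathreshold samples, so genuine transients shorter than ~2 s are
invisible; at 2 Hz the floor is ~1.3 s. This is a property of the published
rule, not of the implementation, and it biases downstream ratio statistics
(see *Recovered statistics and their biases*).

Staircase sub-steps are located by a step contrast — forward 2-s mean minus
backward 2-s mean — with one step per maximal run of contrast above 3 σ,
the first run being the event's initial rise (always step 1), and steps
closer than 2 s to the previous one suppressed.

## Kinetic typing

Metrics are computed on the event segment: the *effective peak* is the
first time a 2-s-smoothed copy reaches 95 % of its maximum (the raw argmax
of a flat noisy plateau lands anywhere on it); *decay_fraction* =
(peak − end)/peak over a window of min(30 s, 80 % of the post-peak span
above threshold) — measuring the span above the detection level keeps the
endpoint off the terminal fall of short plateaus; *monotonicity* is the
Spearman correlation of the post-peak segment with time. Precedence:

1. **staircase** if ≥ 2 steps;
2. **plateaued** if decay_fraction < 0.25 and monotonicity > −0.5 (a very
   slow but steady decline is regular, not plateaued);
3. **regular** if decay_fraction ≥ 0.5 or monotonicity ≤ −0.5;
4. **unclassified** otherwise, or with < 10 post-peak samples.

The numeric cutoffs are operationalizations of qualitative classes; they
are parameters with frozen defaults. On noiseless canonical waveforms the
confusion matrix is the identity (tested over 210 events); at 1 % noise and
amplitudes ≥ 20 % per-class recall exceeds 0.9.

## Pairing and fidelity

A mitochondrial event pairs with the cytosolic event of latest onset in
[onset − L_max, onset + 1 s]; L_max defaults to 3 s (dendrite), 6 s (soma),
8 s (in vitro) — bounds on the typical observed latencies with slack. Ties
break toward the larger amplitude; one cytosolic event triggers at most one
mitochondrial event; unmatched mitochondrial events are orphans. The 1-s
pre-window tolerates onset-detection jitter (small negative latencies are
kept and flagged).

Coupling fidelity is N_mito/N_cyto × 100 % per (ROI × stage), counts pooled
over an ROI's trials; a staircase counts once (an option counts
initiations — first rise plus steps — which is the unbiased trigger count
when long transients absorb later triggers as steps). Fidelity is undefined
at N_cyto = 0; values over 100 % are flagged.

## History windows and statistics policy

Eight 5-s half-open windows, [−20, −15) … [15, 20) s relative to each
mitochondrial onset; a cytosolic event is assigned by its onset, windows
extending beyond the record are dropped (and counted). The trigger event
itself therefore falls in [−5, 0); an exclusion flag is not applied by
default. Window contrasts and all group comparisons go through one policy:
Shapiro–Wilk on every group at α = 0.05; all normal → t-test (2 groups) or
ordinary ANOVA with Šídák post hoc; otherwise Mann–Whitney or
Kruskal–Wallis with Dunn's rank post hoc (tie-corrected, Šídák-adjusted,
implemented in-package). Groups need n ≥ 3; the chosen branch is always
reported. The two-group null rejection rate is calibration-tested to
[0.03, 0.07] at α = 0.05. SEMs in reports are over ROI-level values, not
events.

## The generator

Cytosolic events are an inhomogeneous Poisson process with per-stage
constant rates and i.i.d. log-normal marks: amplitudes median 30 % (σ_log
0.4), durations median 2.5 s (σ_log 0.6) — under 5 % of drawn durations
exceed 8 s. Mitochondrial amplitudes are log-normal median 40 % (σ_log
0.4), durations median 90 s (σ_log 0.5) — about 78 % last ≥ 60 s. Rise
times: 1 s (cyto), 2.5 s (mito). Defaults are calibrated to the
distributional statements the analyses target and are all overridable.

**Duration semantics.** A drawn duration is the width of the clean waveform
above a 3 % ΔF/F reference level — the detection-relevant width under the
default 1 % noise — because the duration models describe *measured*
transient durations. Waveforms are rise → hold → exponential decay with the
decay constant set so the downward reference crossing lands at
onset + duration, followed by a faster sub-threshold tail (τ = 1.2 s cyto,
1.5 s mito — indicator-scale decay) so that near-threshold residuals do not
linger and fragment detection. Regular mitochondrial events decay from the
peak; plateaued ones hold until ~4.5 s before the end and fall with
τ = 1.5 s; staircase events superpose one plateau-like component per step.
Overlapping cytosolic events superpose additively (linear-range indicator).

**Coupling.** In Bernoulli mode each cytosolic event independently triggers
with its stage's probability p; the transient initiates after a
gamma(2, 1.05 s) latency (mean 2.1 s). A trigger landing inside an ongoing
mitochondrial transient becomes a staircase step — mitochondrial transients
do not overlap. Kinetic types are otherwise drawn ⅓/⅓/⅓; an event drawn as
staircase recruits one or two non-triggering cytosolic events inside its
span as step triggers (links flagged `triggered=False`, so the Bernoulli
success fraction remains exactly p), falling back to regular/plateaued when
none exists. In integrator mode a CaMKII-like activity
a ← a·e^(−dt/τ_a) + k·c(t)·dt fires a transient at each upward crossing of
θ; crossings during an ongoing transient add steps; latency is the crossing
time minus the most recent cytosolic onset. The in vitro preset (τ_a = 3 s,
unit impulse gain, θ = 31) first crosses threshold with a 5-s train at
13 Hz; θ is the one calibrated constant, chosen so the deterministic scan
reproduces that measured threshold. For an n-impulse train at f Hz the peak
activity has the closed form (1 − rⁿ)/(1 − r), r = e^(−1/(f·τ_a)), which
the recursion matches to machine precision.

Noise is additive Gaussian on the raw signal, σ = noise_sigma_pct of the
baseline fluorescence (default 1 %); an optional sinusoidal drift is off by
default. Events whose onset falls within 3 s of a trial's end are
discarded (unmeasurable). Presets: REST-DEND / RUN-DEND (2 Hz dendrites,
rates 0.5 / 1.0 per min, p = 0.033 / 0.193), REST-SOMA / RUN-SOMA (1 Hz
somas, 0.33 / 0.66 per min, p = 0.035 / 0.139), TRIAL-DEND / TRIAL-SOMA
(the 300-frame trial protocol with the middle third stimulated, rest
parameters outside it), INVITRO (integrator mode). RUN presets are
sustained single-stage conditions; multi-stage schedules are rendered as
separate per-trial acquisitions.

What the generator does *not* emulate: photon shot noise, bleaching,
indicator binding kinetics and saturation, motion artifacts, ROI
heterogeneity (all ROIs of a session share one rate and one p), burst-like
clustering of cytosolic events, and any dependence of coupling on cytosolic
amplitude or duration (marks and triggers are independent by default).
Passing recovery tests therefore demonstrate correctness of the analysis
chain under these idealized conditions, not robustness to every property of
real recordings.

## Recovered statistics and their biases

The recovery experiments (`mitocoupling.recovery`, exercised by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use 60 ROIs per
fidelity condition (600 s dendritic, 900 s somatic), 1000 60-s in
vitro-style trials for latency (≥ 500 coupled pairs), 100 soma-hours for
the rate, and the deterministic integrator scan; sizes chosen so each
experiment runs in seconds while leaving Monte-Carlo error well inside the
comparison bands.

Three biases are intrinsic to the per-ROI mean of N_mito/N_cyto and worth
stating because they act on real data exactly as on synthetic:

1. **Detection floor** (inflates). Cytosolic transients below the sampling
   floor of the >1-s rule are not counted: the denominator is undercounted
   by ~13 % at 2 Hz and ~24 % at 1 Hz under the default duration model,
   scaling measured fidelity by ~1/0.87 and ~1/0.76 respectively.
2. **Small-count ratio bias** (inflates). E[M/N] > E[M]/E[N] for the small
   per-ROI counts involved (a few cytosolic events per ROI and stage);
   with ~7 detected events per ROI this adds ~10 %.
3. **Busy-period censoring** (deflates). At high trigger rates a new
   trigger often lands inside an ongoing ~100-s transient and becomes a
   staircase step, so transient counting undercounts triggers — a ~28 %
   loss under sustained running-dendrite conditions, ~13 % for running
   somas, negligible at rest.

For resting and running dendrites the biases roughly cancel; for running
somas (1 Hz) the floor and ratio inflation dominate the weaker censoring,
and the recovered per-ROI mean fidelity runs ~1.2–1.4× above the generator's
p = 0.139 (typically 16–21 % across seeds). The initiation-counting option
removes the censoring but not the floor. A pooled-count fidelity
(ΣN_mito/ΣN_cyto) removes the ratio bias and is available as an option;
per-ROI averaging is the default because figure-level summaries are
conventionally per-ROI.

## Numerical and degenerate-input choices

Half-open intervals everywhere (stages, windows); an event belongs to its
onset's stage. Strict inequalities in detection (>3 σ, >1 s) per the
published rule. Float CSV round-trips at 10 significant digits. Constant
traces: noise estimate 0, ΔF/F 0, degenerate group comparisons return
p = 1. Shapiro–Wilk on a zero-variance group counts as non-normal. Unknown
config keys are hard errors. All simulation randomness flows from one
seeded generator; identical (config, seed) give byte-identical artifacts.
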