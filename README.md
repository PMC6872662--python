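# mitocoupling

Analysis of mitochondrial-to-cytosolic Ca²⁺ transient coupling in
two-channel fluorescence recordings.

In cortical pyramidal neurons, mitochondrial-matrix Ca²⁺ ([Ca²⁺]_mito,
reported by a mitochondrially targeted green indicator) rises in discrete
transients that are triggered by ongoing cytosolic Ca²⁺ ([Ca²⁺]_cyto, red
indicator) transients — but only probabilistically: at rest only a few
percent of cytosolic transients recruit a mitochondrial response, and the
fraction rises several-fold with behavioural activity. This package
implements the full analysis chain for that phenomenon, for anyone working
with paired cytosolic/mitochondrial calcium recordings (two-photon in vivo
imaging at 1–2 Hz, or in vitro confocal):

- **ΔF/F₀ conversion** — ΔF/F₀ = (F − F₀)/F₀ × 100 %, with a fixed 2-s
  baseline window (short traces) or a recentred running 10th-percentile
  baseline (long traces).
- **Transient detection** — a transient is a maximal run of samples
  exceeding 3 × the baseline-noise SD with duration strictly greater than
  1 s (hysteresis at 1 σ for the offset; sub-sample dropouts merged).
- **Kinetic typing** of mitochondrial transients into *regular* (monotonic
  post-peak decline), *plateaued* (stable elevation) and *staircase*
  (multiple upward steps, each step linked to a distinct cytosolic event).
- **Pairing and coupling fidelity** — each mitochondrial onset is paired to
  its most recent cytosolic trigger within a compartment-specific window;
  coupling fidelity = N_mito / N_cyto × 100 %.
- **Peri-onset history windows** — counts, amplitudes and durations of
  cytosolic transients in eight 5-s windows centred on each mitochondrial
  onset ([−20, 20) s).
- **Stage-resolved statistics** — pre-run/run/post-run partitioning,
  per-minute (soma) or per-1000-µm²-per-minute (dendrite) frequencies, and
  a normality-gated test policy (t / Mann–Whitney; ANOVA + Šídák or
  Kruskal–Wallis + Dunn).
- **A synthetic session generator** with full ground truth: cytosolic
  events as a rate-modulated marked Poisson process, Bernoulli or
  CaMKII-like leaky-integrator coupling (a(t) decaying with τ_a and charged
  by ΔF/F; a transient fires when a crosses θ), three mitochondrial
  waveform families, Gaussian photon noise.

## Worked example

```python
import mitocoupling as mc

cfg = mc.get_preset("RUN-DEND")          # running dendrites, 2 Hz
recordings, truth = mc.simulate_session(cfg, n_rois=40, duration_s=600.0, seed=1)
tables = mc.analyze_session(recordings)  # dF/F -> detect -> type -> pair

fid = tables["fidelity"]
ok = fid[fid["defined"]]
print(f"mean fidelity {ok['fidelity_pct'].mean():.1f}% over {len(ok)} ROIs")
print(tables["events"]["kinetic_type"].value_counts())
```

prints (seed 1):

```
mean fidelity 18.5% over 40 ROIs
kinetic_type
not_applicable    343
staircase          25
regular            17
plateaued          16
Name: count, dtype: int64
```

i.e. roughly one in five running-stage cytosolic transients recruited a
mitochondrial transient (the generator's per-event trigger probability for
this preset is 0.193), and the mitochondrial transients split roughly
evenly between the three kinetic families. The numbered scripts under
`analysis/` run the same machinery as a narrative: `01` simulates the
session types, `02` detects and types events against ground truth, `03`
computes fidelity and coupled-vs-uncoupled contrasts, `04` measures
latency and the eight-window history profile, `05` scans the integrator's
frequency threshold.

There is also a CLI:

```
mitocoupling simulate --config config.yaml --seed 1 --out run/
mitocoupling analyze  --config config.yaml --seed 1 --out run/
mitocoupling report   --config config.yaml --seed 1 --out run/
```

Identical (config, seed) produce byte-identical artifacts; unknown config
keys are errors.

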