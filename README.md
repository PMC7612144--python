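# cmquant

Quantification toolkit for cardiac microtubule-detyrosination studies. It
re-implements, as a tested and reusable pipeline, four bespoke measurement
procedures used to quantify how the detyrosinating enzyme complex
VASH2/SVBP gains access to the cardiomyocyte microtubule network and what
that does to contraction:

* **Two-channel STED colocalization** (`cmquant.coloc`) — dynamic HSV
  thresholding (signal iff h ∈ [0,180], s ∈ [0,43], v ∈ [k+30, 220], where
  k is the background-adjusted mean), adaptive Gaussian denoising (5×5 for
  the filament channel when k ≥ 35, else 3×3), and per-cell metrics: pixel
  counts v, t, overlap o, on-microtubule fraction o/v, off fraction
  (v−o)/v, Pearson correlation ρ of the two denoised channels, and VASH2
  mean fluorescence intensity.
* **Puncta quantification** (`cmquant.puncta`) — MAP4 oligomer puncta as
  8-connected components with equivalent-circle diameter
  2·√(area/π)·pixel_size > 400 nm, counts normalized to cell area.
* **Contraction and calcium kinetics** (`cmquant.kinetics`) — per-beat
  resting/peak sarcomere length, % shortening, maximum departure/return
  velocities (dSL/dt) and time to peak for 2 Hz-paced cells; Fura-2
  360/380 ratio basal, amplitude, release/reuptake speeds, elevation and
  50 %-decay reuptake times.
* **Densitometry** (`cmquant.densitometry`) — two-step band normalization
  (Norm1 = band/marker, Norm2 = Norm1 / control-group mean, per gel), band
  ratios, and co-sedimentation dose–response summaries.
* **Statistics** (`cmquant.stats`) — two-tailed Pearson correlation test
  (t = r·√(n−2)/√(1−r²), df = n−2) and two-tailed unpaired t-test.

Every input the pipelines consume can be generated with attached ground
truth by `cmquant.simulate` (filament + puncta STED fields with a known
on-filament fraction, paced traces with closed-form kinetics, gel tables,
a lattice competition model), so the whole toolkit is testable without
microscope or photometry hardware. See `docs/methods.md` for the models,
defaults and their rationale.

## Worked example

```python
from cmquant import simulate
from cmquant.coloc import analyze_cell

params = simulate.StedSimParams(true_frac_on=0.8, seed=1)
fx = simulate.simulate_sted_pair(params)          # two channels + truth
result, k_vash2, k_tubulin = analyze_cell(
    fx.vash2_channel, fx.tubulin_channel, fx.cell_roi)
print(f"true frac_on  {fx.truth_frac_on:.3f}")
print(f"est. frac_on  {result.frac_on:.3f}  (o={result.o}, v={result.v})")
print(f"frac_off      {result.frac_off:.3f}   PCC {result.pcc:.3f}")
```

prints

```
true frac_on  0.800
est. frac_on  0.764  (o=1086, v=1422)
frac_off      0.236   PCC 0.336
```

i.e. on this simulated field 76.4 % of VASH2 signal pixels lie on the
segmented microtubule network against a constructed truth of 80 %, and the
two denoised channels correlate at ρ = 0.34.

The same stages run from the shell:

```sh
cmquant simulate --kind sted --seed 1 --out fixtures/ --n-cells 3
cmquant run --config run.yaml --stage imaging   # coloc_metrics.csv + report
cmquant simulate --kind sarcomere --seed 2 --out traces/
cmquant kinetics --trace traces/sarcomere_trace.csv --kind sarcomere --out kin.csv
```

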