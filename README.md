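# myomet

Voxel-based muscle morphometry, countermovement-jump mechanography,
single-voxel ¹H-MRS lipid quantification, and the decomposition of
age-related muscle power loss — with a synthetic-cohort generator so the
whole pipeline is testable end to end with known ground truth.

## The scientific problem

Ageing muscle loses power (**dynapenia**) through three distinguishable
mechanisms:

* **sarcopenia** — loss of muscle volume,
* **myosteatosis** — replacement of contractile tissue by intramuscular
  adipose tissue,
* **sarcosthenia** — an intrinsic, volume-invariant loss of
  power-generating capacity.

`myomet` implements the measurement chain needed to separate them:

1. **Morphometry** (`myomet.morphometry`). A muscle segmentation is a table
   of voxels (three integer grid coordinates plus a fat fraction, FF, in %
   of the total ¹H signal; grid 1.17 × 1.17 × 5.0 mm). Volume is
   `count × voxel size`; lean volume is `V · (100 − FF)/100`. Each muscle
   is split into a **peripheral shell** (the most proximal and distal
   slices plus a 2-voxel ≙ 2.34 mm in-plane outer ring) and a **centre**,
   because intramuscular fat accumulates preferentially at the periphery.
   The glutei + quadriceps + triceps surae matrices are summed into the
   jumping-muscle composite. Muscles averaging ≥ 25% fat are flagged as
   outliers and excluded from group statistics.
2. **Mechanography** (`myomet.mechanography`). From a vertical
   ground-reaction-force trace sampled at 800 Hz: body mass = quiet-standing
   force / 9.81; a(t) = F(t)/m − g; v(t) by trapezoidal integration from
   rest; P(t) = F(t)·v(t); **peak power before take-off**, median of three
   jumps per subject.
3. **Spectroscopy** (`myomet.spectroscopy`). The soleus ¹H spectrum is
   modelled as three damped complex exponentials — water and the split
   methylene lipid resonance (extramyocellular EMCL at 1.5 ppm,
   intramyocellular IMCL at 1.3 ppm) — fitted by bounded prior-knowledge
   least squares in the time domain; lipids are reported as % of the total
   ¹H signal.
4. **Statistics** (`myomet.stats`). Pooled-SD Cohen's *d*, summary-statistic
   t-tests with Bonferroni correction, OLS of peak power (kW) on composite
   volume (ml) with slope in W/ml, an ANCOVA-style test for unequal slopes
   between age groups, and the dynapenia decomposition

   ```
   sarcopenia   [W] = (V_young − V_old) · slope
   myosteatosis [W] = (lipid_old − lipid_young) · slope
   sarcosthenia [W] = total decline − sarcopenia − myosteatosis
   ```

5. **Synthetic cohort** (`myomet.synthetic`). Generates the four-group
   cohort (young/old × athlete/control, n = 10/12/10/11) with muscle maps
   whose shell/centre FF follow the published group means ± SD, jump traces
   with a closed-form trajectory and hence an analytic peak power, and FIDs
   with known amplitudes — all pure functions of (spec, seed).

## Worked example

```python
from myomet.stats import CompositeMeans, dynapenia_decomposition

dec = dynapenia_decomposition(
    young=CompositeMeans(volume_ml=5758, lean_volume_ml=5614, peak_power_kw=4.55),
    old=CompositeMeans(volume_ml=5285, lean_volume_ml=4988, peak_power_kw=3.02),
    slope_w_per_ml=0.89,
)
print(f"total decline : {dec.total_decline_w:.0f} W")
print(f"sarcopenia    : {dec.sarcopenia_w:.0f} W  ({dec.volume_deficit_ml:.0f} ml x 0.89 W/ml)")
print(f"myosteatosis  : {dec.myosteatosis_w:.0f} W  ({dec.lipid_increase_ml:.0f} ml extra lipid)")
print(f"sarcosthenia  : {dec.sarcosthenia_w:.0f} W  ({dec.pct_sarcosthenia:.0f}% of the decline)")
```

prints

```
total decline : 1530 W
sarcopenia    : 421 W  (473 ml x 0.89 W/ml)
myosteatosis  : 136 W  (153 ml extra lipid)
sarcosthenia  : 973 W  (64% of the decline)
```

i.e. of the ~1.5 kW power gap between young and old athletes, the missing
473 ml of muscle explains 421 W and the extra 153 ml of intramuscular
lipid another 136 W — leaving 64% of the deficit to intrinsic muscle
weakness (sarcosthenia).

The measurement chain on synthetic data:

```python
from myomet import morphometry as mo, mechanography as me
from myomet.synthetic import JumpSpec, generate_jump_trace, generate_muscle_map

m = generate_muscle_map("gluteus_maximus", 80.0, 27.9, 11.1, noise_sd=1.0, seed=1)
s = mo.summarize(m)
# volume 80.0 ml  FF 17.9%  shell 27.9%  centre 11.1%  lean 65.7 ml

trace, truth = generate_jump_trace(JumpSpec(body_mass_kg=80.0, dip_depth_m=0.30))
res = me.peak_power(trace)
# mass 80.0 kg  peak power 2.682 kW  (ground truth 2.682 kW)
```

## Command line

One entry point with per-stage subcommands:

```sh
myomet morphometry --voxels DIR --out summary.csv [--shell-thickness 2] [--exclude-ff 25]
myomet jump --trace a.csv --trace b.csv --trace c.csv --out result.json
myomet mrs --fid fid.csv --out quant.json
myomet stats --summaries summaries.csv --out stats.csv
myomet decompose --young young.json --old old.json --slope 0.89 --out dec.json
myomet pipeline all [--config run.yaml] [--seed 1] [--out outdir]
```

`myomet pipeline all` generates the default 43-subject cohort (on a
coarsened 2.34 × 2.34 × 10 mm grid for speed) and writes
`cohort/subjects.csv`, `morphometry.csv`, `jumps.csv`, `mrs.csv`,
`group_summaries.csv`, `stats.csv`, `regression.json`,
`decomposition.json`, `report.md` and `manifest.json`. Runs are
byte-reproducible for a fixed seed.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch at the given seed (cohort
generation through the fitted regressions and decomposition; intermediate
artifacts under `scratch/`) and writes the target report to `--out`.

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
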