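# Methods

This note records the models implemented in `myomet`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Morphometry

**Representation.** A muscle is a set of 0-based integer grid voxels with
one fat-fraction (FF) value each, on an anisotropic grid (default
1.17 × 1.17 × 5.0 mm; `k` indexes the trans-axial slice direction).
Duplicate coordinates are rejected; FF must lie in [0, 100] % of the total
¹H signal. Raw segmentation exports carrying 0–1000 grey values are
converted to percent by /10 (0.1 % precision).

**Volume and means.** Volume is voxel count × voxel size (1 ml =
1000 mm³). Mean FF is the unweighted mean over voxels — all voxels have
equal volume, so this is the tissue mean. Lean volume is
`V · (100 − FF)/100`.

**Shell/centre partition.** The peripheral shell is (a) every voxel on the
minimal- and maximal-`k` occupied slices, plus (b) on intermediate slices,
voxels whose in-plane distance to the nearest non-muscle grid cell is ≤ 2
voxels (2.34 mm). The distance is Chebyshev (8-connected) by default,
implemented as two iterations of binary erosion with a 3 × 3 structuring
element; a city-block (4-connected, cross-shaped element) variant is
available via `connectivity="cityblock"` — the two differ only on
diagonal steps. Background is defined per muscle: any cell not in that
muscle's own voxel set counts as background, so neighbouring muscles do
not shield the shell. Partition correctness is tested against an
independent brute-force per-voxel distance scan.

**Composites.** Muscle matrices of one subject are summed by voxel-set
union (overlaps are an error — segmentations must be disjoint). Composite
FF is therefore the voxel-count-weighted mean of the member means, which
equals the plain mean over the union map; both routes are tested against
each other.

**High-fat exclusion.** Muscles whose mean FF reaches 25 % (inclusive
boundary) are flagged; the threshold is configurable. Rationale: muscles
averaging 25–40 % fat are pathological outliers relative to the
surrounding musculature and distort group statistics.

## Mechanography

Body mass is the mean force over a quiet-standing window (≥ 0.5 s; force
SD ≤ 5 N, else "not quiet") divided by g = 9.81 m/s². Net
centre-of-mass acceleration is `a(t) = F(t)/m − g`: gravity **must** be
subtracted, because integrating the raw `F/m` would give a non-zero
velocity during quiet standing. Velocity is the trapezoidal cumulative
integral from the trace start (v = 0 at rest); no drift correction or
smoothing is applied (traces are short and synthetic traces are clean).
Power is `F · v`; take-off is the first sample with force below 10 N
(configurable); the reported peak power is the maximum of `P` at or
before take-off, in kW; the per-subject value is the median over the
three recorded jumps.

## Spectroscopy

The FID is modelled as three damped complex exponentials (Lorentzian
lineshape) — water, EMCL and IMCL — with a single shared zero-order
phase and first-order phase fixed at 0:

```
s(t) = exp(iφ₀) Σₖ Aₖ exp(−dₖ t) exp(i 2π fₖ t),  fₖ = (ppmₖ − ppm_ref) · f₀[MHz]
```

Default shifts are water 4.7, EMCL 1.5, IMCL 1.3 ppm (the standard
muscle-spectroscopy convention; configurable). The fit is bounded
trust-region least squares on the stacked real/imaginary residual:
amplitudes ≥ 0, frequencies within ±0.15 ppm of the priors, the
EMCL−IMCL separation constrained to [0.1, 0.3] ppm (re-parameterised as
IMCL position + separation, so the constraint is a box), dampings in
[0.1, 500] s⁻¹. A fit whose separation lands on a bound is flagged — the
two lipid components could not be resolved. Non-convergence after
bounded jittered restarts raises an error carrying the best residual.
This is a prior-knowledge simplification in the spirit of time-domain
quantification, not a re-implementation of any particular software.
Amplitudes are relative within one acquisition (no echo-time
back-extrapolation), matching the "% of total ¹H signal" reporting:
`EMCL% = 100·A_EMCL/(A_water + A_EMCL + A_IMCL)`.

**Noise convention.** The generator's `noise_sd` is the standard
deviation of the circularly-symmetric complex noise, i.e. `noise_sd/√2`
per real/imaginary component. This matters quantitatively: at "1 % of
the water amplitude" noise, the numeric Cramér–Rao bound for the default
model (amplitudes 90:7:3, dampings 20/50/25 s⁻¹, 1024 points at 2 kHz)
puts the IMCL median relative error at ≈ 3.9 % under this convention and
≈ 5.5 % under a per-component reading; the implemented fit attains the
bound. The recovery guarantee (median amplitude error < 5 % over 100
noise realisations) is therefore a statement about the complex-SD
convention.

## Statistics

* **Cohen's d** uses the df-weighted pooled SD with no small-sample
  (Hedges) correction — "the common standard deviation" is read as plain
  pooling.
* **Two-sample tests** operate on (mean, SD, n) summaries (Student pooled
  by default, Welch optional); per-subject repeated-measures modelling is
  deliberately out of scope because the published record only carries
  group summaries.
* **Bonferroni**: `p_adj = min(1, m·p)`, `m` defaulting to the number of
  p-values.
* **Power–volume regression** is OLS of peak power (kW) on composite
  volume (ml); the slope is reported in W/ml. Note the unit trap: a slope
  of "0.89" must be W/ml for the worked decomposition to be coherent
  (473 ml × 0.89 W/ml ≈ 421 W).
* **Slope difference** between age groups is the F-test of the
  group × volume interaction: common-slope ANCOVA (volume + group
  intercepts) versus separate slopes, via OLS model comparison.
* **Dynapenia decomposition**: with group-mean composite volume V, lean
  volume L and peak power P per age class, sarcopenia =
  (V_y − V_o)·slope, myosteatosis = ((V_o − L_o) − (V_y − L_y))·slope,
  total = (P_y − P_o)·1000 W, sarcosthenia = the remainder. The identity
  `sarcopenia + myosteatosis + sarcosthenia = total` is exact by
  construction (up to floating-point re-association); a negative total is
  computed as-is and flagged. Percent contributions use the total as
  basis. Percent differences between groups elsewhere take an explicit,
  caller-chosen basis group.

## Synthetic cohort — what it emulates, and what it does not

**Muscle maps.** Shape is an elliptic cylinder (in-plane aspect 0.7) with
end slices tapered to 0.6 of the radius, guaranteeing ≥ 3 slices so the
partition is never degenerate. The in-plane radius is solved by bisection
so the voxel count matches the nominal volume within 2 % (a request that
cannot be met on the grid — e.g. sub-voxel volumes — raises). The FF
field equals the centre value deep inside and the shell value on the
partition's own shell (end slices + 2-voxel Chebyshev ring): the
generator and the analyzer share the partition *definition*, which makes
the generating means exactly recoverable in the noiseless limit — the
partition itself is validated against an independent brute-force oracle,
so this coupling is a definition, not a circular test. Per-voxel Gaussian
noise (default SD 1 %-point) is added, values are clipped to [0, 100] and
quantised to the 0.1 % export precision. Not emulated: realistic anatomy,
partial-volume effects, spatially correlated noise, inter-muscle fat
infiltration patterns. A green recovery test therefore establishes the
arithmetic of the measurement chain, not segmentation accuracy.

**Jump traces.** The centre-of-mass trajectory is piecewise closed-form:
≥ 1 s quiet standing; a sinusoidal-acceleration dip of depth `d` (dip
duration defaults so peak downward acceleration is 0.7 g — a dip too fast
for positive force is rejected); a sinusoidal push of duration `T_p`
(amplitude π·d/T_p², returning the CoM to standing height); a 50 ms
linear force release to exactly zero, so force is continuous at take-off;
then free flight with force clipped at exactly 0. Force is
`m·(g + a(t))`, sampled at 800 Hz. The ground-truth peak power is the
maximum of the closed-form `F·v` on a dense (20 kHz) grid — independent
of the sampled trace and of the analyzer's integration. `calibrate_dip_
for_power` inverts the monotone dip→peak-power map by root finding, so
cohort subjects can be generated at prescribed peak powers. Not emulated:
arm swing, multi-segment dynamics, force-plate noise and filtering,
landing.

**Cohort.** Four groups at the published sizes (10/12/10/11) and
anthropometrics. Each subject draws one multiplicative volume scale (CV =
the published composite-volume CV) shared by all muscles — keeping
within-subject muscle volumes correlated — plus 3 % per-muscle jitter.
The jumping-muscle composite volume is split across the ten jumping
muscles by fixed anatomical fractions (glutei 0.30, quadriceps 0.45,
triceps surae 0.25, subdivided per muscle); the published record shows
the composite only, so the split is a package choice. Shell/centre FF
per muscle and group are drawn from the published means ± SD (with shell
kept ≥ centre + 0.2, since the generator states a periphery-fattier
world). Jump peak power is drawn around the published age-group
power–volume line (young: −0.61 kW + 0.89 W/ml, residual SD 0.33 kW
giving r ≈ 0.94; old: 0.67 kW + 0.45 W/ml, residual SD 0.38 kW giving
r ≈ 0.67) and the trace is calibrated to deliver it. EMCL/IMCL group
means are package choices consistent with the qualitative published
findings (EMCL always distinctly above IMCL; old-athlete EMCL about half
of old controls; IMCL < 2 %): no numeric group values are published, so
spectroscopy claims are property-based only.

**Demo grid.** The default cohort runs on a coarsened grid
(2.34 × 2.34 × 10 mm) so that a full 43-subject pipeline completes in
under a minute; single-muscle analyses use the scanner grid. Coarsening
raises the shell voxel fraction (smaller muscles in voxel units), so
whole-muscle FF on the demo grid sits slightly above what the same
shell/centre values would give in vivo; shell and centre means themselves
are unaffected.

## Numerical choices

* Gravity fixed at 9.81 m/s².
* Trapezoidal integration for velocity; peak search restricted to samples
  at or before take-off.
* Take-off threshold 10 N; quiet-window SD limit 5 N.
* Exclusion boundary ≥ 25 % (inclusive at the boundary).
* The muscle rasteriser's bisection stops at |count − target| within 2 %
  or a 10⁻⁶-voxel bracket, keeping the better iterate.
* MRS fits run with `xtol = ftol = gtol = 1e-14` and up to 4 jittered
  restarts (seeded; the fit itself is deterministic).
* Empty voxel maps yield volume 0 with a warning; empty FF regions are an
  error (a mean of nothing has no value to report).

## Known limitations

* Segmentation itself (atlas registration, manual correction) is out of
  scope: maps enter as given.
* DIXON reconstruction from raw echoes is out of scope; FF values enter
  as given.
* The MRS model is Lorentzian-only, no baseline, no J-coupling
  multiplets, no eddy-current correction; it quantifies well-separated
  peaks and flags (not resolves) merged ones.
* Repeated-measures mixed-effect modelling across the 17 muscles is
  deliberately replaced by summary-statistic pairwise tests.
* The per-subject results of the published record (per-muscle tables,
  scatter figures) are not reproducible from printed summaries; recovery
  suites on synthetic ground truth stand in for them.
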