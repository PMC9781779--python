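# Methods

This note records the models, conventions and deliberate design choices
behind `mangonir`, in the spirit of a statistical software appendix.

## Data model

A scan is an absorbance vector on a shared strictly increasing wavelength
grid bounded by 1350–2500 nm; the default grid is 136 evenly spaced points
(the instrument class this mirrors reports 136 points over that range, which
is taken at face value as an even grid). Each scan is keyed by
`(sample_id, location)` with locations 1–4, the four marked measurement
spots on a fruit, and pairs with a reference record: TA (%), SSC (°Brix),
firmness (kgf), starch (%), plus a maturity label in {80, 85, 90, 95, 100}.
Parameter universes are TA [0, 2.5], SSC [4, 24], firmness [0, 5], starch
[0, 15]; records outside them are rejected at construction.

A scan is *invalid* iff any value is non-finite or exceeds the clip threshold
(default 10 000) in magnitude. No sharper criterion is defined upstream, so
validity is tied to the same threshold the CLIP operator uses.

Stratified train/test splitting draws per-class test counts of
`round(n_class × fraction)` with round-half-up; for class counts
(139, 140, 140, 139, 138) at 10 % this yields 14 per class, 70 in total, the
bookkeeping the real study reports.

## Preprocessing operators

All twelve operators map a spectrum to a spectrum (RESAMPLE also maps the
grid). Conventions that needed fixing:

- **SNV** uses the sample SD (ddof = 1); **RNV** uses linearly interpolated
  percentiles (default 75/25, optionally 90/10). Constant spectra raise a
  degenerate-input error rather than returning NaN.
- **LSNV** standardizes consecutive windows independently; the default
  window is 17 points (no published value exists; 17 divides the 136-point
  grid into 8 equal windows) and a trailing remainder is merged into the
  last window so each point is standardized exactly once.
- **MSC/EMSC** regress each spectrum on a reference spectrum (EMSC adds
  linear and quadratic wavelength terms, wavelength rescaled to [−1, 1] for
  conditioning) and rescale by the fitted slope; a slope within 1e-8 of zero
  is an error. The reference is the **training-set mean at that pipeline
  stage**, frozen at fit time — held-out scans are corrected with training
  statistics only. This leakage guard is this package's choice; upstream
  descriptions are silent on it.
- **NORML** is Euclidean unit-norm scaling (the named alternative, range
  scaling, is not implemented; one variant had to be chosen).
- **DETREND** removes the least-squares line over the full grid (single
  segment, `bp = [0]`); **BASELINE** removes the mean.
- **SMOOTH** convolves with a unit-sum Hamming taper and reflective edge
  padding; **SAVGOL** is scipy's Savitzky–Golay filter with derivatives in
  per-sample units; **RESAMPLE** is Fourier resampling to
  `round(N × ratio)` points on an evenly spaced grid with the same bounds.

**Canonical order.** A pipeline holds at most one instance of each operator
and always applies them as CLIP → DETREND → BASELINE → SNV → RNV → LSNV →
MSC → EMSC → NORML → SMOOTH → SAVGOL → RESAMPLE: clipping and baseline
removal must precede scatter statistics, smoothing and derivatives operate
on corrected spectra, and resampling runs last because it changes the grid.
Published "best operator" sets are printed alphabetically and carry no order
information; they are all expressible in this order.

**Enumeration.** The search space is "any subset of the pooled operators,
crossed with each operator's parameter grid". The upstream reports of 1,152
and 2,112 combinations are not derivable from the printed grids under any
subset rule we could reconstruct, so pools and caps are configuration and
the enumerated count is logged rather than asserted. Search is exhaustive;
ties break toward fewer steps, then lexicographic serialized spec, making
the ranking deterministic.

## Chemometrics

PLS1 is NIPALS with deflation (tolerance 1e-10, max 500 inner iterations),
delegated to scikit-learn's `PLSRegression` with internal centering and no
scaling; `n_components = 0` degenerates to predicting the training mean.
With components equal to the rank of X, predictions coincide with ordinary
least squares — the suite verifies this against a normal-equations oracle.
Component count is selected by repeated k-fold RMSE with ties to the
smallest k.

R² is the coefficient of determination 1 − SS_res/SS_tot (not squared
Pearson correlation): it pairs naturally with RMSE and matches the reported
value ranges. Classifier families (LDA, SVC, k-NN, MLP, decision tree) use
library defaults unless overridden, with seeds fixed where the estimator is
stochastic; cross-validation is repeated stratified k-fold (default 10×3)
with any spectral pipeline refitted inside each training fold.

## Threshold grading

Each parameter has five intervals over its universe, with cut points
(TA: 0.37/0.45/0.55/0.8; SSC: 9.5/13.5/19/19.6; firmness: 1.8/2.9/3.4/3.6;
starch: 1.95/3.5/5/7.2). TA, firmness and starch fall with ripening (class
100 occupies the lowest interval), SSC rises. The published bounds touch, so
a boundary convention is needed: every interval is half-open `(lo, hi]` on
the value axis — a shared bound belongs to the interval it closes from
above (TA = 0.8 grades 85 %, not 80 %). This single rule makes every
parameter's table a partition and preserves monotonicity: rising SSC never
lowers the grade, rising TA/firmness/starch never raises it.

## Fuzzy inference

Input trapezoids read the published overlapping L/M/H ranges as ramp
intervals, e.g. TA: L = [0, 0, 0.60, 0.65], M = [0.60, 0.65, 0.75, 0.80],
H = [0.75, 0.80, 2.5, 2.5] (similarly SSC, firmness). Starch is published
with touching M/H bounds (no overlap); a 0.3-wide ramp is imposed there
(M = [3.0, 3.5, 5.3, 5.6], H = [5.3, 5.6, 15, 15]) to mirror the other
variables and keep every universe point covered.

The 81 rules form a total map {H,M,L}⁴ → maturity class, transcribed with
rows = (TA, SSC) and columns = (firmness, starch). That axis reading is the
only one under which all five published class-mean quadruples grade to their
own class, which the suite asserts.

Output sets are symmetric triangles peaking at 80…100 with feet ±5,
truncated to the published 75–100 universe (the exact published geometry is
not legible). Inference is min implication, max aggregation; defuzzification
is the centroid on a 0.01-step grid, checked against a 0.001-step brute
force to < 0.01 index points over 1,000 random inputs. An all-zero aggregate
raises instead of defaulting. The crisp value maps to the nearest class
peak, ties to the lower class.

**Known structural effect.** Because the 100 % triangle is truncated to a
right triangle on [95, 100], its unclipped centroid is 98.33 and any
admixture of the 95 % set pulls the crisp value below the 97.5 cutoff.
Combined with the firmness Low/Medium ramp at 1.5–1.7 kgf — which sits
*inside* the published class-100 firmness range (0.6–1.9 kgf) — a fruit of
class 100 with firmness above ≈1.6 kgf defuzzifies to 95 %. Under the
synthetic generator (parameters drawn independently per class) roughly a
fifth of class-100 draws land there, capping per-class accuracy near
70–80 % for that class and overall accuracy near 92 %. This is a property
of the published membership geometry, not of the implementation; with real,
correlated data the effect is evidently milder.

## Synthetic generator

The generator emulates the published per-class summary statistics
(min/max/mean/SD per parameter per class). Draws are truncated Gaussians on
the published [min, max] support with the published SD as the parent scale.
Truncating N(mean, SD) to an asymmetric window shifts its mean (class-80 TA
would average 1.20 instead of 1.11), so the parent location is solved by a
bracketed root find so the truncated mean equals the published mean exactly.
The truncated SD is then at most the published one; note that several
published SDs are outright unattainable on their supports (class-85 TA asks
for SD 0.11 on a 0.28-wide range whose uniform-distribution limit is 0.081),
so SD fidelity is best-effort by construction. Parameters are drawn
independently within a class — no covariance information is published —
so cross-parameter correlation arises only through the class label.

Spectra are rendered as Σ_p w_p · value_p · exp(−(λ−c_p)²/2σ_p²) over two
Gaussian bands per parameter (centers 1450/1725, 1940/2100, 1680/2270,
1560/2330 nm; distinct centers make the four parameters linearly
identifiable), plus a uniform baseline offset (0.30–0.40 absorbance), a
linear tilt (slope ±0.05 over the normalized wavelength axis), a
multiplicative scatter factor (0.95–1.05) and white noise (SD 0.002
absorbance). Band placement is an identifiability device, loosely near real
water/sugar overtone regions, not assigned chemistry. A `noiseless()`
variant zeroes every random term, making the model exactly linear in the
parameters — on it, PLS must recover each parameter with R² > 0.99, which
is the generator's own correctness check. What passing tests on this bench
do *not* show: robustness to real instrument drift, nonlinear
scattering/particle-size effects, or correlated within-fruit variation.

## Problem sizes and numerical choices

The test suite runs the full workflow at 12–35 scans per class and the
end-to-end experiment as the mean fuzzy-route accuracy over 10 independent
generate/split/calibrate replicates: a single 10 % split of 5×35 scans holds
out only ~20 scans, quantizing accuracy in 5 % steps, so averaging
replicates is what makes a >90 % claim testable at all. These sizes were
chosen as the smallest at which every stage (CV folds, PLS rank, per-class
splits) is well-posed. Degenerate inputs (constant spectra, zero percentile
ranges, all-zero fuzzy aggregates, empty evaluation sets) raise typed errors
rather than propagating NaNs; seeds thread explicitly through every random
component, and derived seeds stay below 2³¹.

## Limitations

- The real dataset is external and optional; published real-data accuracies
  (e.g. 91.43 % direct LDA, 95.7 % fuzzy indirect) are context, not targets,
  and are not reproduced here.
- The enumeration scheme cannot reproduce the published combination counts
  (1,152 / 2,112) from the printed grids; pools are configuration.
- The fuzzy output geometry is a reconstruction (symmetric ±5 triangles);
  the published figure is not machine-readable.
- Only PLS is implemented for the indirect regression stage; SVM/RF/LR
  regressors from the comparison table are out of scope.
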