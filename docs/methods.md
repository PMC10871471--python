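# Methods

## Scope

`glucest` reimplements, end to end and on synthetic data with known ground
truth, the analysis chain of a single-slice glutamate-weighted CEST (GluCEST)
brain study at 7 T: Bloch-McConnell simulation of the saturation experiment,
WASSR-based B0 field mapping, multi-flip-angle relative-B1 mapping, B0/B1
corrected percent-contrast maps, regional summaries over gray/white matter
and seven cortical regions, and smoker versus non-smoker cohort statistics
(rank-sum comparisons, age regressions, volume-contrast correlations).

## Signal model

Two exchanging proton pools: bulk water (a) and the glutamate amine pool (b)
at +3.0 ppm. Under continuous-wave saturation of amplitude omega1 at offset
Delta the magnetization follows the linear Bloch-McConnell system
`dM/dt = A M + c` over `M = (Mxa, Mya, Mza, Mxb, Myb, Mzb)`. The z-spectrum
value is the normalized water Mz after the saturation period, starting from
equilibrium. Saturation is modeled as CW at the root-mean-square B1 for the
full stated duration; the acquisition's pulse train runs at 99% duty cycle,
so the CW approximation is well below every tolerance used here.

Defaults (all overridable): T1/T2 water 1.8/0.04 s, T1/T2 solute 1.0/0.008 s
(7 T gray-matter-like), exchange rate 5500 1/s, amine shift +3.0 ppm,
solute fraction `fb = 3 [Glu mM] / 111000` (3 amine protons against the two
protons of 55.5 M water). Field 6.99 T with gamma 42.577 MHz/T, so
1 ppm = 297.6 Hz. CEST scheme: 3.06 uT RMS, 0.8 s, offsets ±1.8…±4.2 ppm in
0.3 ppm steps; WASSR scheme: 0.29 uT, 0.2 s, offsets 0, ±0.15…±1.5 ppm.

With these parameters 10 mM glutamate yields a simulated contrast of 1.54%.
In-vivo GluCEST values near 9% additionally contain contributions a two-pool
model deliberately excludes (other labile pools, magnetization-transfer and
NOE asymmetries), so phantom contrasts here live on the 1–1.6% scale. All
relative criteria (CVs, recovery rates, p-values) are scale-free; absolute
contrast-error floors are correspondingly small (see "Estimator floors").

### Numerical engines

The production engine propagates the augmented homogeneous 7-dim system with
a batched scaling-and-squaring Pade-13 matrix exponential (one shared
scaling power per batch; exact, merely conservative for small-norm members).
It vectorizes over tens of thousands of (voxel, offset) generators, which is
what makes 200-cohort end-to-end replicate studies tractable on one CPU.
Two independent routes check it: closed-form propagation of the 6-dim
inhomogeneous system through `scipy.linalg.expm` (built separately in the
tests), and a stiff-ODE integration (LSODA, rtol 1e-9, analytic Jacobian).
Agreement is ~1e-10 absolute; the acceptance surface requires 1e-6.

## Synthetic phantoms

Elliptical brain, white-matter core, gray-matter band, and seven disjoint
gray-matter patches standing in for the cortical regions (cingulate gyrus,
juxtapositional lobule cortex, paracingulate gyrus, frontal pole, middle
frontal gyrus, pre- and postcentral gyri). Default grid 96x64 (the
240x168 acquisition matrix is available by flag); the cohort pipeline
defaults to 48x32 and the replicate studies to 32x22, with every region
keeping nonzero voxel counts. Tissue glutamate defaults: WM 6.5 mM, GM
9.5 mM, cortical patches 8.4-9.7 mM patterned on the regional ordering of
the reported contrasts.

Truth fields: smooth low-order polynomial B0 map scaled to ±0.3 ppm and
relative-B1 (kappa) map spanning 0.8-1.2 by default; per-subject random
coefficients. Noise: additive Gaussian on magnitude frames (sigma relative
to the unit unsaturated signal; default 0.005 for single phantoms, 0.002 in
the cohort studies), Rician by flag. Flip-angle calibration images follow
`S = S0 cos(kappa alpha)` for alpha in {20, 40, 80} degrees.

### WASSR dispersion

Ideal CW simulation of the WASSR scheme (0.29 uT for only 200 ms) leaves
coherent nutation structure: Z oscillates near the water line (Z(0) < 0) at
a ~0.03 ppm scale, and the dip is ~0.14 ppm wide — narrower than the
0.15 ppm offset step. No voxel of an in-vivo 1x1x5 mm acquisition behaves
this way: through-slice and microscopic B0 dispersion dephases the nutation.
The phantom therefore convolves the WASSR spectrum with a Gaussian
frequency spread of sigma 0.07 ppm (~21 Hz across the 5 mm slice at 7 T, a
plausible frontal-lobe figure), which is also the regime in which the
protocol's 0.15 ppm sampling can resolve the dip at all. CEST frames are
left undispersed: their features vary on a ~1 ppm scale, where the
correction is second order and omitting it keeps the contrast chain exactly
checkable against the simulator.

Implementation: a simulate-once lookup table per cohort — the undispersed
spectrum on a 0.005 ppm offset grid (fine enough for the nutation
structure) for 13 kappa nodes, dispersed by discrete convolution, then
cubic interpolation per voxel in offset and kappa. The table matches a
brute-force trapezoid convolution to <2e-4. Gauss-Hermite quadrature was
rejected for this integrand: even 61 nodes leave ~5e-3 errors on the
oscillatory undispersed spectrum. The spectrum's residual dependence on the
dilute solute level is below the table's own error, so one table (at the
cohort's median glutamate) serves all subjects.

## Field mapping

**B0 (WASSR).** The direct-saturation dip is symmetric about the water
frequency regardless of width, so the default estimator is a
maximum-symmetry fit: for each candidate center delta the 21 samples are
least-squares projected onto an even cubic-B-spline basis in
`|offset - delta|` (symmetric lineshapes of arbitrary width, knots dense
near the core); the center minimizing the residual wins. Coarse grid
(10^-2 ppm, data-independent projections cached), one per-voxel refinement
pass at 2e-3 ppm, parabolic vertex. Two alternatives are retained:
`mirror` (classic reflected-spline mismatch) and `spline_min` (dense-grid
minimum of the interpolant). On the dispersed phantom dips the worst-case
noiseless errors are ~0.002, ~0.006 and ~0.02 ppm respectively, which is
why the projection variant is the default: the dip remains undersampled at
the protocol's step, and estimators relying on interpolating it pay for it.

**Relative B1.** Per voxel, kappa minimizes
`sum_i (S_i - S0 cos(kappa alpha_i))^2` with S0 profiled out in closed
form; coarse 1e-3 grid over [0.3, 2.0], fine 1e-4 pass, parabolic vertex;
ties of the non-injective cosine model break toward kappa = 1. Model-exact
inputs are recovered to ~1e-9.

**Brain mask.** Voxels whose mean WASSR signal falls below 5% of the
stack's 99th percentile are background.

### Estimator floors

The solute pool makes WASSR spectra slightly asymmetric (up to 3e-3 in Z at
0.29 uT), so the water frequency and the symmetry center differ: every
symmetry-based estimator carries a bias floor of ~1e-3 ppm (about 1/100 of
the offset step). Two consequences, both verified in the tests rather than
idealized away: (i) an unperturbed phantom (B0 = 0, kappa = 1, no noise) is
recovered to <2e-3 ppm, not to machine precision; (ii) because the contrast
changes by ~45 percentage points per ppm of B0-evaluation error at this
contrast scale, the corrected map agrees with the Bloch-McConnell
prediction to ~0.1% contrast through estimated fields — and to 1e-6 when
the true fields are supplied, which isolates the correction chain itself.

## Contrast computation

`GluCEST% = 100 (Z(-3) - Z(+3)) / Z(-3)`, normalized to the negative-offset
image per the GluCEST convention (an M0-normalized variant is a flag). B0
correction interpolates each voxel's z-spectrum per sign branch (natural
cubic spline over the 9 samples) and evaluates at ±3 + b0; evaluation
points leaving the sampled branch (|b0| > 1.2 ppm) invalidate the voxel —
no extrapolation ever. B1 correction multiplies by `C(1)/C(kappa)` with C
the simulation-derived calibration curve (contrast versus kappa at ±3 ppm,
default table spanning 0.40-1.60 in 0.05 steps, linear interpolation);
kappa outside [0.5, 1.5] invalidates the voxel. The calibration is computed
at 10 mM glutamate; the ratio's residual dependence on the true
concentration is below 0.3% of the correction over the phantom's range.

## Regional analysis

Fixed vocabulary: WholeBrain, GM, WM, and the seven cortical regions. The
cortical patches are gray matter, so GM aggregates them with the generic GM
band; WholeBrain is every labeled voxel. Statistics use valid voxels only;
an empty region is "missing" (never zero), and regions under 10 valid
voxels are flagged low-confidence. Normalized volumes are voxel-count
fractions of total brain (uniform voxel size on a single slice).

## Cohort statistics

Wilcoxon rank-sum, mirroring the defaults of the R implementation the
study's statistics came from: exact two-sided p by dynamic-programming
enumeration of the rank-sum null when both n < 50 and the pooled sample has
no ties; otherwise the normal approximation with tie and continuity
corrections. Cross-checked in tests against `scipy.stats.mannwhitneyu` and
against `wilcox.test` itself through Rscript. No multiple-testing
correction — p-values are reported per region, as in the study design.
Regressions are OLS (contrast on age; contrast on normalized volume per
group and tissue) with R^2 and the two-sided slope-t p-value; a
zero-variance response is reported as degenerate (slope 0, R^2 0, p 1).

The results bundle reproduces the study's table layout — 10 regions x
2 groups with mean (SD) and the comparison p — plus per-group age
regressions for GM, WM and the seven cortical regions, and the
volume-contrast correlation table.

### Exact-p calibration

At group sizes (10, 9) the exact two-sided p-value is discrete (46 atoms)
and conservative (doubling rule); its exact null law deviates from U(0,1)
by a KS distance of 0.063 — an intrinsic property of the exact test, not a
pipeline defect. Calibration of the null pipeline is therefore tested
against the exact null distribution of the p-value itself, per region
(regional p-values within one cohort are dependent, since the tissue
aggregates share voxels with the cortical regions), with the Sidak-adjusted
minimum KS p across the 10 regions as the summary. The KS p-value itself is
computed by parametric bootstrap from the atom distribution: the classical
continuous-case p-value is an order of magnitude anti-conservative in the
tail when the null carries 46 atoms and the sample has many ties.

## Replicate studies

Both run the full chain (phantom acquisition -> field maps -> corrected
contrast -> ROI means -> statistics) per subject, 19 subjects per cohort,
on a 32x22 grid with frame noise 0.002 and between-subject SD 0.4 mM:

* **Slope recovery** — smoker cingulate-gyrus glutamate slope of
  -0.15 mM/year (chosen to emulate the reported moderate age correlation,
  R^2 ~ 0.5 over the smokers' 25-50 y range); 200 cohorts; the fraction
  recovering a negative estimated slope is the figure of merit (>= 95%).
* **Null calibration** — no injected effects; 120 cohorts; per-region KS
  against the exact p-value null as above.

Problem sizes (grid, replicate counts, table resolutions) are the package's
standing desk-scale choices and are stated here once; they keep a full
validation run in the ten-minute range on a single CPU.

## Cohort design emulated

10 non-smokers recruited one female and one male per age decade over 20-70
years; 10 smokers (5F/5M) over 25-50 years, of whom one is excluded as
unusable (motion), leaving 19 analyzable subjects. The recruitment rule
cannot place 10 smokers at one-per-sex-per-decade within three decades, so
smoker ages are uniform over the range. Regional glutamate per subject:
`base + group effect + age slope (age - 45) + N(0, subject SD)`, all terms
configurable; defaults carry no group effect and no age dependence,
matching the null result the cohort statistics reproduce structurally.

## Known limitations

* Two-pool model only: no MT/NOE/amide pools, no pulse-shape-resolved
  saturation, no relaxation during readout; simulated contrast is ~6x
  smaller than in-vivo prints (see "Signal model").
* Hard tissue labels; no partial voluming, motion, or coil sensitivity.
* The WASSR dispersion constant is a modeling choice standing in for
  through-slice dephasing; real acquisitions vary regionally.
* Symmetry-estimator B0 bias floor (~1e-3 ppm) bounds per-voxel corrected
  accuracy at the ~0.1% contrast level; at the in-vivo contrast scale the
  same floor would be relatively ~6x smaller.
* Passing phantom tests demonstrates correctness of the pipeline's
  computations under the stated generative model, not robustness to
  artifacts real 7 T data exhibit (motion, lipid aliasing, drift).
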