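# glucest

Glutamate-weighted CEST (GluCEST) MRI measures glutamate indirectly: a
frequency-selective saturation pulse labels the amine protons resonating
3.0 ppm downfield of water, chemical exchange carries that saturation into
the water pool, and the accumulated water-signal loss is read out as the
asymmetry of the z-spectrum,

    GluCEST% = 100 · (Z(−3 ppm) − Z(+3 ppm)) / Z(−3 ppm).

Turning that asymmetry into a usable brain map requires per-voxel
correction of the static-field shift (B0, via a WASSR low-power z-spectrum
whose dip tracks the water frequency) and of the transmit-field scale
(relative B1 "kappa", via three flip-angle calibration images following
S = S0·cos(κα)).

This package implements that analysis chain for a single-slice 7 T
smoker/non-smoker study design, fully exercisable on synthetic phantoms
with known ground truth:

* `glucest.simulate` — two-pool Bloch–McConnell z-spectrum simulation
  (batched matrix-exponential propagation plus an independent stiff-ODE
  engine) and the simulation-derived B1 calibration curve;
* `glucest.phantom` — synthetic slice acquisitions (CEST stack at
  ±1.8…±4.2 ppm, WASSR stack at 0…±1.5 ppm, flip-angle images, label
  maps) and 19-subject cohorts emulating the study design;
* `glucest.fieldmap` — WASSR B0 fitting (maximum-symmetry estimator) and
  multi-flip-angle κ fitting;
* `glucest.contrast` — B0/B1-corrected percent-contrast maps;
* `glucest.roi` — regional summaries (whole brain, GM, WM, seven cortical
  regions) and normalized tissue volumes;
* `glucest.stats` — exact Wilcoxon rank-sum group comparisons, age
  regressions with R², volume–contrast correlations, and the
  10-region × 2-group results table;
* `glucest.pipeline` / `glucest.cli` — end-to-end orchestration
  (`glucest run`) with YAML configuration and reproducible seeds.

It is aimed at CEST methodologists who want a tested, reproducible
reference implementation of the correction-and-statistics chain, and at
anyone who needs ground-truthed synthetic CEST data to validate their own.

## Worked example

```python
import numpy as np
from glucest import (PoolSystem, default_cest_scheme, simulate_zspectrum,
                     b1_calibration_curve)

pools = PoolSystem()          # 7 T GM-like, 10 mM glutamate amine pool
sat = default_cest_scheme()   # 3.06 uT RMS, 800 ms

zs = simulate_zspectrum(pools, sat, [-3.0, 3.0])
zn, zp = zs.z
print(f"Z(-3)={zn:.5f}  Z(+3)={zp:.5f}  GluCEST={100*(zn-zp)/zn:.4f}%")

cal = b1_calibration_curve(pools, sat, np.arange(0.5, 1.51, 0.25))
print(cal.round(6).to_string(index=False))
```

prints

```
Z(-3)=0.70778  Z(+3)=0.69688  GluCEST=1.5401%
 kappa  glucest_percent
  0.50         0.418433
  0.75         0.909829
  1.00         1.540085
  1.25         2.254846
  1.50         2.989765
```

i.e. a 10 mM glutamate pool yields a 1.54% asymmetry at nominal B1, and the
contrast varies strongly (≈7×) over the κ range seen in a 7 T head — which
is why the per-voxel B1 correction (rescaling by C(1)/C(κ) from this very
curve) matters. A full synthetic cohort run:

```python
from glucest import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(out_dir="run", seed=11))
print(bundle.comparison.head(4).to_string(index=False))
```

```
    region      group     mean       sd  n  p_value
WholeBrain non-smoker 1.314820 0.048004 10 0.094720
WholeBrain     smoker 1.278908 0.071445  9 0.094720
        GM non-smoker 1.450429 0.056679 10 0.112754
        GM     smoker 1.403689 0.071590  9 0.112754
```

— per-group mean (SD) regional contrast for the 10 non-smokers and 9 usable
smokers, with the exact two-sided rank-sum p of the group comparison; the
full bundle also holds per-group age regressions (slope, R², slope p) and
volume–contrast correlations, and everything is written under `run/` as
CSV/XLSX together with the resolved configuration. The same stages are
available from a shell: `glucest simulate`, `glucest fieldmaps`,
`glucest contrast` (with `--no-b0-corr` / `--no-b1-corr` ablations),
`glucest roi`, `glucest stats`, `glucest run`.

Simulated contrasts sit on the 1–1.6% scale: a faithful two-pool model
excludes the confounding pools (MT, NOE, other amines) that inflate the
in-vivo asymmetry; see `docs/methods.md`.

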