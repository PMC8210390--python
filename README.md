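# cardiotox-qmap

Quantitative cardiac MR + histology pipeline for anthracycline
cardiotoxicity studies in small animals: pixel-wise T1/T2 relaxometry,
left-ventricular segment geometry, extracellular volume fraction (ECV),
picrosirius-red collagen quantification, and the cohort statistics that
link imaging to tissue pathology — with a synthetic-data layer providing
ground truth for every stage.

## Who this is for

Chemotherapy with anthracyclines (doxorubicin) injures the myocardium in a
dose-dependent way: myocyte vacuolization, interstitial edema,
inflammation, and eventually diffuse fibrosis. Ejection fraction falls
only late, so quantitative tissue markers — native T1, T2 and ECV from
mapping CMR — are the candidates for early detection, and validating them
requires the full measurement chain from raw image series to cohort
regression tables. This package implements that chain as a reusable,
tested library for preclinical imaging groups.

## The models at the core

* **T1** from saturation recovery: `M(TD) = A − B·exp(−TD/T1)`, fitted
  per pixel by variable projection (closed-form `A, B` at each candidate
  `T1`, golden-section search over `T1`).
* **T2** from multi-echo spin echo: `S(TE) = S0·exp(−TE/T2)`, weighted
  log-linear estimate with optional nonlinear refinement.
* **ECV** from paired T1 and hematocrit:
  `λ = ΔR1_myo/ΔR1_blood`, `ECV = (1 − Hct)·λ`, computed per LV segment
  (15% partial-volume offset, four 90° quadrants, < 5 mm² blood ROI).
* **LV function** by summation of discs: `SV = EDV − ESV`,
  `EF = 100·SV/EDV`, `CO = SV·HR/1000`, mass at 1.05 g/ml.
* **Fibrosis** as the collagen share of tissue pixels after k-means
  (k = 3) clustering in CIE L\*a\*b\*.
* **Statistics**: Shapiro–Wilk-gated group comparisons with Bonferroni
  post-hoc, univariable and multiple linear regression with VIF and
  adjusted R², and exact noncentral-t sample sizing.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from cardiotox_qmap import synthetic as synth
from cardiotox_qmap.relaxometry import fit_t1_map, map_roi_stats

series, truth = synth.make_t1_phantom(
    synth.PhantomSpec(values_ms={0: 1148.0, 1: 1320.0}, noise_sd=20.0, seed=1)
)
t1_map = fit_t1_map(series)
for value in (1148.0, 1320.0):
    print(value, map_roi_stats(t1_map, truth == value))
```

prints

```
1148.0 {'mean': 1153.4401103863725, 'sd': 73.30071677399659, 'n': 512}
1320.0 {'mean': 1318.3225918994598, 'sd': 94.85987148587118, 'n': 512}
```

i.e. at SNR 50 the fit recovers a control-like region (truth 1148 ms) and
a 6-week-treated-like region (truth 1320 ms) with sub-percent bias — the
kind of separation the native-T1 marker relies on.

The full analysis narrative lives in `analysis/01_simulate.py` …
`analysis/06_cohort_stats.py`; each script prints what it found and writes
its tables under `results/`. The umbrella CLI exposes the same stages
(`cardiotox-qmap simulate|fit-t1|fit-t2|lv-function|ecv|fibrosis|histo-aggregate|cohort-stats|run`).

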