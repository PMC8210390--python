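#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes the cohort table and contour stacks (text) under results/data/, and
the image stacks (binary TIFF) under scratch/data/.  All downstream scripts
read only these files, so the whole analysis is reproducible from one seed.
"""

import json
from pathlib import Path

from cardiotox_qmap import synthetic as synth
from cardiotox_qmap.io import write_cohort_csv, write_contours_csv, write_image_stack

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results" / "data"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    table, truth = synth.make_cohort(synth.CohortSpec(seed=SEED))
    write_cohort_csv(RESULTS / "cohort.csv", table)
    with open(RESULTS / "cohort_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
    print(f"cohort: {truth['n_total']} subjects ({truth['n_treated']} treated), "
          f"residual SDs T1 {truth['sigma_t1']:.1f} ms, ECV {truth['sigma_ecv']:.2f}%")

    stacks, vol_truth = synth.make_contour_stack(edv_ml=0.69, esv_ml=0.18, n_vertices=48)
    write_contours_csv(RESULTS / "contours_control.csv", stacks)
    print(f"contours: EDV {vol_truth['EDV_ml']} ml, ESV {vol_truth['ESV_ml']} ml")

    t1_series, _ = synth.make_t1_phantom(
        synth.PhantomSpec(values_ms={0: 1148.0, 1: 1320.0}, noise_sd=20.0, seed=SEED)
    )
    write_image_stack(SCRATCH / "t1_series.tif", t1_series)
    t2_series, _ = synth.make_t2_phantom(
        synth.PhantomSpec(values_ms={0: 10.3, 1: 16.3},
                          timing_ms=synth.DEFAULT_T2_ECHOES_MS, noise_sd=7.0, seed=SEED)
    )
    write_image_stack(SCRATCH / "t2_series.tif", t2_series)
    print(f"phantoms: control vs 6-week truth values, noisy, under {SCRATCH}")


if __name__ == "__main__":
    main()
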