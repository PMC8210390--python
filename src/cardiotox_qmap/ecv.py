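"""Extracellular volume fraction (ECV) from paired pre/post-contrast T1.

Contrast agent shortens T1 in proportion to its local concentration.  The
partition coefficient lambda is the ratio of myocardial to blood relaxation
rate change, ``lambda = dR1_myo / dR1_blood`` with ``R1 = 1/T1``, and the
extracellular volume fraction corrects for the plasma volume:
``ECV = (1 - Hct) * lambda``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .geometry import SEGMENT_NAMES, BloodROI, SegmentModel
from .relaxometry import ParametricMap, map_roi_stats

__all__ = ["ECVInputs", "ECVResult", "compute_ecv", "segmentwise_ecv", "normalize_hct"]

log = logging.getLogger(__name__)


def normalize_hct(hct: float) -> float:
    """Accept hematocrit as a fraction (0, 1] or percent (1, 100]."""
    if not 0 < hct < 100:
        raise InputError(f"hematocrit {hct} out of range")
    if hct > 1:
        log.info("hematocrit %.3g interpreted as percent", hct)
        return hct / 100.0
    return hct


@dataclass
class ECVInputs:
    """Segment- or ROI-mean T1 values (ms) plus hematocrit."""

    t1_myo_pre: float
    t1_myo_post: float
    t1_blood_pre: float
    t1_blood_post: float
    hct: float

    def __post_init__(self) -> None:
        for name in ("t1_myo_pre", "t1_myo_post", "t1_blood_pre", "t1_blood_post"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.t1_myo_post >= self.t1_myo_pre:
            raise InputError("post-contrast myocardial T1 must be below native T1")
        if self.t1_blood_post >= self.t1_blood_pre:
            raise InputError("post-contrast blood T1 must be below native T1")
        self.hct = normalize_hct(self.hct)


@dataclass
class ECVResult:
    ecv: float  # fraction
    partition_coefficient: float

    def __post_init__(self) -> None:
        # identity ecv = lambda * (1 - hct) is enforced at construction sites;
        # here we only sanity-check ranges
        if not np.isfinite(self.ecv) or not np.isfinite(self.partition_coefficient):
            raise InputError("non-finite ECV result")

    @property
    def ecv_percent(self) -> float:
        return 100.0 * self.ecv


def compute_ecv(inputs: ECVInputs) -> ECVResult:
    """ECV and partition coefficient from one set of paired T1 values."""
    dr1_myo = 1.0 / inputs.t1_myo_post - 1.0 / inputs.t1_myo_pre
    dr1_blood = 1.0 / inputs.t1_blood_post - 1.0 / inputs.t1_blood_pre
    if dr1_blood <= 0:
        raise InputError("non-positive blood dR1: invalid contrast dynamics")
    lam = dr1_myo / dr1_blood
    ecv = (1.0 - inputs.hct) * lam
    result = ECVResult(ecv=ecv, partition_coefficient=lam)
    assert abs(result.ecv - result.partition_coefficient * (1.0 - inputs.hct)) < 1e-12
    return result


def segmentwise_ecv(
    t1_pre: ParametricMap,
    t1_post: ParametricMap,
    segments: SegmentModel,
    blood: BloodROI,
    hct: float,
) -> dict:
    """Per-segment and global ECV from co-registered pre/post T1 maps.

    Per segment the segment-mean T1 (pre and post) is paired with the
    blood-ROI-mean T1; the global value is the mean of the four segment
    ECVs (not the ECV of the mean T1 — the two differ in general).
    """
    if t1_pre.values.shape != t1_post.values.shape:
        raise InputError("pre/post maps are not co-registered")
    hct = normalize_hct(hct)
    blood_pre = map_roi_stats(t1_pre, blood.region)["mean"]
    blood_post = map_roi_stats(t1_post, blood.region)["mean"]
    out: dict[str, ECVResult] = {}
    for name in SEGMENT_NAMES:
        roi = segments.segment_mask(name)
        myo_pre = map_roi_stats(t1_pre, roi)["mean"]
        myo_post = map_roi_stats(t1_post, roi)["mean"]
        out[name] = compute_ecv(
            ECVInputs(
                t1_myo_pre=myo_pre,
                t1_myo_post=myo_post,
                t1_blood_pre=blood_pre,
                t1_blood_post=blood_post,
                hct=hct,
            )
        )
    mean_ecv = float(np.mean([r.ecv for r in out.values()]))
    mean_lam = float(np.mean([r.partition_coefficient for r in out.values()]))
    out["global"] = ECVResult(ecv=mean_ecv, partition_coefficient=mean_lam)
    return out
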