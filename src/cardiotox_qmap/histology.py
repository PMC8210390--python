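"""Histology quantification: collagen fraction, myocyte injury and scores.

Interstitial fibrosis is quantified from picrosirius-red-stained RGB images
by k-means clustering (k=3) in CIE L*a*b* space into collagen fiber,
cardiac muscle and background classes; the fibrosis fraction is the
collagen share of tissue pixels.  Myocyte injury arrives as per-HPF counts
of vacuolated cells per 100 cells (10 high-power fields per LV segment,
40 per subject) and is averaged; interstitial inflammation and edema are
ordinal 0-4 scores per segment (0 absent, 1 minimal, 2 mild, 3 moderate,
4 severe), averaged across segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab
from sklearn.cluster import KMeans

from .errors import DegenerateClusterError, InputError

__all__ = [
    "StainImage",
    "LabPixelCloud",
    "ClusterResult",
    "FibrosisResult",
    "HPFVacuolarCount",
    "OrdinalScore",
    "SubjectHistology",
    "rgb_to_lab",
    "kmeans_lab",
    "label_clusters",
    "fibrosis_fraction",
    "aggregate_vacuolar",
    "aggregate_scores",
]

CLASSES = ("collagen", "muscle", "background")
HPFS_PER_SEGMENT = 10
SEGMENTS = ("anterior", "posterior", "lateral", "septal")


@dataclass
class StainImage:
    """8-bit RGB stained-section image with acquisition metadata."""

    pixels: np.ndarray
    magnification: str = "x200"
    segment: str = "anterior"
    subject_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise InputError("expected a non-empty (h, w, 3) RGB image")
        if px.dtype != np.uint8:
            raise InputError("expected 8-bit RGB")
        self.pixels = px


@dataclass
class LabPixelCloud:
    """Per-pixel CIE L*a*b* values plus a link to the source image."""

    lab: np.ndarray  # (h, w, 3)
    source: StainImage | None = None

    @property
    def flat(self) -> np.ndarray:
        return self.lab.reshape(-1, 3)


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-pixel cluster id in {0, 1, 2}
    centroids: np.ndarray  # (3, 3) L*a*b* centers
    class_map: dict = field(default_factory=dict)  # cluster id -> class name
    iterations_run: int = 0
    seed: int = 0


@dataclass
class FibrosisResult:
    collagen_pixels: int
    muscle_pixels: int
    background_pixels: int
    fibrosis_fraction: float  # % of denominator pixels


@dataclass
class HPFVacuolarCount:
    """Vacuolated myocytes per 100 cells in one high-power field."""

    vacuolated_per_100: float
    segment: str = "anterior"

    def __post_init__(self) -> None:
        if not 0 <= self.vacuolated_per_100 <= 100:
            raise InputError("vacuolar count must be in [0, 100]")


@dataclass
class OrdinalScore:
    """Ordinal 0-4 severity grade for one segment and feature."""

    value: int
    feature: str = "inflammation"
    segment: str = "anterior"

    def __post_init__(self) -> None:
        if self.value not in (0, 1, 2, 3, 4):
            raise InputError("ordinal score must be an integer in 0..4")


@dataclass
class SubjectHistology:
    vacuolar_pct: float
    fibrosis_pct: float
    inflammation_score: float
    edema_score: float


def rgb_to_lab(image: StainImage) -> LabPixelCloud:
    """Deterministic sRGB (D65) -> CIE L*a*b* conversion."""
    lab = rgb2lab(image.pixels.astype(float) / 255.0)
    return LabPixelCloud(lab=lab, source=image)


def kmeans_lab(
    cloud: LabPixelCloud,
    k: int = 3,
    max_iterations: int = 100,
    restarts: int = 10,
    seed: int = 0,
) -> ClusterResult:
    """Lloyd's k-means on the L*a*b* pixel cloud.

    Runs ``restarts`` seeded initializations capped at ``max_iterations``
    Lloyd iterations each and keeps the lowest within-cluster sum of
    squares.  Deterministic given the seed.
    """
    pts = cloud.flat
    if np.unique(pts, axis=0).shape[0] < k:
        raise DegenerateClusterError(
            f"need at least {k} distinct pixel colors for k={k} clustering"
        )
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        max_iter=max_iterations,
        random_state=seed,
        algorithm="lloyd",
    ).fit(pts)
    return ClusterResult(
        labels=km.labels_.reshape(cloud.lab.shape[:2]),
        centroids=km.cluster_centers_,
        iterations_run=int(km.n_iter_),
        seed=seed,
    )


def label_clusters(result: ClusterResult) -> ClusterResult:
    """Assign tissue classes to the three clusters.

    Background is the centroid with the highest L* (near-white slide area);
    of the remaining two, collagen is the one with higher a* (picrosirius
    red stains collagen red, i.e. strongly positive a*), muscle the other.
    """
    if result.centroids.shape[0] != 3:
        raise InputError("expected exactly 3 centroids")
    c = result.centroids
    background = int(np.argmax(c[:, 0]))
    rest = [i for i in range(3) if i != background]
    collagen = rest[int(np.argmax(c[rest, 1]))]
    muscle = [i for i in rest if i != collagen][0]
    class_map = {background: "background", collagen: "collagen", muscle: "muscle"}
    return ClusterResult(
        labels=result.labels,
        centroids=result.centroids,
        class_map=class_map,
        iterations_run=result.iterations_run,
        seed=result.seed,
    )


def fibrosis_fraction(result: ClusterResult, denominator: str = "tissue") -> FibrosisResult:
    """Collagen pixel share of the image.

    With ``denominator="tissue"`` (default) the fraction is
    ``100 * collagen / (collagen + muscle)`` — interstitial fibrosis is a
    proportion of tissue, background/lumen excluded.  ``"total"`` divides by
    all pixels instead.
    """
    if not result.class_map:
        raise InputError("clusters are unlabeled; call label_clusters first")
    counts = {name: 0 for name in CLASSES}
    for cid, name in result.class_map.items():
        counts[name] = int(np.sum(result.labels == cid))
    total = int(result.labels.size)
    assert sum(counts.values()) == total
    if denominator == "tissue":
        denom = counts["collagen"] + counts["muscle"]
    elif denominator == "total":
        denom = total
    else:
        raise InputError("denominator must be 'tissue' or 'total'")
    frac = 100.0 * counts["collagen"] / denom if denom else 0.0
    return FibrosisResult(
        collagen_pixels=counts["collagen"],
        muscle_pixels=counts["muscle"],
        background_pixels=counts["background"],
        fibrosis_fraction=frac,
    )


def aggregate_vacuolar(counts: list[HPFVacuolarCount]) -> float:
    """Subject-level vacuolar change: mean over all HPFs (%).

    Emits a completeness warning when any segment has a number of HPFs
    different from the expected 10.
    """
    if not counts:
        raise InputError("no HPF counts provided")
    per_segment: dict[str, int] = {}
    for c in counts:
        per_segment[c.segment] = per_segment.get(c.segment, 0) + 1
    bad = {s: n for s, n in per_segment.items() if n != HPFS_PER_SEGMENT}
    if bad or len(per_segment) != len(SEGMENTS):
        warnings.warn(
            f"incomplete HPF sampling (expected {HPFS_PER_SEGMENT} per segment "
            f"x {len(SEGMENTS)} segments): {per_segment}",
            stacklevel=2,
        )
    return float(np.mean([c.vacuolated_per_100 for c in counts]))


def aggregate_scores(scores: list[OrdinalScore]) -> float:
    """Subject-level ordinal score: mean of segment scores.

    Quarter-step values (0.25, 1.75, ...) arise naturally from averaging
    four 0-4 integer segment grades.
    """
    if not scores:
        raise InputError("no scores provided")
    features = {s.feature for s in scores}
    if len(features) != 1:
        raise InputError(f"mixed features in one aggregation: {features}")
    return float(np.mean([s.value for s in scores]))


def cohort_median(values) -> float:
    """Cohort summary used for ordinal scores (medians, as reported)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InputError("empty cohort")
    return float(np.median(arr))
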