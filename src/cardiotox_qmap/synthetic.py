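"""Synthetic ground-truth inputs for every pipeline stage.

No imaging or histology data were deposited with the study this pipeline
quantifies, so validation runs on forward models with known truth:

* T1/T2 phantoms — mono-exponential recovery/decay signals per pixel with
  seeded Gaussian (or Rician) noise;
* short-axis contour stacks — regular polygons whose disc-summed volumes
  hit requested EDV/ESV;
* stained-tissue images — three-class (collagen / muscle / background)
  color fields with a known collagen fraction of tissue;
* cohort tables — per-group covariates drawn from truncated normals at the
  published group means, with native T1 and ECV generated by the published
  linear models so the regression stage has a known truth.

Every generator is a pure function of its spec plus a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import InputError
from .geometry import PlanarContour, SliceGeometry
from .histology import StainImage
from .relaxometry import EchoSeries, RecoverySeries

__all__ = [
    "STUDY_DESIGN",
    "cumulative_dose_mg_per_kg",
    "PhantomSpec",
    "HistologyImageSpec",
    "CohortSpec",
    "make_t1_phantom",
    "make_t2_phantom",
    "make_contour_stack",
    "make_histology_image",
    "make_cohort",
    "implied_covariate_moments",
    "implied_univariable_r",
]

# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

#: The dosing design this generator emulates: doxorubicin 1 mg/kg IV twice a
#: week for 2/4/6/8/12 weeks (groups 1-5), saline controls (group 0), eight
#: rats enrolled per treated group with deaths before completion, five
#: controls.
STUDY_DESIGN = {
    "weeks": (0, 2, 4, 6, 8, 12),
    "dose_mg_per_kg_per_injection": 1.0,
    "injections_per_week": 2,
    "enrolled_per_treated_group": 8,
    "n_treated_groups": 5,
    "deaths_per_group": (0, 2, 0, 0, 1, 1),
    "included_per_group": (5, 6, 8, 8, 7, 7),
    "hpfs_per_segment": 10,
    "segments": 4,
}


def cumulative_dose_mg_per_kg(weeks: float) -> float:
    """Cumulative doxorubicin dose for a treatment duration in weeks."""
    return (
        weeks
        * STUDY_DESIGN["injections_per_week"]
        * STUDY_DESIGN["dose_mg_per_kg_per_injection"]
    )


# ---------------------------------------------------------------------------
# MR phantoms
# ---------------------------------------------------------------------------

DEFAULT_T1_DELAYS_MS = (50.0, 100.0, 200.0, 400.0, 700.0, 1100.0, 1600.0, 2200.0, 3000.0, 4000.0)
DEFAULT_T2_ECHOES_MS = (16.0, 26.0, 36.0)


@dataclass
class PhantomSpec:
    """Forward-model spec for a relaxometry phantom.

    ``region_map`` is an integer label image; ``values_ms`` maps each label
    to its truth relaxation time.  ``noise_sd`` is in signal units
    (amplitude defaults to 1000, so SNR 50 means ``noise_sd = 20``).
    """

    region_map: np.ndarray = None
    values_ms: dict = None
    timing_ms: tuple = DEFAULT_T1_DELAYS_MS
    amplitude: float = 1000.0
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_map is None:
            self.region_map = two_region_map()
        if self.values_ms is None:
            self.values_ms = {0: 1148.0, 1: 1320.0}
        self.region_map = np.asarray(self.region_map, dtype=int)
        if any(v <= 0 for v in self.values_ms.values()):
            raise InputError("truth relaxation times must be positive")
        t = np.asarray(self.timing_ms, dtype=float)
        if np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise InputError("timing must be positive and strictly increasing")
        if self.noise_model not in ("gaussian", "rician"):
            raise InputError("noise_model must be 'gaussian' or 'rician'")


def two_region_map(shape: tuple = (32, 32)) -> np.ndarray:
    """Left/right half-plane label image (labels 0 and 1)."""
    m = np.zeros(shape, dtype=int)
    m[:, shape[1] // 2 :] = 1
    return m


def _truth_map(spec: PhantomSpec) -> np.ndarray:
    truth = np.zeros(spec.region_map.shape, dtype=float)
    for label, value in spec.values_ms.items():
        truth[spec.region_map == label] = value
    return truth


def _add_noise(clean: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sd == 0:
        return clean
    if spec.noise_model == "gaussian":
        noisy = clean + rng.normal(0.0, spec.noise_sd, clean.shape)
        return np.clip(noisy, 0.0, None)
    # Rician: magnitude of a complex signal with independent Gaussian parts
    re = clean + rng.normal(0.0, spec.noise_sd, clean.shape)
    im = rng.normal(0.0, spec.noise_sd, clean.shape)
    return np.hypot(re, im)


def make_t1_phantom(spec: PhantomSpec) -> tuple[RecoverySeries, np.ndarray]:
    """Saturation-recovery series ``M = A - B exp(-TD/T1)`` with A = B."""
    rng = np.random.default_rng(spec.seed)
    truth = _truth_map(spec)
    td = np.asarray(spec.timing_ms, dtype=float)
    a = spec.amplitude
    clean = a - a * np.exp(-td[:, None, None] / truth[None, :, :])
    series = RecoverySeries(frames=_add_noise(clean, spec, rng), delays=td)
    return series, truth


def make_t2_phantom(spec: PhantomSpec) -> tuple[EchoSeries, np.ndarray]:
    """Multi-echo decay series ``S = S0 exp(-TE/T2)``."""
    if spec.timing_ms is DEFAULT_T1_DELAYS_MS:
        spec = PhantomSpec(
            region_map=spec.region_map,
            values_ms=spec.values_ms,
            timing_ms=DEFAULT_T2_ECHOES_MS,
            amplitude=spec.amplitude,
            noise_model=spec.noise_model,
            noise_sd=spec.noise_sd,
            seed=spec.seed,
        )
    rng = np.random.default_rng(spec.seed)
    truth = _truth_map(spec)
    te = np.asarray(spec.timing_ms, dtype=float)
    clean = spec.amplitude * np.exp(-te[:, None, None] / truth[None, :, :])
    series = EchoSeries(frames=_add_noise(clean, spec, rng), echoes=te)
    return series, truth


# ---------------------------------------------------------------------------
# contour stacks
# ---------------------------------------------------------------------------


def _circle_contour(area_mm2: float, center, n_vertices: int, slice_index: int, phase: str) -> PlanarContour:
    # radius chosen so the *polygon* area equals the target exactly
    r = math.sqrt(2.0 * area_mm2 / (n_vertices * math.sin(2.0 * math.pi / n_vertices)))
    ang = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    verts = np.column_stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)])
    return PlanarContour(verts, slice_index=slice_index, phase=phase)


def make_contour_stack(
    edv_ml: float,
    esv_ml: float,
    n_slices: int = 5,
    thickness_mm: float = 2.0,
    gap_mm: float = 0.0,
    wall_volume_ml: float = 0.63,
    n_vertices: int = 128,
    center=(0.0, 0.0),
) -> tuple[dict, dict]:
    """Circular endo/epi contour stacks hitting target ED/ES volumes.

    Returns ``{"ED": [SliceGeometry...], "ES": [...]}`` plus a truth dict.
    Polygon areas are chosen so the summation-of-discs volumes equal the
    requested values to well under 0.5%.
    """
    if edv_ml <= 0 or esv_ml < 0 or esv_ml > edv_ml:
        raise InputError("need 0 <= ESV <= EDV and EDV > 0")
    eff = thickness_mm + gap_mm
    out: dict[str, list[SliceGeometry]] = {}
    for phase, vol in (("ED", edv_ml), ("ES", esv_ml)):
        endo_area = vol * 1000.0 / (n_slices * eff)
        epi_area = endo_area + wall_volume_ml * 1000.0 / (n_slices * eff)
        slices = []
        for k in range(n_slices):
            endo = _circle_contour(endo_area, center, n_vertices, k, phase)
            epi = _circle_contour(epi_area, center, n_vertices, k, phase)
            slices.append(SliceGeometry(endo=endo, epi=epi, thickness=thickness_mm, gap=gap_mm))
        out[phase] = slices
    truth = {
        "EDV_ml": edv_ml,
        "ESV_ml": esv_ml,
        "SV_ml": edv_ml - esv_ml,
        "EF_pct": 100.0 * (edv_ml - esv_ml) / edv_ml,
        "wall_volume_ml": wall_volume_ml,
    }
    return out, truth


# ---------------------------------------------------------------------------
# histology images
# ---------------------------------------------------------------------------

#: Picrosirius-red-like palette: collagen deep red, muscle pale yellow-pink,
#: background (slide / lumen) near white.  RGB means, one shared channel SD.
DEFAULT_STAIN_PALETTE = {
    "collagen": (150.0, 35.0, 60.0),
    "muscle": (235.0, 170.0, 160.0),
    "background": (248.0, 245.0, 242.0),
}

CLASS_CODES = {"collagen": 0, "muscle": 1, "background": 2}


@dataclass
class HistologyImageSpec:
    """Spec for a three-class stained-tissue image with known truth."""

    shape: tuple = (96, 96)
    collagen_fraction_pct: float = 6.25  # % of tissue pixels
    background_fraction: float = 0.2  # fraction of all pixels
    palette: dict = field(default_factory=lambda: dict(DEFAULT_STAIN_PALETTE))
    color_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.collagen_fraction_pct <= 100:
            raise InputError("collagen fraction must be in [0, 100]%")
        if not 0 <= self.background_fraction < 1:
            raise InputError("background fraction must be in [0, 1)")
        means = [tuple(v) for v in self.palette.values()]
        if len(set(means)) != 3:
            raise InputError("class colors must be pairwise distinct")


def make_histology_image(spec: HistologyImageSpec) -> tuple[StainImage, np.ndarray]:
    """Generate a stained image and its truth label map (class codes)."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.shape[0] * spec.shape[1]
    n_bg = round(spec.background_fraction * n_total)
    n_tissue = n_total - n_bg
    n_collagen = round(spec.collagen_fraction_pct / 100.0 * n_tissue)
    n_muscle = n_tissue - n_collagen

    flat_labels = np.empty(n_total, dtype=int)
    order = rng.permutation(n_total)
    flat_labels[order[:n_collagen]] = CLASS_CODES["collagen"]
    flat_labels[order[n_collagen : n_collagen + n_muscle]] = CLASS_CODES["muscle"]
    flat_labels[order[n_collagen + n_muscle :]] = CLASS_CODES["background"]
    labels = flat_labels.reshape(spec.shape)

    pixels = np.empty(spec.shape + (3,), dtype=float)
    for name, code in CLASS_CODES.items():
        sel = labels == code
        mean = np.asarray(spec.palette[name], dtype=float)
        pixels[sel] = mean + rng.normal(0.0, spec.color_sd, (int(sel.sum()), 3))
    image = StainImage(pixels=np.clip(np.rint(pixels), 0, 255).astype(np.uint8))
    return image, labels


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

#: Per-group (mean, SD) for the physiology/CMR variables the comparison
#: stage consumes, groups 0 (control) through 5 (12-week).
GROUP_PHYSIOLOGY = {
    "hct": [(58.8, 2.0), (41.6, 13.0), (46.3, 10.0), (40.5, 12.0), (43.9, 12.0), (43.0, 14.0)],
    "HR": [(281, 30), (270, 24), (280, 35), (271, 28), (279, 51), (292, 51)],
    "LVEDV": [(0.69, 0.05), (0.73, 0.09), (0.68, 0.09), (0.77, 0.05), (0.69, 0.09), (0.63, 0.01)],
    "LVESV": [(0.18, 0.02), (0.20, 0.04), (0.23, 0.03), (0.27, 0.04), (0.24, 0.06), (0.26, 0.07)],
    "LVmass": [(0.66, 0.08), (0.69, 0.09), (0.67, 0.14), (0.74, 0.11), (0.64, 0.08), (0.61, 0.06)],
    "t2": [(10.3, 1.0), (12.2, 1.0), (11.4, 1.0), (16.3, 2.0), (17.3, 5.0), (14.0, 2.0)],
}

#: Per-group (mean, SD) for the histology covariates.  The source figures
#: report group means (or medians for the ordinal scores) with ranges; SDs
#: default to range/4.
GROUP_HISTOLOGY = {
    "vacuolar_pct": [(0.0, 0.0), (0.5, 0.575), (11.2, 7.8), (13.4, 7.25), (12.7, 8.1), (16.5, 7.475)],
    "fibrosis_pct": [(1.2, 0.15), (2.2, 0.7), (2.1, 0.475), (4.5, 3.075), (6.7, 5.075), (11.0, 5.575)],
    "inflammation_score": [(0.0, 0.1), (0.25, 0.125), (1.0, 0.5), (1.75, 0.75), (0.75, 0.5), (0.5, 0.8125)],
    "edema_score": [(0.0, 0.1), (0.25, 0.3125), (1.0, 0.4375), (1.25, 0.75), (1.5, 0.875), (1.0, 0.75)],
}

COVARIATE_BOUNDS = {
    "vacuolar_pct": (0.0, 100.0),
    "fibrosis_pct": (0.0, 100.0),
    "inflammation_score": (0.0, 4.0),
    "edema_score": (0.0, 4.0),
}

COVARIATES = ("vacuolar_pct", "fibrosis_pct", "inflammation_score", "edema_score")

#: Generating linear models (slopes from the published multivariable fits):
#: native T1 on vacuolar change, inflammation and edema; ECV on all four.
BETA_T1 = {"const": 1148.0, "vacuolar_pct": 4.7, "inflammation_score": 21.0, "edema_score": -1.7}
BETA_ECV = {
    "const": 14.3 - 0.44 * 1.2,  # anchors the control-group mean ECV at 14.3%
    "vacuolar_pct": 0.17,
    "fibrosis_pct": 0.44,
    "inflammation_score": 0.60,
    "edema_score": -0.39,
}

#: Univariable correlations the residual noise is calibrated to reproduce:
#: the strongest published predictor for each outcome.
R_ANCHOR_T1 = ("vacuolar_pct", 0.60)
R_ANCHOR_ECV = ("fibrosis_pct", 0.78)


@dataclass
class CohortSpec:
    """Spec for a synthetic cohort with known regression truth.

    ``sigma_t1`` / ``sigma_ecv`` are the residual SDs of the generating
    linear models; ``None`` calibrates them analytically so the implied
    univariable correlations match the anchors (T1~vacuolar R=0.60,
    ECV~fibrosis R=0.78).
    """

    group_sizes: tuple = tuple(STUDY_DESIGN["included_per_group"])
    physiology: dict = field(default_factory=lambda: {k: list(v) for k, v in GROUP_PHYSIOLOGY.items()})
    histology: dict = field(default_factory=lambda: {k: list(v) for k, v in GROUP_HISTOLOGY.items()})
    beta_t1: dict = field(default_factory=lambda: dict(BETA_T1))
    beta_ecv: dict = field(default_factory=lambda: dict(BETA_ECV))
    sigma_t1: float | None = None
    sigma_ecv: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise InputError("group sizes must be >= 2")
        for table in (self.physiology, self.histology):
            for name, rows in table.items():
                if len(rows) != len(self.group_sizes):
                    raise InputError(f"{name}: need one (mean, sd) per group")
                if any(sd < 0 for _, sd in rows):
                    raise InputError(f"{name}: SDs must be >= 0")


def _trunc_moments(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Mean and variance of a truncated normal (degenerate SD allowed)."""
    if sd == 0:
        return mean, 0.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    m, v = truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
    return float(m), float(v)


def _trunc_draw(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def implied_covariate_moments(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Population mean vector and covariance matrix of the four covariates.

    Within a group the covariates are independent truncated normals; across
    the cohort the group structure induces between-group covariance.  Both
    pieces follow in closed form from the truncated-normal moments.
    """
    w = np.asarray(spec.group_sizes, dtype=float)
    w = w / w.sum()
    k = len(COVARIATES)
    means = np.zeros((len(w), k))
    variances = np.zeros((len(w), k))
    for j, name in enumerate(COVARIATES):
        lo, hi = COVARIATE_BOUNDS[name]
        for g, (m, s) in enumerate(spec.histology[name]):
            means[g, j], variances[g, j] = _trunc_moments(m, s, lo, hi)
    mu = w @ means
    # cov = within-group (diagonal) + between-group (means about mu)
    cov = np.diag(w @ variances)
    centered = means - mu
    cov += (centered * w[:, None]).T @ centered
    return mu, cov


def _model_arrays(beta: dict) -> tuple[float, np.ndarray]:
    b = np.array([beta.get(name, 0.0) for name in COVARIATES])
    return float(beta.get("const", 0.0)), b


def _calibrated_sigma(spec: CohortSpec, beta: dict, anchor: tuple) -> float:
    """Residual SD making the implied univariable R hit the anchor value."""
    name, r_target = anchor
    _, cov = implied_covariate_moments(spec)
    _, b = _model_arrays(beta)
    j = COVARIATES.index(name)
    cov_yx = (cov @ b)[j]
    var_signal = float(b @ cov @ b)
    var_needed = cov_yx**2 / (r_target**2 * cov[j, j])
    var_resid = var_needed - var_signal
    if var_resid <= 0:
        raise InputError(
            f"anchor R={r_target} for {name} is unattainable: signal alone "
            f"already correlates more weakly"
        )
    return math.sqrt(var_resid)


def implied_univariable_r(spec: CohortSpec, outcome: str, covariate: str) -> float:
    """Population correlation between an outcome and one covariate."""
    beta = spec.beta_t1 if outcome == "native_t1" else spec.beta_ecv
    sigma = resolved_sigmas(spec)["native_t1" if outcome == "native_t1" else "ecv"]
    _, cov = implied_covariate_moments(spec)
    _, b = _model_arrays(beta)
    j = COVARIATES.index(covariate)
    var_y = float(b @ cov @ b) + sigma**2
    return float((cov @ b)[j] / math.sqrt(var_y * cov[j, j]))


def resolved_sigmas(spec: CohortSpec) -> dict:
    return {
        "native_t1": spec.sigma_t1
        if spec.sigma_t1 is not None
        else _calibrated_sigma(spec, spec.beta_t1, R_ANCHOR_T1),
        "ecv": spec.sigma_ecv
        if spec.sigma_ecv is not None
        else _calibrated_sigma(spec, spec.beta_ecv, R_ANCHOR_ECV),
    }


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table and return it with the generating truth.

    Histology covariates are truncated-normal per group; native T1 and ECV
    follow the generating linear models plus Gaussian residuals; stroke
    volume, ejection fraction and cardiac output are derived identities,
    and the partition coefficient is ECV/(1-Hct).
    """
    rng = np.random.default_rng(spec.seed)
    sigmas = resolved_sigmas(spec)
    rows = []
    subject = 0
    for g, n in enumerate(spec.group_sizes):
        draws = {}
        for name in COVARIATES:
            lo, hi = COVARIATE_BOUNDS[name]
            m, s = spec.histology[name][g]
            draws[name] = _trunc_draw(rng, m, s, lo, hi, n)
        for name, bounds in (
            ("hct", (0.0, 100.0)),
            ("HR", (0.0, np.inf)),
            ("LVEDV", (0.0, np.inf)),
            ("LVmass", (0.0, np.inf)),
            ("t2", (0.0, np.inf)),
        ):
            m, s = spec.physiology[name][g]
            draws[name] = _trunc_draw(rng, m, s, bounds[0], bounds[1], n)
        m, s = spec.physiology["LVESV"][g]
        draws["LVESV"] = np.array(
            [_trunc_draw(rng, m, s, 0.0, edv, 1)[0] for edv in draws["LVEDV"]]
        )
        c_t1, b_t1 = _model_arrays(spec.beta_t1)
        c_ecv, b_ecv = _model_arrays(spec.beta_ecv)
        x = np.column_stack([draws[name] for name in COVARIATES])
        t1 = c_t1 + x @ b_t1 + rng.normal(0.0, sigmas["native_t1"], n)
        ecv = c_ecv + x @ b_ecv + rng.normal(0.0, sigmas["ecv"], n)
        for i in range(n):
            edv, esv, hr = draws["LVEDV"][i], draws["LVESV"][i], draws["HR"][i]
            sv = edv - esv
            rows.append(
                {
                    "subject": f"S{subject:02d}",
                    "group": g,
                    "hct": draws["hct"][i],
                    "HR": hr,
                    "LVEDV": edv,
                    "LVESV": esv,
                    "LVSV": sv,
                    "CO": sv * hr / 1000.0,
                    "LVmass": draws["LVmass"][i],
                    "LVEF": 100.0 * sv / edv,
                    "native_t1": t1[i],
                    "t2": draws["t2"][i],
                    "ecv": ecv[i],
                    "partition_coefficient": ecv[i] / 100.0 / (1.0 - draws["hct"][i] / 100.0),
                    "vacuolar_pct": draws["vacuolar_pct"][i],
                    "fibrosis_pct": draws["fibrosis_pct"][i],
                    "inflammation_score": draws["inflammation_score"][i],
                    "edema_score": draws["edema_score"][i],
                }
            )
            subject += 1
    table = pd.DataFrame(rows)
    truth = {
        "beta_t1": dict(spec.beta_t1),
        "beta_ecv": dict(spec.beta_ecv),
        "sigma_t1": sigmas["native_t1"],
        "sigma_ecv": sigmas["ecv"],
        "group_sizes": list(spec.group_sizes),
        "n_treated": int(sum(spec.group_sizes[1:])),
        "n_total": int(sum(spec.group_sizes)),
    }
    return table, truth
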