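"""Synthetic omentum-like CT slices and simulated matched cohorts.

Every downstream stage (texture extraction, matched statistics, ROC
validation) is exercised on data from this module, so its defaults define
the study conditions: a test cohort of 41 matched pairs and a validation
cohort of 10 pairs, each pair sharing its clinical T/N stratum, with
clinical covariates drawn identically for both groups (null clinical
effect).

Images emulate an axial slice through omental fat: stored gray values
(HU + 1024, fat baseline ~920) plus a spatially smoothed Gaussian noise
field.  The occult-carcinomatosis group receives two extra heterogeneity
sources: (a) additional spatially *uncorrelated* noise raising the marginal
SD from ``noise_sd_control`` to ``noise_sd_case`` while diluting the lag-1
co-occurrence correlation, and (b) a Poisson number of small bright nodules
(micro-deposits).  Together these push the occult group toward higher SD and
entropy and lower GLCM correlation — the direction structure observed in the
reference study — without touching the controls.

A feature-level generator is also provided for statistics-stage tests that
need cohorts with exactly controlled effect sizes, bypassing images.

Randomness: one global seed expands into per-patient substreams through
``numpy.random.SeedSequence`` spawn keys, so each patient's data is
reproducible independently of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .texture import rasterize_polygon

__all__ = [
    "SimConfig",
    "DEFAULT_FEATURE_MODEL",
    "TABLE1_EFFECT",
    "MIN_ROI_PIXELS",
    "gen_image",
    "gen_cohort",
    "gen_feature_table",
    "validate_cohort",
    "patient_rng",
    "COHORT_COLUMNS",
    "FEATURE_COLUMNS",
]

#: minimum accepted ROI size after rasterization (smallest ROI in the
#: reference study's range of 157-5128 pixels)
MIN_ROI_PIXELS = 157

COHORT_COLUMNS = [
    "patient_id",
    "group",
    "pair_id",
    "cohort",
    "age",
    "sex",
    "bmi",
    "ascites",
    "grade",
    "cT",
    "cN",
]

FEATURE_COLUMNS = [
    "average",
    "std_dev",
    "kurtosis",
    "skewness",
    "entropy",
    "correlation_standard",
    "correlation_paper_scale",
    "contrast",
    "n_pixels",
]

#: test-cohort clinical T/N strata with their per-group counts (41 pairs)
TEST_STRATA: tuple[tuple[str, str, int], ...] = (
    ("T2", "N0", 2),
    ("T3-4a", "N0", 6),
    ("T3-4a", "N1", 10),
    ("T3-4a", "N2", 17),
    ("T4b", "N1", 4),
    ("T4b", "N2", 2),
)
#: validation-cohort strata (10 pairs)
VALIDATION_STRATA: tuple[tuple[str, str, int], ...] = (
    ("T3-4a", "N0", 5),
    ("T3-4a", "N1", 2),
    ("T3-4a", "N2", 3),
)


def _default_clinical_margins() -> dict:
    # identical for both groups: the matched design has no clinical effect
    return {
        "age_mean": 60.0,
        "age_sd": 10.0,
        "age_range": (25.0, 90.0),
        "p_male": 0.65,
        "bmi_mean": 22.0,
        "bmi_sd": 2.2,
        "bmi_range": (15.0, 35.0),
        "p_ascites": 10.0 / 41.0,
        "p_md": 0.40,  # moderately differentiated vs poorly differentiated / signet ring
    }


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic generator.

    Gray values are stored values (HU + 1024) unless ``signed_hu`` is set, in
    which case ``base_level`` and ``nodule_intensity`` are interpreted on the
    signed HU scale and offset by 1024 internally.
    """

    seed: int = 0
    n_pairs_test: int = 41
    n_pairs_validation: int = 10
    image_size: int = 128
    base_level: float = 920.0  # stored value of omental fat (~ -104 HU)
    noise_sd_control: float = 15.0  # matches the control-group SD scale
    noise_sd_case: float = 24.0  # occult-group SD scale
    smoothing_scale: float = 2.0  # Gaussian kernel sigma, pixels
    nodule_rate_case: float = 3.0  # expected nodules per occult ROI
    nodule_intensity: float = 60.0  # gray-value offset of a nodule
    nodule_radius: float = 2.0  # pixels
    # between-patient dispersion of the noise level (lognormal CV); real
    # cohorts are not homogeneous within a group — the reported entropy IQRs
    # (~0.3 wide) correspond to a ~15% spread of the underlying noise SD
    patient_sd_cv: float = 0.15
    signed_hu: bool = False
    clinical_margins: Mapping[str, object] = field(default_factory=_default_clinical_margins)

    def __post_init__(self):
        if self.n_pairs_test < 1 or self.n_pairs_validation < 1:
            raise ValueError("n_pairs_* must be >= 1")
        if not (self.noise_sd_case >= self.noise_sd_control >= 0):
            raise ValueError("need noise_sd_case >= noise_sd_control >= 0")
        base = self.base_level + (1024.0 if self.signed_hu else 0.0)
        if not (0 <= base <= 65535):
            raise ValueError("base_level outside the storable range")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.nodule_rate_case < 0 or self.nodule_radius <= 0:
            raise ValueError("nodule parameters must be non-negative")
        if self.patient_sd_cv < 0:
            raise ValueError("patient_sd_cv must be >= 0")

    @property
    def stored_base(self) -> float:
        return self.base_level + (1024.0 if self.signed_hu else 0.0)

    @property
    def stored_nodule_intensity(self) -> float:
        return self.nodule_intensity

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def patient_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based per-patient random substream.

    ``key`` identifies the patient (e.g. cohort index, pair index, member
    index); the stream is independent of the order patients are generated in.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key)))


# --------------------------------------------------------------------------
# image generation
# --------------------------------------------------------------------------


def _star_polygon(rng: np.random.Generator, size: int, radius_frac: tuple[float, float]) -> np.ndarray:
    """Random star-shaped (hence simple) polygon around the image center."""
    n_vert = int(rng.integers(8, 14))
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
    radii = rng.uniform(radius_frac[0] * size, radius_frac[1] * size, n_vert)
    cx = cy = size / 2.0
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return np.column_stack([xs, ys])


def gen_image(
    config: SimConfig,
    group: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one synthetic omentum slice and its polygonal ROI.

    Returns ``(image, vertices)``: a uint16 array of stored gray values and an
    ``(n, 2)`` float array of ROI vertices.  The image is the fat baseline plus
    a smoothed Gaussian field rescaled to the group's marginal SD; the occult
    group additionally receives uncorrelated excess noise and Poisson-seeded
    bright nodules inside the ROI.  ROIs smaller than ``MIN_ROI_PIXELS`` after
    rasterization are regenerated with a larger polygon.
    """
    if group not in ("occult", "control"):
        raise ValueError(f"invalid group label {group!r}")
    size = config.image_size

    # patient-level noise dispersion (unit-mean lognormal factor)
    cv = config.patient_sd_cv
    factor = float(np.exp(cv * rng.standard_normal() - cv**2 / 2.0)) if cv > 0 else 1.0

    # smoothed field, rescaled to this patient's baseline marginal SD
    white = rng.standard_normal((size, size))
    if config.smoothing_scale > 0:
        smooth = ndimage.gaussian_filter(white, config.smoothing_scale, mode="reflect")
        sd = smooth.std()
        smooth = smooth / sd if sd > 0 else smooth
    else:
        smooth = white
    img = config.stored_base + factor * config.noise_sd_control * smooth

    if group == "occult":
        excess = config.noise_sd_case**2 - config.noise_sd_control**2
        if excess > 0:
            img = img + factor * np.sqrt(excess) * rng.standard_normal((size, size))

    # ROI polygon; regenerate larger until the rasterized mask is big enough
    radius_frac = (0.22, 0.42)
    for _ in range(20):
        verts = _star_polygon(rng, size, radius_frac)
        try:
            mask = rasterize_polygon(verts, (size, size))
        except ValueError:
            radius_frac = (radius_frac[0] * 1.2, min(0.48, radius_frac[1] * 1.2))
            continue
        if int(mask.sum()) >= MIN_ROI_PIXELS:
            break
        radius_frac = (radius_frac[0] * 1.2, min(0.48, radius_frac[1] * 1.2))
    else:
        raise RuntimeError("failed to generate a large enough ROI")

    if group == "occult" and config.nodule_rate_case > 0:
        n_nodules = int(rng.poisson(config.nodule_rate_case))
        rows, cols = np.nonzero(mask)
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_nodules):
            k = int(rng.integers(rows.size))
            cy, cx = rows[k], cols[k]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= config.nodule_radius**2
            img = img + config.stored_nodule_intensity * disk

    image = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return image, verts


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


def _sample_strata(rng: np.random.Generator, n_pairs: int, strata: Sequence[tuple[str, str, int]]):
    counts = np.array([c for _, _, c in strata], dtype=float)
    total = int(counts.sum())
    if n_pairs == total:
        labels = [(t, n) for t, n, c in strata for _ in range(c)]
    else:
        idx = rng.choice(len(strata), size=n_pairs, p=counts / counts.sum())
        labels = [(strata[i][0], strata[i][1]) for i in idx]
    return labels


def _clinical_record(rng: np.random.Generator, margins: Mapping) -> dict:
    age = float(np.clip(rng.normal(margins["age_mean"], margins["age_sd"]), *margins["age_range"]))
    bmi = float(np.clip(rng.normal(margins["bmi_mean"], margins["bmi_sd"]), *margins["bmi_range"]))
    return {
        "age": round(age, 1),
        "sex": "M" if rng.random() < margins["p_male"] else "F",
        "bmi": round(bmi, 1),
        "ascites": "present" if rng.random() < margins["p_ascites"] else "absent",
        "grade": "MD" if rng.random() < margins["p_md"] else "PD-SRC",
    }


def gen_cohort(
    config: SimConfig,
    with_images: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the test and validation cohorts.

    Returns ``(test, validation, images)`` where the DataFrames follow
    ``COHORT_COLUMNS`` and ``images`` maps patient_id to ``(image, vertices)``
    (empty when ``with_images`` is false).  Both members of a pair share their
    cT/cN stratum, and clinical covariates are drawn from the same margins for
    cases and controls (null clinical effect by construction).
    """
    images: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    frames = []
    for cohort_idx, (cohort_name, n_pairs, strata) in enumerate(
        [("test", config.n_pairs_test, TEST_STRATA), ("validation", config.n_pairs_validation, VALIDATION_STRATA)]
    ):
        strata_rng = patient_rng(config.seed, cohort_idx, 0, 0, 99)
        pair_strata = _sample_strata(strata_rng, n_pairs, strata)
        rows = []
        for pair_idx in range(n_pairs):
            ct, cn = pair_strata[pair_idx]
            for member_idx, group in enumerate(["occult", "control"]):
                rng = patient_rng(config.seed, cohort_idx, pair_idx, member_idx, 0)
                pid = f"{cohort_name[0].upper()}{pair_idx + 1:03d}{'A' if group == 'occult' else 'B'}"
                rec = {
                    "patient_id": pid,
                    "group": group,
                    "pair_id": f"{cohort_name[0].upper()}{pair_idx + 1:03d}",
                    "cohort": cohort_name,
                    **_clinical_record(rng, config.clinical_margins),
                    "cT": ct,
                    "cN": cn,
                }
                rows.append(rec)
                if with_images:
                    img_rng = patient_rng(config.seed, cohort_idx, pair_idx, member_idx, 1)
                    images[pid] = gen_image(config, group, img_rng)
        frames.append(pd.DataFrame(rows, columns=COHORT_COLUMNS))
    test, validation = frames
    validate_cohort(test)
    validate_cohort(validation)
    return test, validation, images


# --------------------------------------------------------------------------
# feature-level simulator
# --------------------------------------------------------------------------

#: Control-group feature distribution: locations on the scale of the
#: reference study's control medians, spreads back-solved from the reported
#: interquartile ranges (IQR / 1.349 for a normal marginal).
DEFAULT_FEATURE_MODEL = {
    "means": {
        "average": 920.0,
        "contrast": 134.0,
        "correlation_standard": 0.65,
        "correlation_paper_scale": 0.003,
        "entropy": 7.0,
        "kurtosis": 0.36,
        "skewness": 0.32,
        "std_dev": 14.6,
    },
    "sds": {
        "average": 18.0,
        "contrast": 35.0,
        "correlation_standard": 0.08,
        "correlation_paper_scale": 0.00075,
        "entropy": 0.22,
        "kurtosis": 0.92,
        "skewness": 0.45,
        "std_dev": 3.4,
    },
    # one-factor dependence: all seven features are functionals of the same
    # underlying ROI heterogeneity, so they co-vary strongly (correlation
    # variants load negatively — more heterogeneity, less gray-tone linear
    # dependence); corr(f, g) = loading_f * loading_g for f != g
    "loadings": {
        "average": 0.6,
        "contrast": 0.7,
        "correlation_standard": -0.7,
        "correlation_paper_scale": -0.7,
        "entropy": 0.85,
        "kurtosis": 0.2,
        "skewness": 0.3,
        "std_dev": 0.85,
    },
}

#: Case-minus-control location shifts matching the reference study's
#: median gaps (occult higher average/entropy/SD, lower correlation).
TABLE1_EFFECT = {
    "average": 29.0,
    "contrast": 37.0,
    "correlation_standard": -0.08,
    "correlation_paper_scale": -0.001,
    "entropy": 0.3,
    "kurtosis": 0.06,
    "skewness": 0.2,
    "std_dev": 9.2,
}

_FEATURE_ORDER = tuple(DEFAULT_FEATURE_MODEL["means"].keys())


def _feature_cov(model: Mapping) -> np.ndarray:
    names = _FEATURE_ORDER
    sds = np.array([model["sds"][f] for f in names])
    if "corr_matrix" in model:
        corr = np.asarray(model["corr_matrix"], dtype=float)
        if corr.shape != (len(names), len(names)):
            raise ValueError("corr_matrix must be 8x8 in canonical feature order")
    else:
        lam = np.array([float(model["loadings"].get(f, 0.0)) for f in names])
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("feature correlation structure is not positive definite") from None
    return cov


def gen_feature_table(
    config: SimConfig,
    effect: Mapping[str, float] | None = None,
    model: Mapping | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate matched cohorts with features drawn directly from a model.

    Features come from group-specific multivariate normals: controls at the
    model means, cases shifted by ``effect`` (case minus control, default
    the reference-scale shifts ``TABLE1_EFFECT``; pass ``{}`` for a global
    null).  Clinical covariates are generated exactly as in ``gen_cohort``.
    Returns ``(test, validation)`` DataFrames with feature columns appended.
    """
    if effect is None:
        effect = TABLE1_EFFECT
    if model is None:
        model = DEFAULT_FEATURE_MODEL
    cov = _feature_cov(model)
    mean_ctrl = np.array([model["means"][f] for f in _FEATURE_ORDER])
    shift = np.array([float(effect.get(f, 0.0)) for f in _FEATURE_ORDER])
    chol = np.linalg.cholesky(cov)

    test, validation, _ = gen_cohort(config, with_images=False)
    out = []
    for cohort_idx, df in enumerate([test, validation]):
        df = df.copy()
        feats = np.empty((len(df), len(_FEATURE_ORDER)))
        for row_pos, (_, rec) in enumerate(df.iterrows()):
            pair_idx = int(rec["pair_id"][1:]) - 1
            member_idx = 0 if rec["group"] == "occult" else 1
            rng = patient_rng(config.seed, cohort_idx, pair_idx, member_idx, 2)
            mu = mean_ctrl + (shift if rec["group"] == "occult" else 0.0)
            feats[row_pos] = mu + chol @ rng.standard_normal(len(_FEATURE_ORDER))
        for j, name in enumerate(_FEATURE_ORDER):
            df[name] = feats[:, j]
        df["n_pixels"] = 0
        out.append(df)
    return out[0], out[1]


# --------------------------------------------------------------------------
# cohort validation
# --------------------------------------------------------------------------


def validate_cohort(df: pd.DataFrame) -> None:
    """Check matched-cohort integrity; raise ValueError naming the offender.

    Enforced invariants: required columns present, unique patient ids, each
    pair_id has exactly one occult and one control member, and both members
    share their cT/cN stratum.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing column(s): {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id: {dup.iloc[0]!r}")
    bad_group = df.loc[~df["group"].isin(["occult", "control"]), "group"]
    if len(bad_group):
        raise ValueError(f"invalid group label: {bad_group.iloc[0]!r}")
    for pair_id, sub in df.groupby("pair_id"):
        groups = sorted(sub["group"])
        if groups != ["control", "occult"]:
            raise ValueError(f"pair {pair_id!r} is not one occult + one control")
        if sub["cT"].nunique() != 1 or sub["cN"].nunique() != 1:
            raise ValueError(f"pair {pair_id!r} members differ in cT/cN stratum")
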