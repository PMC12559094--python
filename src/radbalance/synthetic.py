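"""Synthetic radiograph-cohort generator and model-output simulators.

Stands in for a real pediatric wrist-radiograph dataset and the trained
networks evaluated on it.  :func:`generate_cohort` draws per-image metadata
(age, gender, laterality, projection, study type, fracture presence,
radiologist difficulty grade, diagnosis-uncertain flag) from configurable
marginal distributions; :func:`simulate_classifier` and
:func:`simulate_detector` emit per-image fracture scores and localized
detections whose quality depends on the image's difficulty stratum, so that
harder cases are genuinely harder for the simulated models.

All draws come from one ``numpy`` Generator per call, seeded explicitly:
identical config + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import BoundingBox, ClassScore, Detection, ImageRecord

__all__ = [
    "CohortConfig",
    "VariantProfile",
    "STRATA",
    "generate_cohort",
    "simulate_classifier",
    "simulate_detector",
    "beta_shapes",
    "table2_defaults",
    "classifier_ladder",
    "detector_ladder",
]

#: Prediction-difficulty strata, keyed the way :attr:`ImageRecord.stratum` reports them.
STRATA = ("easy_fracture", "difficult_fracture", "no_fracture")
_FRACTURE_STRATA = ("easy_fracture", "difficult_fracture")


def beta_shapes(mean: float, concentration: float) -> tuple[float, float]:
    """Beta shape pair (a, b) with the given mean and a + b = concentration."""
    if not (0.0 < mean < 1.0) or concentration <= 0:
        raise ValueError("need 0 < mean < 1 and concentration > 0")
    return mean * concentration, (1.0 - mean) * concentration


@dataclass
class CohortConfig:
    """Marginal distributions for one synthetic cohort.

    Ages are drawn from a normal truncated to ``[age_min, age_max]``;
    categorical fields are drawn independently with the stated probabilities.
    ``p_difficult_given_fracture`` is the conditional probability that a
    fracture image is graded difficult; non-fracture images carry the
    ``not_applicable`` grade.  ``boxes_per_fracture`` maps a box count to its
    probability for fracture-positive images.
    """

    n_images: int = 20000
    age_mean: float = 10.9
    age_sd: float = 3.58
    age_min: float = 0.4
    age_max: float = 18.7
    p_female: float = 0.42
    p_left: float = 0.56
    p_projection: tuple[float, float, float] = (0.4825, 0.5114, 0.0061)
    p_initial: float = 0.22
    p_fracture: float = 0.68
    p_difficult_given_fracture: float = 273.0 / 3132.0
    p_uncertain: float = 0.03
    image_width: int = 640
    image_height: int = 640
    boxes_per_fracture: dict[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.25, 3: 0.05}
    )
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_female,
            self.p_left,
            self.p_initial,
            self.p_fracture,
            self.p_difficult_given_fracture,
            self.p_uncertain,
            *self.p_projection,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.p_projection) - 1.0) > 1e-9:
            raise ValueError("p_projection must sum to 1")
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        if not self.boxes_per_fracture or min(self.boxes_per_fracture) < 1:
            raise ValueError("boxes_per_fracture needs counts >= 1")
        if abs(sum(self.boxes_per_fracture.values()) - 1.0) > 1e-9:
            raise ValueError("boxes_per_fracture probabilities must sum to 1")
        if not (self.age_min < self.age_max):
            raise ValueError("age_min must be below age_max")


@dataclass
class VariantProfile:
    """Error model for one simulated network variant.

    ``cls_score_params`` gives per-stratum Beta shape pairs for classification
    scores.  For detection, ``det_sensitivity`` is the per-stratum probability
    that a ground-truth box is found at all, ``det_iou_quality`` the
    (mean, spread) of the realized overlap of found boxes with the truth, and
    ``det_confidence_params`` the per-stratum Beta shapes for true-detection
    confidences.  False detections arrive per image with a Poisson(``fp_rate``)
    count and ``fp_confidence_params`` Beta confidences.
    """

    name: str
    cls_score_params: Mapping[str, tuple[float, float]]
    det_sensitivity: Mapping[str, float] = field(default_factory=dict)
    det_iou_quality: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    det_confidence_params: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    fp_rate: float = 0.0
    fp_confidence_params: tuple[float, float] = (2.0, 6.0)

    def validate(self) -> None:
        for stratum, (a, b) in self.cls_score_params.items():
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r}")
            if a <= 0 or b <= 0:
                raise ValueError("Beta shapes must be positive")
        for stratum, p in self.det_sensitivity.items():
            if stratum not in _FRACTURE_STRATA:
                raise ValueError(f"det_sensitivity stratum {stratum!r} invalid")
            if not (0.0 <= p <= 1.0):
                raise ValueError("det_sensitivity outside [0, 1]")
        for stratum, (m, s) in self.det_iou_quality.items():
            if not (0.0 < m <= 1.0) or s < 0:
                raise ValueError("det_iou_quality mean must be in (0, 1], spread >= 0")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        a, b = self.fp_confidence_params
        if a <= 0 or b <= 0:
            raise ValueError("Beta shapes must be positive")


# ---------------------------------------------------------------------------


def _random_box(rng: np.random.Generator, width: int, height: int) -> BoundingBox:
    # box side between 5% and 30% of each image dimension, fully inside the image
    w = rng.uniform(0.05, 0.30) * width
    h = rng.uniform(0.05, 0.30) * height
    x0 = rng.uniform(0.0, width - w)
    y0 = rng.uniform(0.0, height - h)
    return BoundingBox(x0, y0, x0 + w, y0 + h)


def generate_cohort(config: CohortConfig) -> list[ImageRecord]:
    """Draw a full synthetic cohort; reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_images

    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    genders = rng.random(n) < config.p_female
    lateralities = rng.random(n) < config.p_left
    projections = rng.choice(3, size=n, p=np.asarray(config.p_projection))
    study_types = rng.random(n) < config.p_initial
    fractures = rng.random(n) < config.p_fracture
    difficult = rng.random(n) < config.p_difficult_given_fracture
    uncertain = rng.random(n) < config.p_uncertain
    counts = np.array(sorted(config.boxes_per_fracture), dtype=int)
    count_p = np.array([config.boxes_per_fracture[c] for c in counts])
    n_boxes = rng.choice(counts, size=n, p=count_p)

    proj_names = ("ap", "lateral", "oblique")
    width = int(np.ceil(np.log10(max(n, 10))))
    records: list[ImageRecord] = []
    for i in range(n):
        frac = bool(fractures[i])
        boxes = (
            [_random_box(rng, config.image_width, config.image_height) for _ in range(n_boxes[i])]
            if frac
            else []
        )
        records.append(
            ImageRecord(
                image_id=f"img_{i:0{width}d}",
                patient_age=round(float(ages[i]), 2),
                gender="female" if genders[i] else "male",
                laterality="left" if lateralities[i] else "right",
                projection=proj_names[projections[i]],
                study_type="initial" if study_types[i] else "followup",
                fracture=frac,
                difficulty=("difficult" if difficult[i] else "easy") if frac else "not_applicable",
                diagnosis_uncertain=bool(uncertain[i]),
                image_width=config.image_width,
                image_height=config.image_height,
                boxes=boxes,
            )
        )
    return records


def simulate_classifier(
    records: Sequence[ImageRecord], profile: VariantProfile, seed: int
) -> list[ClassScore]:
    """One fracture-presence score per image, Beta-distributed per difficulty stratum."""
    profile.validate()
    ids = [r.image_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("records contain duplicate image ids")
    rng = np.random.default_rng(seed)
    scores: list[ClassScore] = []
    for r in records:
        try:
            a, b = profile.cls_score_params[r.stratum]
        except KeyError:
            raise ValueError(f"profile {profile.name!r} has no score params for {r.stratum!r}")
        scores.append(ClassScore(image_id=r.image_id, score=float(rng.beta(a, b))))
    return scores


def _jitter_to_iou(
    box: BoundingBox, target_iou: float, axis: int, rng: np.random.Generator
) -> BoundingBox:
    """Shift ``box`` along one axis so its IoU with the original equals ``target_iou``.

    For a pure translation by d along an axis of extent e, the overlap is
    (e - d) / (e + d), which inverts to d = e (1 - t) / (1 + t) for target t.
    The shift goes in the positive direction so coordinates stay >= 0.
    """
    t = float(np.clip(target_iou, 1e-6, 1.0))
    if axis == 0:
        d = box.width * (1.0 - t) / (1.0 + t)
        return BoundingBox(box.x_min + d, box.y_min, box.x_max + d, box.y_max)
    d = box.height * (1.0 - t) / (1.0 + t)
    return BoundingBox(box.x_min, box.y_min + d, box.x_max, box.y_max + d)


def simulate_detector(
    records: Sequence[ImageRecord], profile: VariantProfile, seed: int
) -> list[Detection]:
    """Per-image detections with difficulty-dependent sensitivity and localization.

    Each ground-truth box is found with probability ``det_sensitivity`` of its
    stratum; a found box is shifted so that its realized IoU with the truth is
    drawn around ``det_iou_quality`` (clipped to [0.05, 1]).  False positives
    are unanchored random boxes with a Poisson(``fp_rate``) count per image.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    dets: list[Detection] = []
    for r in records:
        stratum = r.stratum
        if r.boxes:
            sens = profile.det_sensitivity.get(stratum, 0.0)
            mean_iou, spread = profile.det_iou_quality.get(stratum, (0.9, 0.0))
            conf_a, conf_b = profile.det_confidence_params.get(stratum, (8.0, 2.0))
            for truth in r.boxes:
                if rng.random() >= sens:
                    continue
                target = float(np.clip(rng.normal(mean_iou, spread), 0.05, 1.0))
                jittered = _jitter_to_iou(truth, target, axis=int(rng.integers(2)), rng=rng)
                dets.append(
                    Detection(
                        image_id=r.image_id,
                        box=jittered,
                        confidence=float(rng.beta(conf_a, conf_b)),
                    )
                )
        n_fp = rng.poisson(profile.fp_rate)
        for _ in range(n_fp):
            fa, fb = profile.fp_confidence_params
            dets.append(
                Detection(
                    image_id=r.image_id,
                    box=_random_box(rng, r.image_width, r.image_height),
                    confidence=float(rng.beta(fa, fb)),
                )
            )
    return dets


# ---------------------------------------------------------------------------
# presets


def table2_defaults(n_images: int = 20000, seed: int = 0) -> CohortConfig:
    """Cohort config matching the natural frequencies of the emulated dataset.

    Marginals follow the whole-dataset ("random" sample) characteristics:
    age 10.9 +/- 3.58 years on [0.4, 18.7], 42% female, 56% left wrists,
    48/51/0.6% ap/lateral/oblique projections, 22% initial studies, 68%
    fracture prevalence and 273/3132 difficult gradings among fractures
    (about 6% of all images).
    """
    return CohortConfig(n_images=n_images, seed=seed)


def classifier_ladder(n_variants: int = 8) -> list[VariantProfile]:
    """Difficulty-penalized classifier family with monotonically improving rungs.

    Mirrors a capacity ladder of 8 classifier variants: each rung scores easy
    fractures higher and non-fractures lower than the previous one, while
    difficult fractures stay markedly harder at every rung.
    """
    profiles = []
    for i in range(n_variants):
        profiles.append(
            VariantProfile(
                name=f"clf-b{i}",
                cls_score_params={
                    "easy_fracture": beta_shapes(0.80 + 0.015 * i, 10.0),
                    "difficult_fracture": beta_shapes(0.52 + 0.010 * i, 6.0),
                    "no_fracture": beta_shapes(0.18 - 0.008 * i, 10.0),
                },
            )
        )
    return profiles


def detector_ladder(n_variants: int = 5) -> list[VariantProfile]:
    """Difficulty-penalized detector family of 5 sizes (n/s/m/l/x style)."""
    sizes = ("n", "s", "m", "l", "x")
    profiles = []
    for j in range(n_variants):
        profiles.append(
            VariantProfile(
                name=f"det-{sizes[j % len(sizes)]}{'' if j < len(sizes) else j}",
                cls_score_params={
                    "easy_fracture": beta_shapes(0.80 + 0.01 * j, 8.0),
                    "difficult_fracture": beta_shapes(0.55 + 0.01 * j, 6.0),
                    "no_fracture": beta_shapes(0.15, 8.0),
                },
                det_sensitivity={
                    "easy_fracture": 0.85 + 0.015 * j,
                    "difficult_fracture": 0.58 + 0.020 * j,
                },
                det_iou_quality={
                    "easy_fracture": (0.85, 0.07),
                    "difficult_fracture": (0.68, 0.10),
                },
                det_confidence_params={
                    "easy_fracture": beta_shapes(0.80, 12.0),
                    "difficult_fracture": beta_shapes(0.62, 10.0),
                },
                fp_rate=0.12 - 0.012 * j,
                fp_confidence_params=beta_shapes(0.30, 8.0),
            )
        )
    return profiles
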