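"""ADTA scoring: patch positivity, per-image ratios, per-patient medians,
risk classification and stage derivation.

The score of an image is the fraction of in-tumor patches whose lymphocyte
probability reaches the positivity threshold (default 0.775); a patient's
score is the median over that patient's images, and the patient is low-risk
(high lymphocytic infiltrate) when the score reaches the risk cutoff
(default 0.065, the value selected on the original training cohort).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io import ClinicalRecord, ImagePatchSet
from .masking import TumorMask, patch_in_tumor

__all__ = [
    "ScoringConfig",
    "ImageScore",
    "PatientScore",
    "NoTumorPatchesError",
    "score_image",
    "score_image_with_membership",
    "score_patient",
    "derive_stage",
    "t_stage_from_depth",
]

HIGH_RISK = "high_risk"
LOW_RISK = "low_risk"


class NoTumorPatchesError(ValueError):
    """An image has no patches inside the tumor region; it must be excluded
    upstream (with a logged reason) rather than scored."""


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds governing positivity and risk classification.

    positivity_threshold : probability at/above which a patch counts as
        TIL-positive (0.775 — the upstream detector's empirically determined
        operating point).
    risk_cutoff : patient-level score at/above which the patient is
        low-risk (0.065 — ROC-derived on the training cohort).
    boundary_rule : whether a probability exactly at the threshold is
        positive ("at_least", default) or negative ("strictly_above").
        Measure-zero for continuous detector outputs, but both readings
        appear in the source material, so the rule is explicit.
    """

    positivity_threshold: float = 0.775
    risk_cutoff: float = 0.065
    boundary_rule: Literal["at_least", "strictly_above"] = "at_least"

    def __post_init__(self) -> None:
        if not (0 < self.positivity_threshold < 1):
            raise ValueError("positivity_threshold must be in (0, 1)")
        if not (0 <= self.risk_cutoff <= 1):
            raise ValueError("risk_cutoff must be in [0, 1]")
        if self.boundary_rule not in ("at_least", "strictly_above"):
            raise ValueError(f"unknown boundary_rule {self.boundary_rule!r}")

    def is_positive(self, probs: np.ndarray) -> np.ndarray:
        probs = np.asarray(probs, dtype=float)
        if self.boundary_rule == "at_least":
            return probs >= self.positivity_threshold
        return probs > self.positivity_threshold


@dataclass(frozen=True)
class ImageScore:
    image_id: str
    n_total: int  # in-tumor patches
    n_pos: int    # in-tumor TIL-positive patches

    @property
    def value(self) -> float:
        return self.n_pos / self.n_total


@dataclass(frozen=True)
class PatientScore:
    patient_id: str
    image_scores: tuple[ImageScore, ...]
    adta: float
    risk_class: str


def score_image(
    patches: ImagePatchSet,
    mask: TumorMask,
    config: ScoringConfig = ScoringConfig(),
) -> ImageScore:
    """Score one image against a raster tumor mask.

    n_total counts patches whose centre pixel is tumor; n_pos counts those
    among them whose probability is positive under the config's boundary
    rule.  Raises :class:`NoTumorPatchesError` when no patch is in-tumor.
    """
    in_tumor = np.array(
        [patch_in_tumor(mask, p, patches.patch_size) for p in patches.patches],
        dtype=bool,
    )
    return _score_from_membership(patches, in_tumor, config)


def score_image_with_membership(
    patches: ImagePatchSet,
    in_tumor: np.ndarray,
    config: ScoringConfig = ScoringConfig(),
) -> ImageScore:
    """Score one image from a precomputed membership vector (fast path).

    ``in_tumor`` must be the boolean membership of ``patches.patches`` in
    order, e.g. from :func:`adta.masking.patch_membership`.
    """
    return _score_from_membership(patches, np.asarray(in_tumor, bool), config)


def _score_from_membership(
    patches: ImagePatchSet, in_tumor: np.ndarray, config: ScoringConfig
) -> ImageScore:
    n_total = int(in_tumor.sum())
    if n_total == 0:
        raise NoTumorPatchesError(
            f"image {patches.image_id!r}: no tumor patches"
        )
    probs = patches.probs()[in_tumor]
    n_pos = int(config.is_positive(probs).sum())
    return ImageScore(image_id=patches.image_id, n_total=n_total, n_pos=n_pos)


def score_patient(
    patient_id: str,
    images: Sequence[ImageScore],
    config: ScoringConfig = ScoringConfig(),
) -> PatientScore:
    """Aggregate image scores to a patient: median score, then risk class.

    Median uses the standard convention (even count -> mean of the two
    middle values).  Risk: score >= cutoff -> low_risk (high infiltrate),
    else high_risk.
    """
    if not images:
        raise ValueError(f"patient {patient_id!r} has no scored images")
    adta = float(statistics.median([s.value for s in images]))
    risk = LOW_RISK if adta >= config.risk_cutoff else HIGH_RISK
    return PatientScore(
        patient_id=patient_id,
        image_scores=tuple(images),
        adta=adta,
        risk_class=risk,
    )


def t_stage_from_depth(depth_mm: float, ulceration: int | None) -> int:
    """AJCC T category (ordinal 1..8 = T1a..T4b) from Breslow depth and
    ulceration.  Unknown ulceration is treated as absent (the 'a'
    subcategory), the conservative complete-case reading."""
    if depth_mm <= 1.0:
        base = 1
    elif depth_mm <= 2.0:
        base = 2
    elif depth_mm <= 4.0:
        base = 3
    else:
        base = 4
    ulc = 1 if ulceration == 1 else 0
    return (base - 1) * 2 + 1 + ulc


def derive_stage(record: ClinicalRecord) -> int | None:
    """Derive pathologic stage I/II/III (returned as 1/2/3).

    A known positive lymph node or documented satellite metastasis is
    stage III regardless of the primary tumor; otherwise the I-vs-II split
    follows the T category (T1a-T2a -> I, T2b-T4b -> II), with the T
    category itself derived from depth and ulceration when not recorded.
    Returns None when nothing usable is present.
    """
    if record.node_or_satellite_positive == 1:
        return 3
    t = record.t_stage
    if t is None and record.depth_mm is not None:
        t = t_stage_from_depth(record.depth_mm, record.ulceration)
    if t is None:
        return None
    return 1 if t <= 3 else 2
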