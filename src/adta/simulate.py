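"""Synthetic melanoma cohorts for end-to-end pipeline testing.

No patient data ships with this package, so every pipeline stage is
exercised on simulated cohorts built to resemble the published marginals of
early-stage melanoma populations: a minority (~19%) of patients with
substantial lymphocytic infiltrate, Breslow depth log-normal around a
median of ~2.5 mm, ulceration in ~44%, ordinal TIL grades correlated with
the latent infiltrate, and proportional-hazards disease-specific survival
with ~40-55% events under uniform administrative censoring.

The simulation operates at the pipeline's declared input boundary — the
upstream detector's per-patch probability table — rather than rendering
fake H&E pixels.  Per image:

1. a star-shaped tumor loop is drawn covering ~30-90% of the patch grid;
2. a per-patient latent infiltration level ``lambda`` fixes the fraction of
   in-tumor patches that are "hot": the top ``round(lambda * n_in)``
   patches of a smooth Gaussian-bump random field, so hot patches come in
   spatial clusters (bump count is Poisson and scales with lambda) while
   the hot *fraction* is exact;
3. hot patches draw probabilities from a high Beta component (most mass
   above the 0.775 positivity threshold), the rest from a low background
   component (almost no mass above it).

The expected in-tumor positive fraction therefore has the closed form
``f * sf_hot + (1 - f) * sf_bg`` with ``f = round(lambda * n_in) / n_in``
and ``sf`` the Beta survival function at the positivity threshold — the
calibration oracle used by the tests.

Survival times are exponential with hazard
``h0 * exp(b_risk * z + b_depth * depth + b_ulc * ulc)`` where ``z``
indicates the *true* high-risk class (expected score below the cutoff),
censored by an independent uniform administrative time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    ClinicalRecord,
    ImagePatchSet,
    PatchRecord,
    PatientImageIndex,
    TumorAnnotation,
    write_annotation,
    write_clinical_table,
    write_patch_table,
)
from .masking import patch_membership
from .scoring import HIGH_RISK, LOW_RISK, t_stage_from_depth

__all__ = [
    "SimConfig",
    "SyntheticPatient",
    "SyntheticCohort",
    "gen_image",
    "gen_cohort",
    "expected_positive_fraction",
    "expected_event_fraction",
    "write_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.  Defaults are the stated world of the simulation
    and are not tuned per run; see docs/methods.md for their rationale.

    Image geometry
    --------------
    grid_dims : patches per image (cols, rows); 20 x 20 by default.
    patch_size : patch edge in pixels (100, the upstream detector's tiling).
    images_per_patient : inclusive range, uniform; tumors are often
        represented by several whole-slide images.

    Infiltration
    ------------
    high_fraction : mixture weight of the high-infiltrate (good prognosis)
        component; 0.19.
    lambda_low / lambda_high : uniform supports of the latent in-tumor hot
        fraction for the two components; (0.0, 0.06) and (0.10, 0.45) put
        expected scores on either side of the 0.065 cutoff and span ~0-0.4.
    cluster_count : mean Gaussian-bump count per unit lambda (Poisson).
    cluster_radius : bump width in patch units.
    prob_mean_bg / prob_mean_hot : Beta-component means (0.15 / 0.90).
    prob_noise : Beta concentration (a + b) of both components.

    Clinical covariates
    -------------------
    depth_median_mm / depth_sigma : log-normal Breslow depth (median 2.5 mm,
        log-SD 0.8, spanning the 2.0-2.75 medians of typical cohorts).
    ulceration_rate : 0.44.
    node_positive_rate : known positive node / satellite metastasis (0.25,
        matching stage III fractions of ~16-33%).
    grade_noise : probability a pathologist's ordinal TIL grade moves one
        step off the latent-derived grade.
    institutions / institution_weights : labels for per-institution
        stratification.

    Survival
    --------
    baseline_hazard : events/month for a zero-covariate patient (0.0012,
        putting the cohort event fraction near 50% under the default
        censoring horizon).
    beta_risk : true log-HR of the high-risk indicator (log 4).
    beta_depth : per-mm log-HR (log 1.2).
    beta_ulc : ulceration log-HR (log 1.6).
    censor_window_months : uniform administrative censoring horizon (180).
    risk_cutoff : score cutoff defining the true risk class (0.065).
    positivity_threshold : detector operating point (0.775).
    """

    seed: int = 0
    n_patients: int = 145
    images_per_patient: tuple[int, int] = (1, 4)
    grid_dims: tuple[int, int] = (20, 20)
    patch_size: int = 100
    high_fraction: float = 0.19
    lambda_low: tuple[float, float] = (0.0, 0.06)
    lambda_high: tuple[float, float] = (0.10, 0.45)
    cluster_count: float = 12.0
    cluster_radius: float = 2.5
    prob_mean_bg: float = 0.15
    prob_mean_hot: float = 0.90
    prob_noise: float = 8.0
    depth_median_mm: float = 2.5
    depth_sigma: float = 0.8
    ulceration_rate: float = 0.44
    node_positive_rate: float = 0.25
    grade_noise: float = 0.25
    institutions: tuple[str, ...] = ("YSM", "GHS")
    institution_weights: tuple[float, ...] = (0.69, 0.31)
    baseline_hazard: float = 0.0012
    beta_risk: float = float(np.log(4.0))
    beta_depth: float = float(np.log(1.2))
    beta_ulc: float = float(np.log(1.6))
    censor_window_months: float = 180.0
    risk_cutoff: float = 0.065
    positivity_threshold: float = 0.775

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.patch_size < 1:
            raise ValueError("n_patients and patch_size must be positive")
        if not (0 < self.high_fraction < 1):
            raise ValueError("high_fraction must be in (0, 1)")
        for nm in ("baseline_hazard", "censor_window_months", "prob_noise",
                   "cluster_radius", "depth_median_mm"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")

    # Beta component parameters (mean/concentration parametrization)
    def beta_params(self, hot: bool) -> tuple[float, float]:
        mu = self.prob_mean_hot if hot else self.prob_mean_bg
        return mu * self.prob_noise, (1 - mu) * self.prob_noise


@dataclass
class SyntheticPatient:
    patient_id: str
    lam: float
    true_expected_adta: float
    true_risk_class: str
    images: list[tuple[ImagePatchSet, TumorAnnotation]]
    memberships: list[np.ndarray]  # in-tumor flags per image (ground truth)
    clinical: ClinicalRecord


@dataclass
class SyntheticCohort:
    config: SimConfig
    patients: list[SyntheticPatient]

    def image_index(self) -> PatientImageIndex:
        return PatientImageIndex(
            {p.patient_id: [ips.image_id for ips, _ in p.images]
             for p in self.patients}
        )

    def clinical_records(self) -> list[ClinicalRecord]:
        return [p.clinical for p in self.patients]

    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "lambda": [p.lam for p in self.patients],
                "true_expected_adta": [p.true_expected_adta for p in self.patients],
                "true_risk_class": [p.true_risk_class for p in self.patients],
            }
        )


def expected_positive_fraction(
    config: SimConfig, lam: float, n_in: int | None = None
) -> float:
    """Closed-form expected in-tumor positive fraction at latent level lam.

    With n_in given, uses the exact realized hot fraction
    round(lam * n_in) / n_in; otherwise the ideal fraction lam.
    """
    a_bg, b_bg = config.beta_params(hot=False)
    a_hot, b_hot = config.beta_params(hot=True)
    tau = config.positivity_threshold
    sf_bg = float(stats.beta.sf(tau, a_bg, b_bg))
    sf_hot = float(stats.beta.sf(tau, a_hot, b_hot))
    f = lam if n_in is None else round(lam * n_in) / n_in
    return f * sf_hot + (1 - f) * sf_bg


def expected_event_fraction(rate: float, window: float) -> float:
    """P(exponential(rate) event observed before uniform(0, window)
    censoring): 1 - (1 - exp(-rate*window)) / (rate*window)."""
    rw = rate * window
    return 1.0 - (1.0 - np.exp(-rw)) / rw


def _star_polygon(
    rng: np.random.Generator, width: float, height: float, n_vertices: int = 16
) -> list[tuple[float, float]]:
    """Random star-shaped polygon around the image centre.  Jittered regular
    angular spacing keeps every gap below pi, so the ring is always simple."""
    cx, cy = width / 2.0, height / 2.0
    angles = (np.arange(n_vertices)
              + rng.uniform(0.05, 0.95, n_vertices)) * 2 * np.pi / n_vertices
    radii = rng.uniform(0.60, 0.95, n_vertices) * min(width, height) / 2.0
    return [
        (float(cx + r * np.cos(a)), float(cy + r * np.sin(a)))
        for a, r in zip(angles, radii)
    ]


def gen_image(
    config: SimConfig,
    lam: float,
    rng: np.random.Generator,
    image_id: str = "img",
) -> tuple[ImagePatchSet, TumorAnnotation, np.ndarray]:
    """Generate one image: patch probability map, tumor loop, and the
    ground-truth in-tumor membership vector.

    Retries (with a log entry) when the random loop covers <30% or >90% of
    the patch grid or no patch centre falls inside it.
    """
    gw, gh = config.grid_dims
    ps = config.patch_size
    width, height = gw * ps, gh * ps
    xs, ys = np.meshgrid(np.arange(gw) * ps, np.arange(gh) * ps)
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(int)
    n_patches = len(coords)

    for attempt in range(50):
        ring = _star_polygon(rng, width, height)
        annotation = TumorAnnotation(
            image_id=image_id, polygons=[(ring + [ring[0]], [])]
        )
        in_tumor = patch_membership(annotation, coords, ps)
        frac = in_tumor.mean()
        if 0.30 <= frac <= 0.90 and in_tumor.any():
            break
        logger.debug("image %s: tumor loop covers %.2f of grid; retrying",
                     image_id, frac)
    else:
        raise RuntimeError("could not draw a tumor loop covering 30-90% of grid")

    n_in = int(in_tumor.sum())
    n_hot = round(lam * n_in)

    # smooth bump field over the patch lattice; top-n_hot in-tumor patches
    # become hot -> clustered hot regions with an exact hot fraction
    px = coords[:, 0] / ps
    py = coords[:, 1] / ps
    n_bumps = int(rng.poisson(config.cluster_count * lam)) + 1
    in_idx = np.flatnonzero(in_tumor)
    centers = coords[rng.choice(in_idx, size=n_bumps, replace=True)] / ps
    d2 = (px[:, None] - centers[None, :, 0]) ** 2 + (
        py[:, None] - centers[None, :, 1]
    ) ** 2
    fld = np.exp(-d2 / (2 * config.cluster_radius**2)).sum(axis=1)
    fld = fld + rng.normal(0.0, 1e-6, n_patches)  # tie-break

    hot = np.zeros(n_patches, dtype=bool)
    if n_hot > 0:
        order = np.argsort(-fld[in_idx], kind="stable")
        hot[in_idx[order[:n_hot]]] = True

    a_bg, b_bg = config.beta_params(hot=False)
    a_hot, b_hot = config.beta_params(hot=True)
    probs = rng.beta(a_bg, b_bg, size=n_patches)
    if hot.any():
        probs[hot] = rng.beta(a_hot, b_hot, size=int(hot.sum()))

    patch_set = ImagePatchSet(
        image_id=image_id,
        patch_size=ps,
        patches=[
            PatchRecord(int(x), int(y), float(p))
            for (x, y), p in zip(coords, probs)
        ],
    )
    return patch_set, annotation, in_tumor


def gen_cohort(config: SimConfig, max_regen: int = 20) -> SyntheticCohort:
    """Generate a full cohort (deterministic given the config, seed
    included).  A cohort with zero observed events is regenerated with a
    warning, since it would break every survival-fitting precondition."""
    for regen in range(max_regen):
        rng = np.random.default_rng((config.seed, regen))
        cohort = _gen_cohort_once(config, rng)
        n_events = sum(p.clinical.dss_event for p in cohort.patients)
        if n_events > 0:
            return cohort
        logger.warning("cohort draw %d had zero events; regenerating", regen)
    raise RuntimeError(f"no events after {max_regen} cohort draws")


def _gen_cohort_once(config: SimConfig, rng: np.random.Generator) -> SyntheticCohort:
    patients: list[SyntheticPatient] = []
    pid_width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{pid_width}d}"
        high = rng.random() < config.high_fraction
        lo, hi = config.lambda_high if high else config.lambda_low
        lam = float(rng.uniform(lo, hi))

        n_images = int(rng.integers(config.images_per_patient[0],
                                    config.images_per_patient[1] + 1))
        images = []
        memberships = []
        for k in range(n_images):
            iid = f"{pid}_img{k + 1}"
            ips, ann, in_tumor = gen_image(config, lam, rng, image_id=iid)
            images.append((ips, ann))
            memberships.append(in_tumor)

        expected_adta = expected_positive_fraction(config, lam)
        true_risk = HIGH_RISK if expected_adta < config.risk_cutoff else LOW_RISK

        depth = float(np.exp(rng.normal(np.log(config.depth_median_mm),
                                        config.depth_sigma)))
        depth = max(depth, 0.1)
        ulc = int(rng.random() < config.ulceration_rate)
        node_pos = int(rng.random() < config.node_positive_rate)
        t_stage = t_stage_from_depth(depth, ulc)

        grade = _grade_from_lambda(config, lam, rng)

        inst = str(rng.choice(config.institutions,
                              p=np.asarray(config.institution_weights)
                              / np.sum(config.institution_weights)))

        z = 1 if true_risk == HIGH_RISK else 0
        rate = config.baseline_hazard * np.exp(
            config.beta_risk * z
            + config.beta_depth * depth
            + config.beta_ulc * ulc
        )
        t_event = rng.exponential(1.0 / rate)
        t_censor = rng.uniform(0.0, config.censor_window_months)
        followup = max(min(t_event, t_censor), 1e-3)
        event = int(t_event <= t_censor)

        clinical = ClinicalRecord(
            patient_id=pid,
            dss_event=event,
            followup_months=float(followup),
            depth_mm=depth,
            ulceration=ulc,
            t_stage=t_stage,
            til_grade=grade,
            node_or_satellite_positive=node_pos,
            institution=inst,
        )
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                lam=lam,
                true_expected_adta=expected_adta,
                true_risk_class=true_risk,
                images=images,
                memberships=memberships,
                clinical=clinical,
            )
        )
    return SyntheticCohort(config=config, patients=patients)


def _grade_from_lambda(
    config: SimConfig, lam: float, rng: np.random.Generator
) -> int:
    """Ordinal pathologist grade: latent-derived, then misgraded one step
    with probability grade_noise (absent < 0.02 <= non-brisk <= 0.25 < brisk)."""
    if lam < 0.02:
        grade = 0
    elif lam > 0.25:
        grade = 2
    else:
        grade = 1
    if rng.random() < config.grade_noise:
        grade += int(rng.choice([-1, 1]))
    return int(np.clip(grade, 0, 2))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort in the exact on-disk formats the readers consume:
    one patch CSV and one GeoJSON annotation per image, plus clinical,
    patient-image index, and ground-truth CSVs."""
    out = Path(out_dir)
    (out / "patches").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    index_rows = []
    for patient in cohort.patients:
        for ips, ann in patient.images:
            write_patch_table(ips, out / "patches" / f"{ips.image_id}.csv")
            write_annotation(ann, out / "annotations" / f"{ann.image_id}.geojson")
            index_rows.append({"patient_id": patient.patient_id,
                               "image_id": ips.image_id})
    pd.DataFrame(index_rows).to_csv(out / "patient_images.csv", index=False)
    write_clinical_table(cohort.clinical_records(), out / "clinical.csv")
    cohort.ground_truth().to_csv(out / "ground_truth.csv", index=False,
                                )
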