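"""Synthetic two-group imaging cohorts with linked survival outcomes.

Generates a full synthetic study emulating the structure of a multiplexed
tissue imaging cohort: two patient groups (``CLR`` and ``DII``), several
images per patient, a handful of cell types including a vasculature type,
ground-truth interaction parameters with a configured between-group
difference and patient-level heterogeneity, and exponential survival
times whose hazard depends on a designated interaction parameter (plus
age and sex).  Every downstream stage of the pipeline — fitting,
cohort aggregation, heterogeneity, survival screening — is testable
against the recorded ground truth without any external download.

Defaults are roughly an order of magnitude smaller than a real cohort
(6 patients per group x 4 images, 4 modeled cell types) so that the full
pipeline runs in minutes; scale up through :class:`CohortConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gibbs import ModelSpec, Parameters
from .patterns import MultitypePointPattern, Window, distance_map, write_pattern_csv
from .simulate import SamplerConfig, mh_sample

DEFAULT_TYPES = ("tumor", "CD4 T cell", "CD8 T cell", "macrophage", "vasculature")

#: reference age subtracted before entering the hazard, years
AGE_CENTER = 62.5


@dataclass
class CohortConfig:
    """Study design and ground-truth parameters of a synthetic cohort."""

    n_patients_per_group: int = 6
    images_per_patient: int = 4
    group_labels: tuple = ("CLR", "DII")
    type_set: tuple = DEFAULT_TYPES
    vasculature_type: str = "vasculature"
    window: Window = field(default_factory=lambda: Window(0.0, 500.0, 0.0, 500.0))
    saturation: int = 2
    #: per-type first-order intensity of modeled cells, points / micron^2
    modeled_intensity: float = 4e-4
    vasculature_intensity: float = 1.2e-4
    #: effect of distance-to-vasculature (per micron) on tumor cells
    distance_effect: float = -2e-3
    #: SD of the patient-level Gaussian noise added to alpha and gamma
    patient_noise_sd: float = 0.1
    designated_pair: tuple = ("tumor", "CD8 T cell")
    designated_scale: str = "short"
    #: designated short-range coefficient per group (the group difference
    #: the cohort stage should recover).  Moderate magnitudes: with
    #: exponential potentials every point of a rare type accumulates
    #: unsaturated potential gains from the whole partner population, so
    #: coefficients beyond ~+-1 drive types to extinction in a dense
    #: window rather than merely thinning them.
    #: CLR: mild immune exclusion of CD8 cells from tumor neighbourhoods;
    #: DII: mild infiltration
    designated_values: dict = field(
        default_factory=lambda: {"CLR": -0.2, "DII": 0.1})
    baseline_hazard: float = 0.02  # events per month at theta=0, age 62.5
    log_hr: float = 0.7  # b: log hazard ratio per unit of designated theta
    age_effect: float = 0.02
    sex_effect: float = 0.3
    censoring_horizon: float = 60.0  # months
    covariate_grid: tuple = (64, 64)
    sampler_burn_in: int = 5000
    sampler_steps: int = 2500

    def __post_init__(self):
        if self.images_per_patient < 1:
            raise ValueError("images_per_patient must be >= 1")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring horizon must be positive")
        if self.vasculature_type not in self.type_set:
            raise ValueError("type_set must include the vasculature type")
        for lab in self.group_labels:
            if lab not in self.designated_values:
                raise ValueError(f"designated_values missing group {lab!r}")

    @property
    def modeled_types(self) -> list:
        return [t for t in self.type_set if t != self.vasculature_type]

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            type_set=self.modeled_types,
            covariate_names=[f"dist_to_{self.vasculature_type}"],
            saturation=self.saturation,
        )

    def base_parameters(self, group: str) -> Parameters:
        """Group-level true Parameters for the modeled types."""
        types = self.modeled_types
        p = len(types)
        beta0 = np.full(p, np.log(self.modeled_intensity))
        beta = np.zeros((p, 1))
        beta[types.index("tumor") if "tumor" in types else 0, 0] = \
            self.distance_effect
        alpha = np.zeros((p, p))
        gamma = np.zeros((p, p))
        if "tumor" in types:
            k = types.index("tumor")
            alpha[k, k] = 0.3  # mild tumor self-clustering, both groups
        i = types.index(self.designated_pair[0])
        j = types.index(self.designated_pair[1])
        target = alpha if self.designated_scale == "short" else gamma
        target[i, j] = target[j, i] = self.designated_values[group]
        return Parameters(beta0=beta0, beta=beta, alpha=alpha, gamma=gamma)


@dataclass
class CohortImage:
    image_id: str
    patient_id: str
    group: str
    pattern: MultitypePointPattern  # all cells, vasculature included


@dataclass
class SyntheticCohort:
    config: CohortConfig
    model: ModelSpec
    images: list
    survival: pd.DataFrame  # patient_id, group, age, sex, time, event
    truth: pd.DataFrame  # patient_id, group, type1, type2, scale, value


def _perturbed(base: Parameters, sd: float, rng: np.random.Generator) -> Parameters:
    """Patient-level parameters: group base + symmetric Gaussian noise on
    the interaction coefficients."""
    p = len(base.beta0)
    out_alpha = base.alpha.copy()
    out_gamma = base.gamma.copy()
    if sd > 0:
        for m in (out_alpha, out_gamma):
            noise = np.zeros((p, p))
            iu = np.triu_indices(p)
            noise[iu] = rng.normal(0.0, sd, len(iu[0]))
            noise = noise + np.triu(noise, 1).T
            m += noise
    return Parameters(beta0=base.beta0.copy(), beta=base.beta.copy(),
                      alpha=out_alpha, gamma=out_gamma)


def _truth_rows(params: Parameters, model: ModelSpec, patient_id, group):
    rows = []
    for i, j in model.pairs():
        for scale, m in (("short", params.alpha), ("medium", params.gamma)):
            t1, t2 = sorted((model.type_set[i], model.type_set[j]))
            rows.append({"patient_id": patient_id, "group": group,
                         "type1": t1, "type2": t2, "scale": scale,
                         "value": float(m[i, j])})
    return rows


def _survival_record(theta, age, sex, config: CohortConfig,
                     rng: np.random.Generator):
    hazard = config.baseline_hazard * np.exp(
        config.log_hr * theta
        + config.age_effect * (age - AGE_CENTER)
        + config.sex_effect * sex
    )
    t = rng.exponential(1.0 / hazard)
    event = int(t <= config.censoring_horizon)
    return min(t, config.censoring_horizon), event


def generate_cohort(config: CohortConfig = None, seed: int = 0) -> SyntheticCohort:
    """Generate patterns, survival records and the ground-truth table.

    Per patient: parameters = group base + Gaussian noise; per image:
    vasculature scattered as a Poisson process, the distance-to-vasculature
    covariate built from it, and the modeled types drawn from the Gibbs
    model by MCMC.  Survival times are exponential with hazard
    ``lambda0 * exp(b*theta + b_age*(age - 62.5) + b_sex*sex)`` where
    ``theta`` is the patient's true designated interaction parameter,
    censored at the horizon.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    model = config.model_spec()
    window = config.window
    cov_name = model.covariate_names[0]

    images, truth_rows, surv_rows = [], [], []
    for group in config.group_labels:
        base = config.base_parameters(group)
        for ip in range(config.n_patients_per_group):
            patient_id = f"{group}_p{ip:02d}"
            params = _perturbed(base, config.patient_noise_sd, rng)
            truth_rows += _truth_rows(params, model, patient_id, group)
            i, j = (model.type_index(config.designated_pair[0]),
                    model.type_index(config.designated_pair[1]))
            theta = (params.alpha if config.designated_scale == "short"
                     else params.gamma)[i, j]
            age = rng.uniform(40.0, 85.0)
            sex = int(rng.integers(2))
            time, event = _survival_record(theta, age, sex, config, rng)
            surv_rows.append({"patient_id": patient_id, "group": group,
                              "age": age, "sex": sex, "time": time,
                              "event": event})
            for im in range(config.images_per_patient):
                image_id = f"{patient_id}_img{im}"
                n_vasc = max(int(rng.poisson(
                    config.vasculature_intensity * window.area)), 1)
                vasc = np.column_stack([
                    rng.uniform(window.x_min, window.x_max, n_vasc),
                    rng.uniform(window.y_min, window.y_max, n_vasc),
                ])
                vasc_pattern = MultitypePointPattern(
                    vasc, [config.vasculature_type] * n_vasc, window)
                covariates = {cov_name: distance_map(
                    vasc_pattern, config.vasculature_type,
                    grid=config.covariate_grid)}
                sampler = SamplerConfig(
                    n_steps=config.sampler_steps,
                    burn_in=config.sampler_burn_in,
                    seed=int(rng.integers(2**31)),
                )
                modeled = mh_sample(model, params, covariates, window, sampler)
                coords = np.vstack([modeled.coords, vasc])
                labels = (list(modeled.types)
                          + [config.vasculature_type] * n_vasc)
                pattern = MultitypePointPattern(
                    coords, labels, window, type_set=list(config.type_set))
                images.append(CohortImage(image_id, patient_id, group, pattern))

    return SyntheticCohort(
        config=config,
        model=model,
        images=images,
        survival=pd.DataFrame(surv_rows),
        truth=pd.DataFrame(truth_rows),
    )


def synthesize_estimate_table(config: CohortConfig = None,
                              n_patients_per_group: int = None,
                              images_per_patient: int = None,
                              estimate_noise_sd: float = 0.3,
                              seed: int = 0):
    """Metadata-level cohort: per-image interaction *estimates* without
    images.

    Per patient the true parameters are drawn exactly as in
    :func:`generate_cohort`; per image, each interaction estimate is the
    patient's truth plus Gaussian estimation noise.  This is the
    calibration harness for survival-stage simulation studies (null
    rejection rates, log-HR recovery) where running the imaging pipeline
    hundreds of times would be pointless — the estimates' distribution,
    not their provenance, is what the Cox stage sees.

    Returns ``(table, survival)`` in the same long format as
    :func:`mgpp.cohort.extract_parameters`.
    """
    config = config or CohortConfig()
    npg = n_patients_per_group or config.n_patients_per_group
    ipp = images_per_patient or config.images_per_patient
    rng = np.random.default_rng(seed)
    model = config.model_spec()

    rows, surv_rows = [], []
    for group in config.group_labels:
        base = config.base_parameters(group)
        for ip in range(npg):
            patient_id = f"{group}_p{ip:03d}"
            params = _perturbed(base, config.patient_noise_sd, rng)
            i, j = (model.type_index(config.designated_pair[0]),
                    model.type_index(config.designated_pair[1]))
            theta = (params.alpha if config.designated_scale == "short"
                     else params.gamma)[i, j]
            age = rng.uniform(40.0, 85.0)
            sex = int(rng.integers(2))
            time, event = _survival_record(theta, age, sex, config, rng)
            surv_rows.append({"patient_id": patient_id, "group": group,
                              "age": age, "sex": sex, "time": time,
                              "event": event})
            for im in range(ipp):
                image_id = f"{patient_id}_img{im}"
                for ti, tj in model.pairs():
                    for scale, kind, m in (("short", "alpha", params.alpha),
                                           ("medium", "gamma", params.gamma)):
                        t1, t2 = sorted((model.type_set[ti],
                                         model.type_set[tj]))
                        rows.append({
                            "image_id": image_id, "patient_id": patient_id,
                            "group": group, "kind": kind, "type1": t1,
                            "type2": t2, "covariate": None, "scale": scale,
                            "estimate": float(m[ti, tj])
                            + rng.normal(0.0, estimate_noise_sd),
                            "se": estimate_noise_sd,
                            "significant": False,
                        })
    return pd.DataFrame(rows), pd.DataFrame(surv_rows)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write per-image ``cells.csv`` files plus ``metadata.csv``,
    ``survival.csv`` and ``truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for img in cohort.images:
        write_pattern_csv(
            img.pattern, outdir / f"{img.image_id}_cells.csv",
            extra_columns={"image_id": img.image_id,
                           "patient_id": img.patient_id},
        )
        meta.append({"image_id": img.image_id, "patient_id": img.patient_id,
                     "group": img.group,
                     "file": f"{img.image_id}_cells.csv"})
    pd.DataFrame(meta).to_csv(outdir / "metadata.csv", index=False)
    cohort.survival.to_csv(outdir / "survival.csv", index=False)
    (outdir / "truth.json").write_text(
        json.dumps(cohort.truth.to_dict(orient="records")))
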