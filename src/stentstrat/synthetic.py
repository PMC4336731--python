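"""Synthetic cohort generator with planted subgroup-specific risk structure.

Emulates the statistical shape of a PCI registry cohort: ~2,700 interventions
collected across three protocol eras (each era records one clinical and one
biomarker feature set), about a third of interventions treated with
drug-eluting stents, roughly a third of patients lost to follow-up, and
binary endpoints whose prevalences match the published clinical ranges
(bare-metal-stent restenosis 20-30%, drug-eluting-stent restenosis 4-8%).

Outcomes are drawn from leaf-subgroup-specific logistic models over the
latent (unmasked) features, with intercepts auto-calibrated by bisection so
realized per-arm prevalences hit their targets. The planted truth — leaf
coefficients, per-record linear predictors, and counterfactual event
probabilities and labels under both treatments — is returned separately and
is never consumed by the fitting pipeline; it exists for oracle evaluation
and parameter-recovery tests only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .catalog import FeatureCatalog
from .cohort import ENDPOINTS, META_COLUMNS, SubgroupSpec, _coerce_frame

#: Default cohort scale: interventions, DES share and loss to follow-up.
DEFAULT_N = 2733
DEFAULT_DES_FRACTION = 0.342
DEFAULT_LOST_FOLLOWUP = 913 / 2733

_RESTENOSIS_ENDPOINTS = ("angio_restenosis_6m", "clin_restenosis_1y", "clin_restenosis_3y")
_HAZARD_ENDPOINTS = ("hazard_1y", "hazard_3y")

#: Default per-arm target prevalences. Restenosis under BMS/DES uses the
#: midpoints of the published clinical ranges; the remaining values are
#: calibration choices (hazard rates similar across arms, rising with the
#: horizon; 3-year clinical restenosis above 1-year).
DEFAULT_TARGET_PREVALENCES = {
    "angio_restenosis_6m": {"BMS": 0.25, "DES": 0.06},
    "clin_restenosis_1y": {"BMS": 0.18, "DES": 0.04},
    "clin_restenosis_3y": {"BMS": 0.23, "DES": 0.08},
    "hazard_1y": {"BMS": 0.045, "DES": 0.05},
    "hazard_3y": {"BMS": 0.095, "DES": 0.105},
}

#: Natural-unit location/scale for continuous features (values are
#: mean + sd * z with z standard normal, correlated within family).
_CONTINUOUS_PARAMS = {
    "ccs_grade": (2.0, 1.0),
    "bmi": (27.0, 4.0),
    "ejection_fraction": (55.0, 10.0),
    "lesion_length": (13.0, 6.0),
    "min_lumen_diameter": (0.9, 0.4),
    "n_stents": (1.4, 0.7),
    "nyha_class": (2.0, 0.9),
    "height": (170.0, 9.0),
    "weight": (80.0, 14.0),
    "reference_diameter": (3.0, 0.5),
    "timi_rating": (2.5, 0.7),
    "vessels_affected": (1.9, 0.8),
    "cholesterol": (200.0, 40.0),
    "creatine_kinase": (90.0, 50.0),
    "ck_mb": (12.0, 6.0),
    "creatinine": (1.0, 0.3),
    "crp": (4.0, 5.0),
    "hdl": (48.0, 13.0),
    "ldl": (125.0, 35.0),
    "nt_probnp": (300.0, 400.0),
    "triglycerides": (150.0, 80.0),
    "troponin_t": (0.05, 0.08),
    "hs_troponin_t": (15.0, 20.0),
}

_BINARY_PARAMS = {
    "angina": 0.7,
    "angulation": 0.15,
    "hypercholesterolemia": 0.6,
    "dissection": 0.1,
    "eccentric_lesion": 0.45,
    "family_history": 0.3,
    "history_bypass": 0.1,
    "history_intervention": 0.25,
    "history_mi": 0.3,
    "hypertension": 0.65,
    "smoker": 0.35,
    "plaques": 0.5,
    "st_elevation": 0.12,
    "thrombus": 0.08,
    "tortuosity": 0.12,
}

_CATEGORICAL_PARAMS = {
    "aha_lesion_class": (("A", "B1", "B2", "C"), (0.15, 0.35, 0.3, 0.2)),
    "lv_function": (("normal", "moderately_reduced", "severely_reduced"), (0.6, 0.3, 0.1)),
    "stenosis_type": (("de_novo", "restenotic", "in_stent"), (0.75, 0.15, 0.1)),
}

ERA_TAGS = ("era1", "era2", "era3")


@dataclass
class SubgroupTruth:
    """Planted logistic coefficients for one fully-specified leaf subgroup.

    Coefficients are keyed by feature name and act on the latent standardized
    value for continuous features and on the 0/1 value for binary features.
    """

    coef_r: dict[str, float] = field(default_factory=dict)
    coef_h: dict[str, float] = field(default_factory=dict)


@dataclass
class GeneratorConfig:
    n_interventions: int = DEFAULT_N
    des_fraction: float = DEFAULT_DES_FRACTION
    era_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)
    subgroup_truth: dict[SubgroupSpec, SubgroupTruth] = field(default_factory=dict)
    target_prevalences: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TARGET_PREVALENCES.items()})
    three_vessel_rate: float = 0.25
    lost_followup_rate: float = DEFAULT_LOST_FOLLOWUP
    female_rate: float = 0.25
    diabetes_rate: float = 0.28
    age_mean: float = 65.0
    age_sd: float = 10.0
    age_min: float = 18.0
    within_block_correlation: float = 0.2

    def validate(self, catalog: FeatureCatalog | None = None) -> None:
        catalog = catalog or FeatureCatalog.default()
        probs = [
            self.des_fraction,
            self.three_vessel_rate,
            self.lost_followup_rate,
            self.female_rate,
            self.diabetes_rate,
            self.within_block_correlation,
            *self.era_weights,
        ]
        for ep, arms in self.target_prevalences.items():
            probs.extend(arms.values())
            if ep not in ENDPOINTS:
                raise ValueError(f"unknown endpoint {ep!r} in target_prevalences")
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.era_weights) - 1) > 1e-9:
            raise ValueError("era weights must sum to 1")
        for sg, truth in self.subgroup_truth.items():
            if not sg.is_leaf_of_full_tree:
                raise ValueError("subgroup truth must be keyed by fully-specified subgroups")
            for coef in (truth.coef_r, truth.coef_h):
                for name in coef:
                    if name not in catalog:
                        raise ValueError(f"coefficient on unknown feature {name!r}")
                    if catalog.kind(name) == "categorical":
                        raise ValueError("planted coefficients act on continuous/binary features only")


@dataclass
class PlantedTruth:
    """Ground truth of a generated cohort; for oracle evaluation only."""

    subgroup_truth: dict[SubgroupSpec, SubgroupTruth]
    leaf_of_record: list[SubgroupSpec]
    lp_r: np.ndarray
    lp_h: np.ndarray
    offsets: dict  # endpoint -> arm -> calibrated intercept
    probabilities: dict  # endpoint -> arm -> per-record event probability
    labels_counterfactual: dict  # endpoint -> arm -> per-record bool labels

    def to_jsonable(self) -> dict:
        return {
            "subgroup_truth": {
                sg.label: {"coef_r": t.coef_r, "coef_h": t.coef_h}
                for sg, t in self.subgroup_truth.items()
            },
            "leaf_of_record": [sg.label for sg in self.leaf_of_record],
            "lp_r": self.lp_r.tolist(),
            "lp_h": self.lp_h.tolist(),
            "offsets": self.offsets,
            "probabilities": {
                ep: {arm: p.tolist() for arm, p in arms.items()}
                for ep, arms in self.probabilities.items()
            },
            "labels_counterfactual": {
                ep: {arm: l.astype(int).tolist() for arm, l in arms.items()}
                for ep, arms in self.labels_counterfactual.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_jsonable()))


def _leaf_subgroups() -> list[SubgroupSpec]:
    return [
        SubgroupSpec(a, s, d)
        for a in ("LE60", "GT60")
        for s in ("FEMALE", "MALE")
        for d in ("NO", "YES")
    ]


def default_heterogeneous_config(n_interventions: int = DEFAULT_N) -> GeneratorConfig:
    """A config in which the planted coefficients flip sign across diabetes
    strata and change magnitude across age (and mildly sex) strata, so a
    single population-wide model is misspecified while leaf models are
    well-specified. Active features are available in every era."""
    base_r = {
        "ejection_fraction": -0.8,
        "bmi": 0.7,
        "lesion_length": 0.9,
        "hypertension": 0.6,
        "crp": 0.8,
        "troponin_t": 0.7,
    }
    base_h = {
        "ejection_fraction": -0.9,
        "nyha_class": 0.7,
        "min_lumen_diameter": -0.6,
        "smoker": 0.6,
        "crp": 1.0,
        "troponin_t": 0.9,
    }
    truth = {}
    for sg in _leaf_subgroups():
        sign = 1.0 if sg.diabetes == "NO" else -1.0
        scale = 0.7 if sg.age == "LE60" else 1.3
        scale *= 1.1 if sg.sex == "MALE" else 1.0
        truth[sg] = SubgroupTruth(
            coef_r={k: sign * scale * v for k, v in base_r.items()},
            coef_h={k: sign * scale * v for k, v in base_h.items()},
        )
    return GeneratorConfig(n_interventions=n_interventions, subgroup_truth=truth)


def default_homogeneous_config(n_interventions: int = DEFAULT_N) -> GeneratorConfig:
    """Same coefficients in every leaf: no planted subgroup heterogeneity."""
    het = default_heterogeneous_config(n_interventions)
    ref = het.subgroup_truth[SubgroupSpec("LE60", "FEMALE", "NO")]
    truth = {sg: SubgroupTruth(dict(ref.coef_r), dict(ref.coef_h)) for sg in _leaf_subgroups()}
    return GeneratorConfig(n_interventions=n_interventions, subgroup_truth=truth)


def _sigmoid(z):
    return np.where(z >= 0, 1 / (1 + np.exp(-np.clip(z, -700, 700))), np.exp(np.clip(z, -700, 700)) / (1 + np.exp(np.clip(z, -700, 700))))


def _calibrate_offset(lp: np.ndarray, target: float, has_slopes: bool) -> float:
    """Intercept such that mean(sigmoid(lp + c)) == target, by bisection."""
    if not 0 < target < 1:
        if has_slopes:
            raise ValueError(f"cannot calibrate prevalence target {target} with nonzero slopes")
        return math.inf if target >= 1 else -math.inf

    def f(c):
        return float(np.mean(_sigmoid(lp + c))) - target

    return float(brentq(f, -40.0, 40.0, xtol=1e-10))


def generate_cohort(
    config: GeneratorConfig,
    seed: int,
    catalog: FeatureCatalog | None = None,
    as_records: bool = False,
):
    """Generate a cohort and its planted truth; fixed seed, identical output.

    Returns ``(frame, truth)`` where the frame is the canonical cohort table
    (or a list of PatientRecord if ``as_records``). Features outside a
    record's era are masked to missing; lost-to-follow-up records have all
    endpoint labels missing (the latent truth still records them).
    """
    catalog = catalog or FeatureCatalog.default()
    config.validate(catalog)
    rng = np.random.default_rng(seed)
    n = config.n_interventions

    # demographics and administrative fields
    a = (config.age_min - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    sex = np.where(rng.random(n) < config.female_rate, "female", "male")
    diabetes = np.where(rng.random(n) < config.diabetes_rate, "yes", "no")
    era = rng.choice(3, size=n, p=config.era_weights)
    treatment = np.where(rng.random(n) < config.des_fraction, "DES", "BMS")
    three_vessel = np.where(rng.random(n) < config.three_vessel_rate, "yes", "no")
    followed_up = rng.random(n) >= config.lost_followup_rate
    n_patients = max(1, int(round(n * 2377 / 2733)))
    patient_idx = np.concatenate([np.arange(n_patients), rng.integers(0, n_patients, size=n - n_patients)]) if n > n_patients else np.arange(n)

    # latent feature values
    rho = config.within_block_correlation
    z_values: dict[str, np.ndarray] = {}
    columns: dict[str, np.ndarray] = {}
    for family in ("clinical", "biomarkers"):
        shared = rng.standard_normal(n)
        for name in catalog.family_names(family):
            kind = catalog.kind(name)
            if kind == "continuous":
                z = math.sqrt(rho) * shared + math.sqrt(1 - rho) * rng.standard_normal(n)
                mean, sd = _CONTINUOUS_PARAMS[name]
                z_values[name] = z
                columns[name] = mean + sd * z
            elif kind == "binary":
                x = (rng.random(n) < _BINARY_PARAMS[name]).astype(float)
                z_values[name] = x
                columns[name] = x
            else:
                levels, probs = _CATEGORICAL_PARAMS[name]
                columns[name] = rng.choice(levels, size=n, p=probs)

    # planted linear predictors by leaf subgroup
    leaves = _leaf_subgroups()
    lp_r = np.zeros(n)
    lp_h = np.zeros(n)
    leaf_of_record: list[SubgroupSpec | None] = [None] * n
    le60 = age <= 60
    for sg in leaves:
        m = (le60 if sg.age == "LE60" else ~le60)
        m = m & (sex == ("female" if sg.sex == "FEMALE" else "male"))
        m = m & (diabetes == ("no" if sg.diabetes == "NO" else "yes"))
        idx = np.flatnonzero(m)
        for i in idx:
            leaf_of_record[i] = sg
        truth = config.subgroup_truth.get(sg, SubgroupTruth())
        for name, c in truth.coef_r.items():
            lp_r[idx] += c * z_values[name][idx]
        for name, c in truth.coef_h.items():
            lp_h[idx] += c * z_values[name][idx]

    # intercept calibration and endpoint labels
    has_slopes = any(
        bool(t.coef_r) or bool(t.coef_h) for t in config.subgroup_truth.values()
    )
    offsets: dict = {}
    probabilities: dict = {}
    labels_cf: dict = {}
    u_family = {
        "angio_restenosis_6m": rng.random(n),
        "clin_restenosis": rng.random(n),
        "hazard": rng.random(n),
    }
    for ep in ENDPOINTS:
        lp = lp_r if ep in _RESTENOSIS_ENDPOINTS else lp_h
        offsets[ep] = {}
        probabilities[ep] = {}
        labels_cf[ep] = {}
        for arm in ("BMS", "DES"):
            arm_mask = treatment == arm
            target = config.target_prevalences[ep][arm]
            c = _calibrate_offset(lp[arm_mask], target, has_slopes)
            offsets[ep][arm] = c
            p = _sigmoid(lp + c) if math.isfinite(c) else np.full(n, float(target))
            u = u_family["clin_restenosis" if ep.startswith("clin") else ("hazard" if ep.startswith("hazard") else ep)]
            probabilities[ep][arm] = p
            labels_cf[ep][arm] = u < p
    # monotone horizons: same uniform, probability increasing with horizon
    for pair in (("clin_restenosis_1y", "clin_restenosis_3y"), ("hazard_1y", "hazard_3y")):
        for arm in ("BMS", "DES"):
            if offsets[pair[1]][arm] < offsets[pair[0]][arm]:
                raise ValueError(
                    f"3-year target below 1-year target for {pair[0]}/{arm}; horizons must be monotone"
                )

    # assemble the cohort table
    data = {
        "record_id": [f"r{i:06d}" for i in range(n)],
        "patient_id": [f"p{j:06d}" for j in patient_idx],
        "age": age,
        "sex": sex,
        "diabetes": diabetes,
        "era_tag": [ERA_TAGS[e] for e in era],
        "treatment": treatment,
        "three_vessel": three_vessel,
        "followed_up": followed_up,
    }
    arm_pick = (treatment == "DES").astype(int)
    for ep in ENDPOINTS:
        lab = np.where(arm_pick == 1, labels_cf[ep]["DES"], labels_cf[ep]["BMS"])
        col = np.where(lab, "event", "no_event").astype(object)
        col[~followed_up] = None
        data[ep] = col
    frame = pd.DataFrame(data)
    # era-dependent availability: era k records feature sets C_k and B_k
    era_features = [
        set(catalog.set_members(f"C{k+1}")) | set(catalog.set_members(f"B{k+1}")) for k in range(3)
    ]
    for name in catalog.features:
        col = pd.Series(columns[name], dtype=object if catalog.kind(name) == "categorical" else float)
        avail = np.array([name in era_features[e] for e in era])
        col[~avail] = None if catalog.kind(name) == "categorical" else np.nan
        frame[name] = col
    frame = _coerce_frame(frame, catalog)

    truth_out = PlantedTruth(
        subgroup_truth=config.subgroup_truth,
        leaf_of_record=leaf_of_record,
        lp_r=lp_r,
        lp_h=lp_h,
        offsets=offsets,
        probabilities=probabilities,
        labels_counterfactual=labels_cf,
    )
    if as_records:
        from .cohort import frame_to_cohort

        return frame_to_cohort(frame, catalog), truth_out
    return frame, truth_out
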