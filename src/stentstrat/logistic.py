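"""Ridge-penalized logistic regression — the base learner at every leaf.

The fit maximizes ``log-likelihood - penalty * ||coefficients||^2`` with the
intercept unpenalized and the penalty applied as stated (no 1/n scaling), so
results are reproducible across sample sizes. Optimization is deterministic:
damped Newton iteration from a zero start with analytic derivatives, with the
gradient norm checked at the solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

from .catalog import FeatureCatalog
from .cohort import DesignSpec, EligibleSample, PatientRecord, SubgroupSpec, cohort_to_frame

#: Fixed ridge penalty used throughout (selecting it by nested cross-validation
#: would be prohibitively expensive at the scale of the full pipeline).
DEFAULT_PENALTY = 0.01

GRADIENT_TOL = 1e-6


class ConvergenceError(RuntimeError):
    def __init__(self, grad_norm: float):
        super().__init__(f"optimizer did not converge; gradient norm {grad_norm:.3e}")
        self.grad_norm = grad_norm


class MissingFeatureError(ValueError):
    pass


@dataclass
class ScoreSet:
    """Predicted probabilities paired with binary labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass
class LogisticModel:
    """A fitted leaf classifier, self-contained for scoring raw records."""

    coefficients: np.ndarray
    intercept: float
    design: DesignSpec
    feature_pair: tuple[str, str]
    subgroup: SubgroupSpec
    endpoint_kind: str  # "R" (restenosis under BMS) | "H" (hazard under DES)
    endpoint: str = ""

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coefficients

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Probabilities for rows of a cohort frame (must be complete cases)."""
        feats = frame[self.design.feature_names]
        if feats.isna().any().any():
            missing = feats.columns[feats.isna().any()].tolist()
            raise MissingFeatureError(f"missing required feature(s): {missing}")
        return _sigmoid(self.decision_function(self.design.transform(feats)))

    def scoreable_mask(self, frame: pd.DataFrame) -> np.ndarray:
        return frame[self.design.feature_names].notna().all(axis=1).to_numpy()

    def to_jsonable(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "design": self.design.to_jsonable(),
            "feature_pair": list(self.feature_pair),
            "subgroup": [self.subgroup.age, self.subgroup.sex, self.subgroup.diabetes],
            "endpoint_kind": self.endpoint_kind,
            "endpoint": self.endpoint,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "LogisticModel":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            design=DesignSpec.from_jsonable(d["design"]),
            feature_pair=tuple(d["feature_pair"]),
            subgroup=SubgroupSpec(*d["subgroup"]),
            endpoint_kind=d["endpoint_kind"],
            endpoint=d.get("endpoint", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_jsonable()))

    @classmethod
    def load(cls, path: str | Path) -> "LogisticModel":
        return cls.from_jsonable(json.loads(Path(path).read_text()))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def penalized_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray, penalty: float) -> float:
    """log L(beta0, beta) - penalty * ||beta||^2 (intercept unpenalized)."""
    z = params[0] + X @ params[1:]
    # log-likelihood = sum(y*z - log(1+e^z)), computed stably
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    return ll - penalty * float(params[1:] @ params[1:])


def _neg_obj_and_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray, penalty: float):
    z = params[0] + X @ params[1:]
    p = _sigmoid(z)
    nll = -float(np.sum(y * z - np.logaddexp(0.0, z)))
    resid = p - y
    grad = np.empty_like(params)
    grad[0] = resid.sum()
    grad[1:] = X.T @ resid + 2.0 * penalty * params[1:]
    return nll + penalty * float(params[1:] @ params[1:]), grad


def fit_l2_logistic(
    sample: EligibleSample,
    penalty: float = DEFAULT_PENALTY,
    catalog: FeatureCatalog | None = None,
    endpoint_kind: str = "R",
    max_iter: int = 500,
) -> LogisticModel:
    """Fit the leaf model on an eligible sample (features standardized first)."""
    catalog = catalog or FeatureCatalog.default()
    design = DesignSpec.fit(sample.features, catalog)
    X = design.transform(sample.features)
    y = sample.y.astype(float)
    if y.min() == y.max():
        raise ValueError("both classes must be present to fit a classifier")
    beta0, beta = _fit_matrix(X, y, penalty, max_iter)
    return LogisticModel(
        coefficients=beta,
        intercept=beta0,
        design=design,
        feature_pair=sample.feature_pair,
        subgroup=sample.subgroup,
        endpoint_kind=endpoint_kind,
        endpoint=sample.endpoint,
    )


def _fit_matrix(X: np.ndarray, y: np.ndarray, penalty: float, max_iter: int = 100) -> tuple[float, np.ndarray]:
    """Damped Newton iteration from a zero start.

    The ridge term keeps the Hessian positive definite, so the Newton step
    with objective-based step halving is globally convergent and fully
    deterministic. Falls back to L-BFGS-B if the linear solve fails.
    """
    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    ridge = np.zeros((p + 1, p + 1))
    ridge[1:, 1:] = 2.0 * penalty * np.eye(p)
    params = np.zeros(p + 1)
    obj, grad = _neg_obj_and_grad(params, X, y, penalty)
    for _ in range(max_iter):
        gnorm = float(np.max(np.abs(grad)))
        if gnorm <= GRADIENT_TOL * 1e-1:
            break
        z = Xa @ params
        w = _sigmoid(z)
        w = w * (1 - w) + 1e-12
        H = (Xa * w[:, None]).T @ Xa + ridge
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            res = minimize(
                _neg_obj_and_grad, params, args=(X, y, penalty), jac=True,
                method="L-BFGS-B", options={"maxiter": 1000, "gtol": 1e-9, "ftol": 1e-15},
            )
            params = res.x
            obj, grad = _neg_obj_and_grad(params, X, y, penalty)
            break
        # step halving until the objective decreases
        t = 1.0
        for _ in range(60):
            cand = params - t * step
            cand_obj, cand_grad = _neg_obj_and_grad(cand, X, y, penalty)
            if cand_obj <= obj + 1e-12:
                params, obj, grad = cand, cand_obj, cand_grad
                break
            t *= 0.5
        else:
            break
    gnorm = float(np.max(np.abs(grad)))
    if gnorm > GRADIENT_TOL:
        raise ConvergenceError(gnorm)
    return float(params[0]), params[1:]


def predict_prob(model: LogisticModel, record: PatientRecord, catalog: FeatureCatalog | None = None) -> float:
    """Predicted event probability for one record.

    Raises :class:`MissingFeatureError` naming the missing feature if the
    record lacks any feature the model requires.
    """
    catalog = catalog or FeatureCatalog.default()
    for name in model.design.feature_names:
        if record.feature_value(name) is None:
            raise MissingFeatureError(f"missing required feature(s): ['{name}']")
    frame = cohort_to_frame([record], catalog)
    return float(model.predict_frame(frame)[0])


def roc_auc(scores: ScoreSet | Sequence[float], labels: Sequence[int] | None = None) -> float:
    """Area under the ROC curve: P(random positive outscores random negative),
    ties counted half (midrank convention)."""
    if isinstance(scores, ScoreSet):
        s, l = scores.scores, scores.labels
    else:
        s, l = np.asarray(scores, dtype=float), np.asarray(labels, dtype=int)
    if len(np.unique(l)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(l, s))
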