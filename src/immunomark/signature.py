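"""Multi-component risk-score signature: construction and evaluation.

Starting from the intersected biomarkers, components are min-max scaled,
logistic coefficients are fit to predict treatment response, the per-sample
risk score is the coefficient-weighted sum of scaled component values, and
the score's dichotomization threshold is optimized for PFS stratification
exactly as for single markers.  Backward elimination repeatedly drops the
component whose removal most improves the thresholded score's ``|ln HR|``
and stops when no removal improves it.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .screening import (
    ThresholdResult,
    cox_fit,
    km_curve,
    logrank_p,
    map_response_series,
    optimize_threshold,
    roc_auc,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureModel",
    "EliminationStep",
    "LogisticFit",
    "minmax_scale",
    "apply_scaler",
    "fit_logistic",
    "risk_score",
    "backward_eliminate",
    "evaluate_signature",
]


@dataclass
class SignatureModel:
    """Frozen signature: components, scaling, coefficients, threshold.

    ``orientation`` records whether a score above the threshold marks the
    higher-hazard group; it is data-defined, not assumed, because the fitted
    coefficients set the score's direction.  The logistic intercept is stored
    for reference but excluded from the score, which is a ranking statistic.
    """

    components: list[str]
    scaler: dict[str, tuple[float, float]]  # component -> (min, max)
    coefficients: dict[str, float]
    risk_threshold: float | None
    orientation: str  # "higher_is_risk" | "lower_is_risk"
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not (set(self.components) == set(self.scaler) == set(self.coefficients)):
            raise ValueError("components, scaler and coefficients must align")
        for comp, (lo, hi) in self.scaler.items():
            if not lo < hi:
                raise ValueError(f"component {comp!r}: scaler needs min < max")
        if self.orientation not in ("higher_is_risk", "lower_is_risk"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in self.components])

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["scaler"] = {k: list(v) for k, v in payload["scaler"].items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["scaler"] = {k: tuple(v) for k, v in payload["scaler"].items()}
        return cls(**payload)


@dataclass
class EliminationStep:
    """One round of backward elimination: the best removal candidate found."""

    removed: str
    hr: float
    p: float
    accepted: bool


@dataclass
class LogisticFit:
    coef: np.ndarray
    intercept: float
    converged: bool


def minmax_scale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-wise (x - min) / (max - min) onto [0, 1].

    ``matrix`` is biomarkers x samples.  Returns the scaled matrix and a
    scaler table (columns ``min``, ``max``) for reuse on new cohorts.
    """
    mins = matrix.min(axis=1)
    maxs = matrix.max(axis=1)
    constant = mins >= maxs
    if constant.any():
        raise ValueError(
            f"constant biomarker row(s): {list(matrix.index[constant])}"
        )
    scaled = matrix.sub(mins, axis=0).div(maxs - mins, axis=0)
    scaler = pd.DataFrame({"min": mins, "max": maxs})
    return scaled, scaler


def apply_scaler(
    matrix: pd.DataFrame, scaler: pd.DataFrame, clip: bool = False
) -> pd.DataFrame:
    """Apply a stored min-max scaler to a (possibly new) cohort.

    Out-of-range values are passed through (scaled below 0 / above 1) with a
    warning; set ``clip=True`` to clamp them onto [0, 1].
    """
    missing = [i for i in matrix.index if i not in scaler.index]
    if missing:
        raise KeyError(f"no stored scaling for biomarker(s): {missing}")
    sc = scaler.loc[matrix.index]
    scaled = matrix.sub(sc["min"], axis=0).div(sc["max"] - sc["min"], axis=0)
    out_of_range = (scaled < 0) | (scaled > 1)
    if out_of_range.to_numpy().any():
        n = int(out_of_range.to_numpy().sum())
        if clip:
            scaled = scaled.clip(0.0, 1.0)
            logger.info("clipped %d out-of-range scaled value(s)", n)
        else:
            warnings.warn(
                f"{n} scaled value(s) fall outside [0, 1] (new cohort beyond "
                "training range); passed through unclipped",
                stacklevel=2,
            )
    return scaled


def fit_logistic(
    X, y, ridge: float = 1e-4, include_intercept: bool = True,
    max_iter: int = 200, tol: float = 1e-10,
) -> LogisticFit:
    """Ridge-penalized logistic regression by iteratively reweighted Newton.

    ``X`` is samples x features; ``y`` codes responders as 1.  The small ridge
    penalty (on slopes only, never on the intercept) guards against complete
    separation on small cohorts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    n, p = X.shape
    if include_intercept:
        design = np.column_stack([np.ones(n), X])
        penalty = np.diag([0.0] + [ridge] * p)
    else:
        design = X
        penalty = np.diag([ridge] * p)

    beta = np.zeros(design.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(design @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = design.T @ (y - mu) - penalty @ beta
        hess = design.T @ (design * w[:, None]) + penalty
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if include_intercept:
        return LogisticFit(coef=beta[1:], intercept=float(beta[0]), converged=converged)
    return LogisticFit(coef=beta, intercept=0.0, converged=converged)


def risk_score(scaled: pd.DataFrame, model: SignatureModel) -> pd.Series:
    """Per-sample score = sum over components of coefficient x scaled value.

    ``scaled`` is components x samples and must already be on the model's
    min-max scale.  The intercept is deliberately excluded.
    """
    missing = [c for c in model.components if c not in scaled.index]
    if missing:
        raise KeyError(f"missing signature component(s): {missing}")
    coef = model.coefficient_vector()
    values = scaled.loc[model.components].to_numpy(dtype=float)
    return pd.Series(coef @ values, index=scaled.columns, name="risk_score")


def _clinical_arrays(clinical: pd.DataFrame, samples) -> dict:
    clin = clinical.loc[[s for s in samples if s in clinical.index]]
    response = map_response_series(clin["recist"])
    return {
        "index": clin.index,
        "resp_mask": (response != "missing").to_numpy(),
        "resp_labels": (response == "responder").to_numpy(),
        "surv_mask": (clin["pfs_months"].notna() & clin["event"].notna()).to_numpy(),
        "pfs": clin["pfs_months"].to_numpy(dtype=float),
        "event": clin["event"].to_numpy(),
    }


def _fit_and_stratify(
    scaled: pd.DataFrame,
    component_ids: list[str],
    arrays: dict,
    min_frac: float,
    ridge: float,
) -> tuple[LogisticFit, pd.Series, ThresholdResult]:
    """Logistic fit on the response samples, scores for all samples,
    HR-optimized threshold on the survival samples."""
    sub = scaled.loc[component_ids]
    X = sub.to_numpy(dtype=float).T
    fit = fit_logistic(
        X[arrays["resp_mask"]], arrays["resp_labels"][arrays["resp_mask"]].astype(float),
        ridge=ridge,
    )
    scores = pd.Series(X @ fit.coef, index=sub.columns, name="risk_score")
    sv = arrays["surv_mask"]
    thr = optimize_threshold(
        scores.to_numpy()[sv], arrays["pfs"][sv], arrays["event"][sv].astype(int),
        min_frac=min_frac,
    )
    return fit, scores, thr


def backward_eliminate(
    candidates: pd.DataFrame,
    clinical: pd.DataFrame,
    min_frac: float = 0.3,
    ridge: float = 1e-4,
) -> tuple[SignatureModel, list[EliminationStep]]:
    """Build the signature by stepwise removal of components.

    Each round refits the logistic model without one candidate, re-optimizes
    the risk-score threshold under the 30% group-size constraint, and fits a
    Cox model on the two groups.  The removal giving the largest ``|ln HR|``
    is accepted when it strictly improves on the current signature; ties
    break on the lexicographically smallest removed id.  The loop stops when
    no removal improves the signature (or two components remain).
    """
    if len(candidates) < 2:
        raise ValueError("at least 2 candidate biomarkers are required")
    arrays = _clinical_arrays(clinical, candidates.columns)
    if not arrays["resp_mask"].any() or not arrays["surv_mask"].any():
        raise ValueError("clinical table must provide both response labels and PFS")
    scaled_all, scaler = minmax_scale(candidates[arrays["index"]])

    def metric(thr: ThresholdResult) -> float:
        return abs(math.log(thr.hr)) if thr.ok else -math.inf

    current = list(candidates.index)
    fit, scores, thr = _fit_and_stratify(scaled_all, current, arrays, min_frac, ridge)
    current_metric = metric(thr)
    trace: list[EliminationStep] = []

    while len(current) > 2:
        best_id: str | None = None
        best_metric = -math.inf
        best_eval = None
        for comp in sorted(current):
            remaining = [c for c in current if c != comp]
            cand_fit, cand_scores, cand_thr = _fit_and_stratify(
                scaled_all, remaining, arrays, min_frac, ridge
            )
            m = metric(cand_thr)
            if m > best_metric + 1e-12:
                best_metric = m
                best_id = comp
                best_eval = (cand_fit, cand_scores, cand_thr)
        if best_id is None:
            break
        accepted = best_metric > current_metric + 1e-12
        best_thr = best_eval[2]
        trace.append(
            EliminationStep(
                removed=best_id,
                hr=float(best_thr.hr) if best_thr.ok else float("nan"),
                p=float(best_thr.p) if best_thr.ok else float("nan"),
                accepted=accepted,
            )
        )
        if not accepted:
            break
        current = [c for c in current if c != best_id]
        fit, scores, thr = best_eval
        current_metric = best_metric

    if not thr.ok:
        raise RuntimeError(
            "no valid risk-score threshold at the final step; trace: "
            + "; ".join(f"{s.removed}(accepted={s.accepted})" for s in trace)
        )
    orientation = "higher_is_risk" if thr.hr > 1 else "lower_is_risk"
    model = SignatureModel(
        components=current,
        scaler={c: (float(scaler.loc[c, "min"]), float(scaler.loc[c, "max"])) for c in current},
        coefficients={c: float(v) for c, v in zip(current, fit.coef)},
        risk_threshold=float(thr.threshold),
        orientation=orientation,
        intercept=fit.intercept,
    )
    return model, trace


def evaluate_signature(
    model: SignatureModel,
    markers: pd.DataFrame,
    clinical: pd.DataFrame,
    min_frac: float = 0.3,
    reoptimize_threshold: bool = False,
    clip: bool = False,
) -> dict:
    """Apply a signature to a cohort and report AUC / HR / KM statistics.

    Returns a dict with per-sample ``scores`` always present.  Response AUC is
    computed on the score oriented so that the training direction is
    preserved (responders are expected on the protective side).  The PFS HR
    uses the stored threshold unless ``reoptimize_threshold`` is set.
    Cohorts without PFS yield an AUC-only report; a single-sample cohort
    yields scores with statistics refused.
    """
    scaler = pd.DataFrame(
        {c: model.scaler[c] for c in model.components}, index=["min", "max"]
    ).T
    cohort_samples = [s for s in markers.columns if s in clinical.index]
    scaled = apply_scaler(
        markers.loc[model.components, cohort_samples], scaler, clip=clip
    )
    scores = risk_score(scaled, model)
    report: dict = {"scores": scores, "n": int(len(scores))}
    if len(scores) < 2:
        report["message"] = "statistics refused: fewer than 2 samples"
        return report

    arrays = _clinical_arrays(clinical, scores.index)
    scores = scores.loc[arrays["index"]]

    # response axis: orient so responders are expected to score high
    oriented = scores if model.orientation == "lower_is_risk" else -scores
    rl = arrays["resp_labels"][arrays["resp_mask"]]
    if arrays["resp_mask"].sum() >= 2 and 0 < rl.sum() < len(rl):
        report["auc"] = roc_auc(oriented.to_numpy()[arrays["resp_mask"]], rl)

    sv = arrays["surv_mask"]
    if sv.sum() >= 2 and arrays["event"][sv].astype(int).sum() >= 1:
        st = arrays["pfs"][sv]
        se = arrays["event"][sv].astype(int)
        svals = scores.to_numpy()[sv]
        if reoptimize_threshold:
            thr = optimize_threshold(svals, st, se, min_frac=min_frac)
            if thr.ok:
                report.update(hr=thr.hr, hr_p=thr.p, threshold=thr.threshold)
                high = svals > thr.threshold
            else:
                high = None
        else:
            high = svals > model.risk_threshold
            report["threshold"] = model.risk_threshold
            if 0 < high.sum() < len(high):
                try:
                    fit = cox_fit(st, se, high.astype(float))
                    hr, p = fit.single()
                    report.update(hr=hr, hr_p=p, cox_flagged=fit.flagged)
                except ValueError as exc:
                    report["message"] = f"Cox fit failed: {exc}"
                    high = None
            else:
                report["message"] = "stored threshold puts all samples in one group"
                high = None
        if high is not None and 0 < high.sum() < len(high):
            report["km_high"] = km_curve(st[high], se[high])
            report["km_low"] = km_curve(st[~high], se[~high])
            report["logrank_p"] = logrank_p(st, se, high)
            report["n_high"] = int(high.sum())
            report["n_low"] = int((~high).sum())
    else:
        report.setdefault("message", "no usable PFS data: AUC-only report")
    return report
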