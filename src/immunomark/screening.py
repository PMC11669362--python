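"""Biomarker screening against treatment response and progression-free survival.

Every candidate biomarker is scored twice:

* response axis — rank-based ROC AUC plus a Mann-Whitney test (numeric
  markers) or Fisher's exact test (categorical markers) between responders
  and non-responders;
* survival axis — a Cox proportional-hazards model.  Numeric markers are
  dichotomized at the threshold that maximizes ``|ln HR|`` subject to both
  groups holding at least 30% of the samples.

Selection filters: a PFS biomarker needs HR > 2.5 or HR < 0.4 with p < 0.05;
a response biomarker needs response-test p < 0.05 and AUC > 0.62.  The two
lists are intersected to obtain the universal biomarkers.

The Cox fitter is implemented here (partial likelihood with Efron tie
handling, Newton iteration, Wald p-values) because it is called thousands of
times during threshold optimization and backward elimination; it is verified
against brute-force likelihood maximization in the test suite.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RESPONSE_MAP",
    "map_response",
    "map_response_series",
    "roc_auc",
    "mann_whitney",
    "fisher_exact",
    "CoxResult",
    "cox_fit",
    "ThresholdResult",
    "optimize_threshold",
    "KMCurve",
    "km_curve",
    "logrank_p",
    "screen_biomarkers",
    "select_pfs_biomarkers",
    "select_response_biomarkers",
    "intersect_biomarkers",
    "load_clinical",
]

#: RECIST / pathological-response label -> binary response class.
RESPONSE_MAP = {
    "CR": "responder",
    "PR": "responder",
    "MPR": "responder",
    "SD": "non_responder",
    "PD": "non_responder",
    "non-MPR": "non_responder",
}

CLINICAL_COLUMNS = [
    "sample_id", "histotype", "recist", "pfs_months", "event",
    "anti_pd1", "anti_pdl1", "anti_ctla4",
]


def map_response(recist) -> str:
    """CR/PR/MPR -> responder; SD/PD/non-MPR -> non_responder; NA -> missing."""
    if recist is None or (isinstance(recist, float) and math.isnan(recist)):
        return "missing"
    label = str(recist).strip()
    if label in ("", "missing", "NA", "nan"):
        return "missing"
    try:
        return RESPONSE_MAP[label]
    except KeyError:
        raise ValueError(
            f"unknown response label {label!r}; accepted: {sorted(RESPONSE_MAP)}"
        ) from None


def map_response_series(recist: pd.Series) -> pd.Series:
    return recist.map(map_response)


# ---------------------------------------------------------------------------
# response-axis statistics

def roc_auc(values, labels) -> float:
    """Rank (Mann-Whitney) AUC with midranks for ties.

    ``labels`` flags responders; the AUC is the probability that a responder's
    value exceeds a non-responder's (ties count half).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be non-empty for AUC")
    ranks = stats.rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def mann_whitney(values, labels) -> float:
    """Two-sided Mann-Whitney U p-value between the two label groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    x, y = values[labels], values[~labels]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(values == values[0]):
        warnings.warn("constant values: Mann-Whitney p defined as 1", stacklevel=2)
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    A table with a zero margin carries no information; p is defined as 1 with
    a warning.
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin): p defined as 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton iteration)

@dataclass
class CoxResult:
    """Per-covariate Cox fit: coefficient, HR = exp(coef), SE, Wald p."""

    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    flagged: bool = False
    message: str = ""

    def single(self) -> tuple[float, float]:
        """(HR, p) of the sole covariate; errors if multivariate."""
        if len(self.coef) != 1:
            raise ValueError("single() requires a univariate fit")
        return float(self.hr[0]), float(self.p[0])


def _efron_ll_grad_hess(beta, t, e, X, w_cache=None):
    """Efron partial log-likelihood with gradient and Hessian.

    Inputs must be sorted by ascending time.  Fully vectorized: per-event
    fractional subtraction terms are built with reduceat over tie groups.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # reverse cumulative risk-set sums
    R = np.cumsum(w[::-1])[::-1]
    wX = w[:, None] * X
    RX = np.cumsum(wX[::-1], axis=0)[::-1]
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)
    RXX = np.cumsum(wXX[::-1], axis=0)[::-1]

    ev = np.flatnonzero(e)
    if len(ev) == 0:
        raise ValueError("at least one event is required")
    t_ev = t[ev]
    # tie groups among events
    new_group = np.r_[True, t_ev[1:] != t_ev[:-1]]
    starts = np.flatnonzero(new_group)
    group_id = np.cumsum(new_group) - 1
    d = np.diff(np.r_[starts, len(ev)])  # events per group
    within = np.arange(len(ev)) - starts[group_id]
    frac = within / d[group_id]

    # risk-set sums at each group's time (first sorted index with that time)
    s_idx = np.searchsorted(t, t_ev, side="left")
    S = R[s_idx]
    SX = RX[s_idx]
    SXX = RXX[s_idx]

    Wd = np.add.reduceat(w[ev], starts)[group_id]
    WXd = np.add.reduceat(wX[ev], starts, axis=0)[group_id]
    WXXd = np.add.reduceat(wXX[ev], starts, axis=0)[group_id]

    denom = S - frac * Wd
    gnum = SX - frac[:, None] * WXd
    hnum = SXX - frac[:, None, None] * WXXd

    loglik = float(eta[ev].sum() - np.log(denom).sum())
    grad = X[ev].sum(axis=0) - (gnum / denom[:, None]).sum(axis=0)
    hess = -(
        (hnum / denom[:, None, None]).sum(axis=0)
        - np.einsum("ij,ik,i->jk", gnum, gnum, 1.0 / denom**2)
    )
    return loglik, grad, hess


def cox_fit(times, events, covariates, max_iter: int = 50, tol: float = 1e-9) -> CoxResult:
    """Maximize the Efron partial likelihood by Newton iteration.

    ``covariates`` is a vector or an (n, p) matrix.  Non-convergence or a
    runaway coefficient (monotone likelihood, e.g. a group without events) is
    flagged on the result rather than silently reported.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (len(t) == len(e) == X.shape[0]):
        raise ValueError("times, events and covariates must share length")
    if e.sum() < 1:
        raise ValueError("at least one event is required")
    for j in range(X.shape[1]):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"covariate column {j} is constant")

    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    # center columns: improves conditioning, leaves coefficients unchanged
    shift = X.mean(axis=0)
    Xc = X - shift

    beta = np.zeros(X.shape[1])
    loglik, grad, hess = _efron_ll_grad_hess(beta, t, e, Xc)
    converged = False
    message = ""
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            message = "singular Hessian"
            break
        # step halving keeps the likelihood monotone
        scale = 1.0
        for _half in range(30):
            candidate = beta + scale * step
            new_ll, new_grad, new_hess = _efron_ll_grad_hess(candidate, t, e, Xc)
            if new_ll >= loglik - 1e-12:
                break
            scale *= 0.5
        beta, loglik, grad, hess = candidate, new_ll, new_grad, new_hess
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break

    flagged = not converged
    if np.max(np.abs(beta)) > 15:
        flagged = True
        message = message or "monotone likelihood suspected (runaway coefficient)"
    elif not converged and not message:
        message = "Newton iteration did not converge"

    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
        flagged = True
        message = message or "singular information matrix"
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CoxResult(
        coef=beta,
        se=se,
        hr=np.exp(beta),
        p=pvals,
        loglik=loglik,
        converged=converged,
        flagged=flagged,
        message=message,
    )


# ---------------------------------------------------------------------------
# HR-optimized dichotomization

@dataclass
class ThresholdResult:
    """Outcome of HR-optimized dichotomization of a numeric marker.

    ``hr`` is for the high group (value > threshold) vs the low group.  ``ok``
    is False when no valid split exists (constant marker, or the group-size
    constraint cannot be met).
    """

    threshold: float | None
    hr: float
    p: float
    n_low: int
    n_high: int
    ok: bool
    message: str = ""


def optimize_threshold(values, times, events, min_frac: float = 0.3) -> ThresholdResult:
    """Pick the dichotomization threshold maximizing ``|ln HR|``.

    Candidate thresholds are midpoints between consecutive sorted distinct
    values; only splits leaving at least ``ceil(min_frac * n)`` samples in
    each group are considered.  Samples are dichotomized as value > threshold
    vs value <= threshold.  Ties on ``|ln HR|`` resolve to the smallest
    threshold, making the scan deterministic.
    """
    values = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(values)
    min_group = math.ceil(min_frac * n)
    distinct = np.unique(values)
    if len(distinct) < 2:
        return ThresholdResult(None, np.nan, np.nan, 0, 0, False, "constant marker")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    best: ThresholdResult | None = None
    best_metric = -np.inf
    for thr in candidates:
        high = values > thr
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_low, n_high) < min_group:
            continue
        try:
            fit = cox_fit(t, e, high.astype(float))
        except ValueError:
            continue
        if fit.flagged:
            continue
        hr, p = fit.single()
        metric = abs(math.log(hr))
        if metric > best_metric + 1e-12:
            best_metric = metric
            best = ThresholdResult(float(thr), hr, p, n_low, n_high, True)
    if best is None:
        return ThresholdResult(
            None, np.nan, np.nan, 0, 0, False,
            f"no split satisfies the >= {min_group} per-group constraint",
        )
    return best


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit estimate: survival step function and median."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # nan when the curve never reaches 0.5

    def at(self, t: float) -> float:
        mask = self.times <= t
        return float(self.survival[mask][-1]) if mask.any() else 1.0


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier estimator; median is the smallest time with S <= 0.5."""
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) < 1:
        raise ValueError("at least one subject is required")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"]
    median = float(kmf.median_survival_time_)
    if math.isinf(median):
        median = float("nan")
    return KMCurve(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        median=median,
    )


def logrank_p(times, events, groups) -> float:
    """Two-group log-rank test p-value (reported alongside KM plots)."""
    from lifelines.statistics import logrank_test

    groups = np.asarray(groups, dtype=bool)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    res = logrank_test(t[groups], t[~groups], e[groups], e[~groups])
    return float(res.p_value)


# ---------------------------------------------------------------------------
# screening orchestration and selection filters

def load_clinical(path) -> pd.DataFrame:
    """Read the clinical CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table is missing column(s): {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    bad = df["pfs_months"].notna() & df["event"].isna()
    if bad.any():
        raise ValueError(
            f"event flag missing for samples with PFS: {list(df.loc[bad, 'sample_id'])}"
        )
    return df.set_index("sample_id", drop=False)


def _is_binary(values: np.ndarray) -> bool:
    finite = values[np.isfinite(values)]
    return bool(np.isin(finite, (0.0, 1.0)).all())


def screen_biomarkers(
    markers: pd.DataFrame,
    clinical: pd.DataFrame,
    min_frac: float = 0.3,
    kinds: dict[str, str] | None = None,
    hr_low: float = 0.4,
    hr_high: float = 2.5,
    auc_cutoff: float = 0.62,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every biomarker (rows of ``markers``) on both axes.

    ``markers`` is biomarkers x samples; ``clinical`` is indexed by sample id
    with ``recist``, ``pfs_months`` and ``event`` columns.  Samples missing
    RECIST are excluded from the response axis only; samples missing PFS are
    excluded from the survival axis only.

    Returns one row per biomarker with columns id, kind, hr, hr_p, threshold,
    n_low, n_high, auc, response_p, Benjamini-Hochberg companions (reported
    for transparency, never used for selection) and the three selection flags.
    """
    shared = [s for s in markers.columns if s in clinical.index]
    dropped = set(markers.columns) - set(shared)
    for s in sorted(dropped):
        logger.info("sample %s excluded: no clinical annotation", s)
    clin = clinical.loc[shared]
    response = map_response_series(clin["recist"])
    resp_mask = (response != "missing").to_numpy()
    resp_labels = (response == "responder").to_numpy()
    surv_mask = (clin["pfs_months"].notna() & clin["event"].notna()).to_numpy()
    for s in clin.index[~resp_mask]:
        logger.info("sample %s excluded from response screening: missing RECIST", s)
    for s in clin.index[~surv_mask]:
        logger.info("sample %s excluded from survival screening: missing PFS", s)
    pfs = clin["pfs_months"].to_numpy(dtype=float)
    event = clin["event"].to_numpy()

    rows = []
    for marker_id, row in markers.loc[:, shared].iterrows():
        values = row.to_numpy(dtype=float)
        kind = (kinds or {}).get(
            marker_id, "categorical" if _is_binary(values) else "numeric"
        )
        rec: dict = {
            "id": marker_id, "kind": kind,
            "hr": np.nan, "hr_p": np.nan, "threshold": np.nan,
            "n_low": 0, "n_high": 0, "auc": np.nan, "response_p": np.nan,
        }
        # survival axis
        sv, st, se_ = values[surv_mask], pfs[surv_mask], event[surv_mask].astype(int)
        if len(sv) >= 2 and se_.sum() >= 1:
            if kind == "numeric":
                thr = optimize_threshold(sv, st, se_, min_frac=min_frac)
                if thr.ok:
                    rec.update(
                        hr=thr.hr, hr_p=thr.p, threshold=thr.threshold,
                        n_low=thr.n_low, n_high=thr.n_high,
                    )
            else:
                high = sv > 0.5
                if 0 < high.sum() < len(high):
                    try:
                        fit = cox_fit(st, se_, high.astype(float))
                    except ValueError:
                        fit = None
                    if fit is not None and not fit.flagged:
                        hr, p = fit.single()
                        rec.update(
                            hr=hr, hr_p=p,
                            n_low=int((~high).sum()), n_high=int(high.sum()),
                        )
        # response axis
        rv, rl = values[resp_mask], resp_labels[resp_mask]
        if len(rv) >= 2 and 0 < rl.sum() < len(rl):
            rec["auc"] = roc_auc(rv, rl)
            if kind == "numeric":
                rec["response_p"] = mann_whitney(rv, rl)
            else:
                pos = rv > 0.5
                rec["response_p"] = fisher_exact(
                    int((pos & rl).sum()), int((pos & ~rl).sum()),
                    int((~pos & rl).sum()), int((~pos & ~rl).sum()),
                )
        rows.append(rec)

    out = pd.DataFrame(rows).set_index("id", drop=False)
    for col in ("hr_p", "response_p"):
        vals = out[col].to_numpy(dtype=float)
        adj = np.full_like(vals, np.nan)
        ok = np.isfinite(vals)
        if ok.any():
            adj[ok] = stats.false_discovery_control(vals[ok], method="bh")
        out[col + "_bh"] = adj
    pfs_ids = set(select_pfs_biomarkers(out, hr_low=hr_low, hr_high=hr_high, alpha=alpha))
    resp_ids = set(select_response_biomarkers(out, auc_cutoff=auc_cutoff, alpha=alpha))
    out["selected_pfs"] = out["id"].isin(pfs_ids)
    out["selected_response"] = out["id"].isin(resp_ids)
    out["selected_both"] = out["selected_pfs"] & out["selected_response"]
    return out


def select_pfs_biomarkers(
    results: pd.DataFrame,
    hr_low: float = 0.4,
    hr_high: float = 2.5,
    alpha: float = 0.05,
) -> list[str]:
    """Keep markers with (HR > 2.5 or HR < 0.4) and Cox p < 0.05."""
    hr = results["hr"].to_numpy(dtype=float)
    p = results["hr_p"].to_numpy(dtype=float)
    keep = np.isfinite(hr) & np.isfinite(p) & ((hr > hr_high) | (hr < hr_low)) & (p < alpha)
    return list(results["id"][keep])


def select_response_biomarkers(
    results: pd.DataFrame, auc_cutoff: float = 0.62, alpha: float = 0.05
) -> list[str]:
    """Keep markers with response-test p < 0.05 and AUC > 0.62."""
    auc = results["auc"].to_numpy(dtype=float)
    p = results["response_p"].to_numpy(dtype=float)
    keep = np.isfinite(auc) & np.isfinite(p) & (p < alpha) & (auc > auc_cutoff)
    return list(results["id"][keep])


def intersect_biomarkers(pfs_ids, response_ids) -> list[str]:
    """Ids present in both lists, in the order of the first."""
    response_set = set(response_ids)
    return [i for i in pfs_ids if i in response_set]
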