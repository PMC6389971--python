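"""Clustered ischemia-classification statistics.

Per-cycle end-systolic motion values are repeated, correlated measures
within subjects.  The classification chain therefore first fits a logistic
mixed model (subject as random intercept, ESM as the single fixed effect)
and uses its fitted probabilities as ROC scores; AUC is the Mann-Whitney
estimator (ties counted 1/2) and paired ROC curves are compared with
DeLong's placement-value covariance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ROCResult",
    "fit_ischemia_probability",
    "roc_points",
    "auc",
    "delong_compare",
    "sensitivity_at_specificity",
    "POSITIVE_INTERVENTIONS",
    "NEGATIVE_INTERVENTIONS",
    "label_from_intervention",
]

#: ischemia with and without dobutamine is the positive class; baseline,
#: dobutamine and reperfusion recordings are negative
POSITIVE_INTERVENTIONS = frozenset({"ischemia", "dob_isc"})
NEGATIVE_INTERVENTIONS = frozenset({"baseline", "dobutamine", "reperfusion"})


def label_from_intervention(intervention: str) -> int:
    if intervention in POSITIVE_INTERVENTIONS:
        return 1
    if intervention in NEGATIVE_INTERVENTIONS:
        return 0
    raise ValueError(f"unknown intervention label: {intervention!r}")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def _plain_logistic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ordinary logistic fit; ridge-penalised fallback on separation."""
    import statsmodels.api as sm

    exog = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e3:
            raise RuntimeError("separation suspected")
        return np.asarray(res.predict(exog))
    except Exception:
        warnings.warn(
            "logistic fit did not converge cleanly (possible complete "
            "separation); using a ridge-penalised fit"
        )
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=10.0)
        clf.fit(x.reshape(-1, 1), y)
        return clf.predict_proba(x.reshape(-1, 1))[:, 1]


def fit_ischemia_probability(
    esm_values: np.ndarray,
    labels: np.ndarray,
    subject_ids: np.ndarray,
    return_model: bool = False,
):
    """Fitted ischemia probabilities from a random-intercept logistic model.

    logit P(ischemic) = b0 + b1 * ESM + u_subject,  u ~ N(0, sd^2)

    Fit is a mean-field variational approximation (statsmodels
    BinomialBayesMixedGLM.fit_vb), which is the numerically stable GLMM
    route in this stack.
    When fewer than 3 subjects are present, or the fitted intercept sd
    collapses to ~0, the model falls back to a plain logistic regression
    with a logged warning.  Returned scores are the fitted probabilities
    (random effects included), which feed the ROC analysis.
    """
    x = np.asarray(esm_values, dtype=float)
    y = _check_labels(labels)
    subjects = np.asarray(subject_ids)
    if x.shape != y.shape or subjects.shape != y.shape:
        raise ValueError("esm_values, labels and subject_ids must align")
    uniq, subj_idx = np.unique(subjects, return_inverse=True)
    n_subj = uniq.size

    # standardise the covariate for numerical stability (monotone, so the
    # downstream ROC is unchanged)
    sd = x.std()
    xs = (x - x.mean()) / sd if sd > 0 else x - x.mean()

    if n_subj < 3:
        warnings.warn(
            f"only {n_subj} subjects: falling back to plain logistic regression"
        )
        probs = _plain_logistic(xs, y)
        return (probs, None) if return_model else probs

    import statsmodels.api as sm

    exog = np.column_stack([np.ones_like(xs), xs])
    exog_vc = np.zeros((xs.size, n_subj))
    exog_vc[np.arange(xs.size), subj_idx] = 1.0
    ident = np.zeros(n_subj, dtype=int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.BinomialBayesMixedGLM(y, exog, exog_vc, ident)
            # explicit starting sd: the default draws it from the global
            # RNG, which would make repeated fits non-deterministic
            n_par = 2 + 1 + n_subj  # fixed effects + vcp + intercepts
            fit = model.fit_vb(sd=np.full(n_par, np.exp(-0.5)))
        sd_u = float(np.exp(fit.vcp_mean[0]))
        if sd_u < 1e-3:
            raise RuntimeError("random-intercept variance collapsed to zero")
        eta = exog @ fit.fe_mean + exog_vc @ fit.vc_mean
        probs = expit(eta)
    except Exception as exc:  # noqa: BLE001 - deliberate documented fallback
        warnings.warn(f"mixed-model fit unavailable ({exc}); plain logistic fallback")
        probs = _plain_logistic(xs, y)
        fit = None
    return (probs, fit) if return_model else probs


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2 (equals the trapezoidal area
    under the tie-grouped ROC polygon)."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    m, n = pos.size, neg.size
    return float((r_pos - m * (m + 1) / 2.0) / (m * n))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Operating points at every distinct score threshold (ties grouped).

    The decision rule is ``score >= threshold -> positive``.  Points run
    from the all-negative operating point (threshold above the max score)
    to the all-positive one.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    thr = np.unique(scores)[::-1]
    # prepend a threshold above all scores: the (0, 1) corner
    thresholds = np.concatenate([[np.inf], thr])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        sens[i] = (pred & (labels == 1)).sum() / n_pos
        spec[i] = (~pred & (labels == 0)).sum() / n_neg
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc(scores, labels),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _placement_values(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components: V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10_i = fraction of negatives strictly below pos_i plus half the ties
    v10 = (np.sum(pos[:, None] > neg[None, :], axis=1)
           + 0.5 * np.sum(pos[:, None] == neg[None, :], axis=1)) / neg.size
    v01 = (np.sum(pos[None, :] > neg[:, None], axis=1)
           + 0.5 * np.sum(pos[None, :] == neg[:, None], axis=1)) / pos.size
    return v10, v01


def delong_compare(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """DeLong's test for two correlated ROC curves on paired scores.

    Returns ``(z, p)`` for the two-sided normal test of AUC_A = AUC_B.
    Identical curves (zero variance of the difference) give z = 0, p = 1.
    """
    labels = _check_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("paired scores must share the label rows")
    v10_a, v01_a = _placement_values(a, labels)
    v10_b, v01_b = _placement_values(b, labels)
    auc_a, auc_b = v10_a.mean(), v10_b.mean()
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))  # 2x2, ddof=1
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0 or (diff == 0 and var < 1e-15):
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def sensitivity_at_specificity(
    roc: ROCResult, spec_target: float = 0.8
) -> tuple[float, float]:
    """Cutoff and sensitivity at the operating point with specificity >=
    ``spec_target`` and maximal sensitivity (ties broken toward higher
    specificity).  The all-negative point (specificity 1) always qualifies,
    so a result always exists."""
    ok = roc.specificity >= spec_target
    idx = np.flatnonzero(ok)
    best = idx[np.lexsort((roc.specificity[idx], roc.sensitivity[idx]))][-1]
    return float(roc.thresholds[best]), float(roc.sensitivity[best])
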