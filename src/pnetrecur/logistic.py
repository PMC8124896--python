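"""Logistic risk-factor models and ROC analysis.

Three binary outcomes are modelled from one eligible cohort: any recurrence,
early recurrence (recurrence at or before the cut-off, versus every other
eligible patient) and late recurrence (recurrence after the cut-off, versus
every other eligible patient).  The workflow mirrors standard clinical
reporting: a univariable screen retains factors with p < 0.10, a
multivariable model is fitted on the retained factors, and effects are
reported as odds ratios with symmetric Wald intervals exp(β ± 1.96·SE).

The fitting engine is iteratively reweighted least squares (Newton–Raphson
with step halving) written on numpy; separation is detected and raised, not
silently returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .records import PatientRecord, classify_er_status

__all__ = [
    "LogisticFit",
    "ScreenResult",
    "RocCurve",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic",
    "univariable_screen",
    "multivariable_model",
    "roc_auc",
    "design_matrix",
    "build_outcome",
    "DEFAULT_FACTORS",
    "OUTCOME_TAGS",
]

OUTCOME_TAGS = ("recurrence", "early", "late")

#: Factor columns available to the risk models; each maps a patient record
#: to a numeric covariate (binary 0/1 or continuous), NaN when missing.
_FACTOR_FUNCS = {
    "age_gt_65": lambda r: np.nan if r.age is None else float(r.age > 65),
    "male": lambda r: np.nan if r.sex is None else float(r.sex == "male"),
    "symptomatic": lambda r: np.nan if r.symptomatic is None else float(r.symptomatic),
    "functional": lambda r: np.nan if r.functional is None else float(r.functional),
    "tumor_size": lambda r: np.nan if r.tumor_size is None else float(r.tumor_size),
    "margin_r1": lambda r: np.nan if r.margin is None else float(r.margin == "R1"),
    "severe_complication": lambda r: np.nan
    if r.severe_complication is None
    else float(r.severe_complication),
    "grade_g2": lambda r: np.nan if r.grade is None else float(r.grade == "G2"),
    "lvi": lambda r: np.nan if r.lvi is None else float(r.lvi),
    "pni": lambda r: np.nan if r.pni is None else float(r.pni),
    "nodes_positive": lambda r: np.nan
    if r.nodes_positive is None
    else float(r.nodes_positive),
}

DEFAULT_FACTORS = tuple(_FACTOR_FUNCS)

#: Reference level of each binary factor (continuous factors are per-unit).
FACTOR_REFERENCES = {
    "age_gt_65": "age ≤ 65",
    "male": "female",
    "symptomatic": "asymptomatic",
    "functional": "non-functional",
    "tumor_size": "per cm",
    "margin_r1": "R0",
    "severe_complication": "no severe complication",
    "grade_g2": "G1",
    "lvi": "no LVI",
    "pni": "no PNI",
    "nodes_positive": "node negative",
}


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """IRLS failed to reach the gradient tolerance within max_iter."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``table`` has one row per covariate with columns coef, se, odds_ratio,
    ci_low, ci_high, p; the intercept is kept separate.
    """

    outcome: str
    table: pd.DataFrame
    intercept: float
    intercept_se: float
    converged: bool
    n_iter: int
    log_likelihood: float
    n: int
    dropped: tuple = ()
    references: dict = field(default_factory=dict)


@dataclass
class ScreenResult:
    """Univariable odds ratios with the strict p < threshold inclusion flag."""

    outcome: str
    table: pd.DataFrame  # rows: factor; columns: odds_ratio, ci_low, ci_high, p, n, included
    threshold: float = 0.10

    @property
    def included(self) -> list[str]:
        return list(self.table.index[self.table["included"]])


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray  # sensitivity at score ≥ threshold
    fpr: np.ndarray  # 1 − specificity
    auc: float


# ---------------------------------------------------------------------------
# IRLS engine
# ---------------------------------------------------------------------------

_BETA_BOUND = 30.0  # |log-odds| beyond this flags separation


def _drop_aliased(X: np.ndarray, names: list[str]):
    """Greedily drop columns that do not increase the rank of [1 | X]."""
    n = X.shape[0]
    kept_cols = [np.ones(n)]
    kept_names: list[str] = []
    dropped: list[str] = []
    for j, name in enumerate(names):
        trial = np.column_stack(kept_cols + [X[:, j]])
        if np.linalg.matrix_rank(trial) > len(kept_cols):
            kept_cols.append(X[:, j])
            kept_names.append(name)
        else:
            dropped.append(name)
    return np.column_stack(kept_cols), kept_names, dropped


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # Numerically stable Bernoulli log-likelihood: -log(1+exp(-(2y-1)η)).
    z = (2 * y - 1) * eta
    return float(-np.sum(np.logaddexp(0.0, -z)))


def fit_logistic(
    design,
    outcome,
    tol: float = 1e-8,
    max_iter: int = 100,
    outcome_tag: str = "",
    names: Optional[Sequence[str]] = None,
) -> LogisticFit:
    """Fit a logistic regression by IRLS with step halving.

    ``design`` is an n × p covariate matrix (or DataFrame) without an
    intercept column — the intercept is added internally.  Aliased
    (collinear) columns are dropped with a warning before fitting.
    Convergence requires the gradient's max norm to fall below ``tol``;
    separation (any |β| exceeding a fixed log-odds bound, or non-finite
    updates) raises :class:`SeparationError` with a hint.
    """
    if isinstance(design, pd.DataFrame):
        col_names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        col_names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("design and outcome lengths differ")
    if y.size == 0 or np.all(y == y[0]):
        raise ValueError("outcome has no variation; logistic fit undefined")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")

    Xd, kept, dropped = _drop_aliased(X, col_names)
    if dropped:
        warnings.warn(
            f"dropped aliased covariate(s): {', '.join(dropped)}", stacklevel=2
        )

    p = Xd.shape[1]
    beta = np.zeros(p)
    eta = Xd @ beta
    ll = _log_likelihood(eta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        grad = Xd.T @ (y - mu)
        if np.max(np.abs(grad)) <= tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (quasi-separation); consider an "
                "exact or penalized method"
            ) from exc
        # Step halving keeps the log-likelihood monotone.
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            cand_eta = Xd @ candidate
            cand_ll = _log_likelihood(cand_eta, y)
            if cand_ll >= ll - 1e-12:
                break
            scale *= 0.5
        beta, eta, ll = candidate, cand_eta, cand_ll
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > _BETA_BOUND:
            raise SeparationError(
                "diverging coefficients indicate complete or quasi-complete "
                "separation; consider an exact or penalized method"
            )
    if not converged:
        mu = expit(eta)
        grad = Xd.T @ (y - mu)
        if np.max(np.abs(grad)) <= tol:
            converged = True
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(gradient max norm {np.max(np.abs(grad)):.3g})"
        )

    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (Xd * w[:, None]).T @ Xd
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))

    zcrit = 1.96
    rows = []
    for j, name in enumerate(kept, start=1):
        coef = beta[j]
        rows.append(
            {
                "coef": coef,
                "se": se[j],
                "odds_ratio": np.exp(coef),
                "ci_low": np.exp(coef - zcrit * se[j]),
                "ci_high": np.exp(coef + zcrit * se[j]),
                "p": 2.0 * stats.norm.sf(abs(coef) / se[j]),
            }
        )
    table = pd.DataFrame(rows, index=list(kept))
    return LogisticFit(
        outcome=outcome_tag,
        table=table,
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        converged=converged,
        n_iter=it,
        log_likelihood=ll,
        n=int(y.size),
        dropped=tuple(dropped),
        references={k: FACTOR_REFERENCES.get(k, "") for k in kept},
    )


# ---------------------------------------------------------------------------
# Cohort-level modelling
# ---------------------------------------------------------------------------

def design_matrix(
    records: Sequence[PatientRecord], factors: Sequence[str] = DEFAULT_FACTORS
) -> pd.DataFrame:
    """Numeric covariate frame (NaN = missing) for the requested factors."""
    unknown = [f for f in factors if f not in _FACTOR_FUNCS]
    if unknown:
        raise KeyError(f"unknown factor(s): {unknown}")
    data = {
        f: [_FACTOR_FUNCS[f](r) for r in records] for f in factors
    }
    return pd.DataFrame(data, index=[r.patient_id for r in records])


def build_outcome(
    records: Sequence[PatientRecord], tag: str, cutoff_months: float = 18.0
) -> np.ndarray:
    """Binary outcome vector for one of the three modelled endpoints.

    ``early`` codes recurrence at or before the cut-off against *all* other
    eligible patients (late recurrences and never-recurred alike); ``late``
    symmetrically.  NaN never occurs: eligibility guarantees recurrence
    status is known.
    """
    if tag not in OUTCOME_TAGS:
        raise ValueError(f"outcome tag must be one of {OUTCOME_TAGS}")
    out = np.empty(len(records))
    for i, rec in enumerate(records):
        if tag == "recurrence":
            out[i] = float(bool(rec.recurrence))
        else:
            status = classify_er_status(rec, cutoff_months).value
            out[i] = float(status == tag)
    return out


def univariable_screen(
    records: Sequence[PatientRecord],
    factors: Sequence[str] = DEFAULT_FACTORS,
    outcome_tag: str = "recurrence",
    cutoff_months: float = 18.0,
    threshold: float = 0.10,
) -> ScreenResult:
    """One single-covariate logistic fit per factor, complete-case each.

    Factors reach the multivariable stage when their Wald p is strictly
    below ``threshold``.  Factors with no non-missing values, or whose fit
    fails (separation), are excluded with a warning.
    """
    X = design_matrix(records, factors)
    y = build_outcome(records, outcome_tag, cutoff_months)
    if np.all(y == y[0]):
        raise ValueError("outcome has a single class; screen undefined")
    rows = []
    for factor in factors:
        x = X[factor].to_numpy()
        mask = ~np.isnan(x)
        if not mask.any() or np.nanstd(x) == 0:
            warnings.warn(f"factor {factor!r} has no usable variation; skipped")
            continue
        try:
            fit = fit_logistic(
                x[mask][:, None], y[mask], outcome_tag=outcome_tag, names=[factor]
            )
        except (SeparationError, ConvergenceError, ValueError) as exc:
            warnings.warn(f"factor {factor!r} skipped: {exc}")
            continue
        rec = fit.table.loc[factor]
        rows.append(
            {
                "factor": factor,
                "odds_ratio": rec["odds_ratio"],
                "ci_low": rec["ci_low"],
                "ci_high": rec["ci_high"],
                "p": rec["p"],
                "n": fit.n,
                "included": bool(rec["p"] < threshold),
            }
        )
    table = pd.DataFrame(rows).set_index("factor") if rows else pd.DataFrame(
        columns=["odds_ratio", "ci_low", "ci_high", "p", "n", "included"]
    )
    return ScreenResult(outcome=outcome_tag, table=table, threshold=threshold)


def multivariable_model(
    records: Sequence[PatientRecord],
    factors: Sequence[str],
    outcome_tag: str = "recurrence",
    cutoff_months: float = 18.0,
) -> LogisticFit:
    """Joint logistic fit of the screened factors on complete cases."""
    if not list(factors):
        raise ValueError(
            "no factors passed the screen; report univariable results only"
        )
    X = design_matrix(records, factors)
    y = build_outcome(records, outcome_tag, cutoff_months)
    mask = ~X.isna().any(axis=1).to_numpy()
    n_complete = int(mask.sum())
    if n_complete < 10 * len(list(factors)):
        warnings.warn(
            f"only {n_complete} complete cases for {len(list(factors))} covariates; "
            "estimates may be unstable"
        )
    return fit_logistic(X[mask], y[mask], outcome_tag=outcome_tag)


def roc_auc(scores, outcome) -> RocCurve:
    """ROC curve and AUC for a single continuous predictor.

    AUC is computed from midranks, so tied scores share rank mass; this
    equals the normalized Mann–Whitney U between the two classes.  Curve
    points use the rule score ≥ threshold ⇒ predicted positive, one point
    per distinct score.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcome must be equal-length 1-d arrays")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(s)  # midranks
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.unique(s)[::-1]
    tpr = np.array([np.mean(s[y] >= t) for t in thresholds])
    fpr = np.array([np.mean(s[~y] >= t) for t in thresholds])
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))
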