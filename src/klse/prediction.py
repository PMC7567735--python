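"""The metabolic-connectome-expression (MCE) prognostic pipeline.

MCE is an L1-penalized (LASSO) logistic score over the network feature
vector: the penalty selects a sparse subset of the 457 properties on the
training set and the score is their linear combination on training-
standardized features. Downstream, Cox proportional-hazards models (Efron
tie handling, per-SD hazard ratios) compare clinical, connectome, pattern
and combined covariate sets; performance is summarized by Harrell's
C-index on the test-set prognostic index (PI), and a median PI split feeds
Kaplan-Meier curves with a log-rank test.

Training hygiene: feature standardization and the cross-validated penalty
are computed on training rows only and frozen into the model artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MCEModel",
    "SurvivalRecord",
    "CoxFit",
    "fit_mce",
    "mce_score",
    "roc_auc",
    "fit_cox",
    "prognostic_index",
    "concordance_index",
    "km_stratified",
    "records_to_frame",
]


@dataclass
class MCEModel:
    """Sparse logistic score: intercept + sum(coef * standardized feature)."""

    coefficients: dict[str, float]
    intercept: float
    means: dict[str, float]
    sds: dict[str, float]
    lambda_: float
    n_folds: int
    seed: int
    rule: str = "1se"

    @property
    def selected_features(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "coefficients": self.coefficients,
                "intercept": self.intercept,
                "means": self.means,
                "sds": self.sds,
                "lambda": self.lambda_,
                "n_folds": self.n_folds,
                "seed": self.seed,
                "rule": self.rule,
            },
            sort_keys=True,
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "MCEModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            coefficients=d["coefficients"],
            intercept=d["intercept"],
            means=d["means"],
            sds=d["sds"],
            lambda_=d["lambda"],
            n_folds=d["n_folds"],
            seed=d["seed"],
            rule=d.get("rule", "1se"),
        )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_mce(
    features: pd.DataFrame,
    labels,
    n_folds: int = 10,
    seed: int = 0,
    rule: str = "1se",
    n_lambdas: int = 30,
    refit: bool = False,
) -> MCEModel:
    """LASSO logistic selection of network properties by cross-validated deviance.

    The penalty path runs from the smallest lambda that zeroes every
    coefficient down two decades (the usual n < p path); stratified ``n_folds``-fold CV picks
    lambda by held-out binomial deviance using the ``"1se"`` rule by default
    (largest lambda within one SE of the minimum; ``"min"`` optional). With
    ``refit=True`` the selected features are refit unpenalized. Deterministic
    given ``seed``.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    y = np.asarray(labels).astype(float).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    y = (y == classes.max()).astype(float)
    if len(features) < 20:
        raise ValueError("need >= 20 subjects")
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    Z, mu, sd = _standardize(X)
    n = len(y)

    lam_max = np.max(np.abs(Z.T @ (y - y.mean()))) / n
    lambdas = np.geomspace(lam_max, lam_max * 1e-2, n_lambdas)

    def fit_at(lam: float, Ztr: np.ndarray, ytr: np.ndarray) -> LogisticRegression:
        clf = LogisticRegression(
            l1_ratio=1, C=1.0 / (len(ytr) * lam), solver="liblinear",
            max_iter=2000, tol=1e-7, random_state=0,
        )
        clf.fit(Ztr, ytr)
        return clf

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Z, y))
    dev = np.empty((len(lambdas), n_folds))
    for fi, (tr, te) in enumerate(folds):
        for li, lam in enumerate(lambdas):
            clf = fit_at(lam, Z[tr], y[tr])
            p = clf.predict_proba(Z[te])[:, 1]
            dev[li, fi] = _binomial_deviance(y[te], p)
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        i_pick = i_min
    else:
        within = np.nonzero(mean_dev <= mean_dev[i_min] + se_dev[i_min])[0]
        i_pick = int(within.min())  # lambdas descend, so min index = largest penalty
    lam = float(lambdas[i_pick])

    clf = fit_at(lam, Z, y)
    coef = clf.coef_.ravel()
    intercept = float(clf.intercept_[0])
    nz = np.nonzero(coef != 0)[0]

    if refit and nz.size:
        refit_clf = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-9)
        refit_clf.fit(Z[:, nz], y)
        coef = np.zeros_like(coef)
        coef[nz] = refit_clf.coef_.ravel()
        intercept = float(refit_clf.intercept_[0])

    sel = {names[j]: float(coef[j]) for j in nz}
    return MCEModel(
        coefficients=sel,
        intercept=intercept,
        means={names[j]: float(mu[j]) for j in nz},
        sds={names[j]: float(sd[j]) for j in nz},
        lambda_=lam,
        n_folds=n_folds,
        seed=seed,
        rule=rule,
    )


def mce_score(model: MCEModel, features: pd.DataFrame) -> pd.Series:
    """Apply an MCE model: intercept + coef . (feature - mean)/sd per subject.

    Uses the standardization frozen at training time; unselected columns are
    ignored, missing selected columns raise naming the feature.
    """
    missing = [f for f in model.selected_features if f not in features.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    score = np.full(len(features), model.intercept, dtype=float)
    for name, c in model.coefficients.items():
        z = (features[name].to_numpy(dtype=float) - model.means[name]) / model.sds[name]
        score += c * z
    return pd.Series(score, index=features.index, name="mce")


def roc_auc(scores, labels) -> float:
    """AUC via the rank-sum (Mann-Whitney) identity; ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need both classes present")
    pos = y == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = sps.rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's time-to-conversion outcome plus model covariates."""

    subject_id: str
    time: float
    event: bool
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.subject_id}: time must be > 0")


def records_to_frame(records) -> pd.DataFrame:
    """SurvivalRecord list (or pass-through DataFrame) -> tidy survival frame."""
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "time": r.time, "event": int(r.event)}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CoxFit:
    """A fitted proportional-hazards model with per-SD hazard ratios."""

    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    c_index: float
    model_tag: str
    standardization: dict[str, tuple[float, float]]
    covariate_names: list[str]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "HR_lo95": self.ci_lower,
                "HR_hi95": self.ci_upper,
                "p": self.p_values,
            }
        )


def _is_binary(col: np.ndarray) -> bool:
    return np.unique(col).size <= 2


def fit_cox(
    records,
    covariate_names: list[str],
    standardize: bool = True,
    model_tag: str = "custom",
):
    """Cox proportional-hazards fit with Efron tie handling (via lifelines).

    Continuous covariates are standardized to unit SD on the provided data
    when ``standardize`` is true, so hazard ratios read as risk per SD
    increase; binary covariates (<= 2 levels) are left on their own scale.
    Wald 95% CIs; a rank-deficient design raises instead of silently fitting.
    """
    from lifelines import CoxPHFitter

    df = records_to_frame(records)
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")
    missing = [c for c in covariate_names if c not in df.columns]
    if missing:
        raise KeyError(f"missing covariates: {missing}")
    X = df[covariate_names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < len(covariate_names):
        raise ValueError("rank-deficient covariate design (collinear columns)")

    standardization: dict[str, tuple[float, float]] = {}
    model_df = df[["time", "event"]].copy()
    for c in covariate_names:
        col = df[c].to_numpy(dtype=float)
        if standardize and not _is_binary(col):
            mu, sd = float(col.mean()), float(col.std())
            sd = sd if sd > 0 else 1.0
            standardization[c] = (mu, sd)
            model_df[c] = (col - mu) / sd
        else:
            standardization[c] = (0.0, 1.0)
            model_df[c] = col

    cph = CoxPHFitter()
    cph.fit(model_df, duration_col="time", event_col="event")
    summ = cph.summary
    fit = CoxFit(
        coefficients={c: float(summ.loc[c, "coef"]) for c in covariate_names},
        hazard_ratios={c: float(summ.loc[c, "exp(coef)"]) for c in covariate_names},
        ci_lower={c: float(np.exp(summ.loc[c, "coef lower 95%"])) for c in covariate_names},
        ci_upper={c: float(np.exp(summ.loc[c, "coef upper 95%"])) for c in covariate_names},
        p_values={c: float(summ.loc[c, "p"]) for c in covariate_names},
        c_index=float(cph.concordance_index_),
        model_tag=model_tag,
        standardization=standardization,
        covariate_names=list(covariate_names),
    )
    return fit


def prognostic_index(fit: CoxFit, records) -> pd.Series:
    """Linear predictor beta . x using the training standardization."""
    df = records_to_frame(records)
    missing = [c for c in fit.covariate_names if c not in df.columns]
    if missing:
        raise KeyError(f"missing covariates: {missing}")
    pi = np.zeros(len(df))
    for c in fit.covariate_names:
        mu, sd = fit.standardization[c]
        pi += fit.coefficients[c] * (df[c].to_numpy(dtype=float) - mu) / sd
    index = df["subject_id"] if "subject_id" in df.columns else df.index
    return pd.Series(pi, index=index, name="PI")


def concordance_index(pi, time, event) -> float:
    """Harrell's C: over comparable pairs (t_i < t_j, event_i), the fraction
    where the earlier converter has the higher PI; PI ties count one half.
    """
    pi = np.asarray(pi, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    n = pi.size
    num = 0.0
    den = 0
    for i in range(n):
        if not e[i]:
            continue
        later = t > t[i]
        den += int(later.sum())
        num += float((pi[i] > pi[later]).sum()) + 0.5 * float((pi[i] == pi[later]).sum())
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


@dataclass
class KMStratification:
    """Median-PI risk strata with KM curves, log-rank test and stratum HR."""

    curves: dict[str, pd.DataFrame]
    logrank_stat: float
    logrank_p: float
    hr_high_vs_low: float
    hr_ci: tuple[float, float]
    threshold: float
    n_low: int
    n_high: int


def km_stratified(pi, records) -> KMStratification:
    """Split subjects at the median PI (ties to low risk) and compare survival.

    Kaplan-Meier curves per stratum, a log-rank test between them, and the
    hazard ratio of high- vs low-risk from a one-covariate Cox model.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df = records_to_frame(records)
    pi = np.asarray(pi, dtype=float)
    if pi.size != len(df):
        raise ValueError("PI and records length mismatch")
    thr = float(np.median(pi))
    high = pi > thr
    n_low, n_high = int((~high).sum()), int(high.sum())
    if n_low < 2 or n_high < 2:
        raise ValueError("degenerate stratum: need >= 2 subjects per risk group")

    curves: dict[str, pd.DataFrame] = {}
    for name, mask in (("low", ~high), ("high", high)):
        km = KaplanMeierFitter()
        km.fit(df.loc[mask, "time"], df.loc[mask, "event"], label=name)
        curves[name] = km.survival_function_

    lr = logrank_test(
        df.loc[~high, "time"], df.loc[high, "time"],
        event_observed_A=df.loc[~high, "event"], event_observed_B=df.loc[high, "event"],
    )
    cox_df = pd.DataFrame({"time": df["time"], "event": df["event"], "high": high.astype(float)})
    cph = CoxPHFitter()
    cph.fit(cox_df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.summary.loc["high", "coef"]))
    ci = (
        float(np.exp(cph.summary.loc["high", "coef lower 95%"])),
        float(np.exp(cph.summary.loc["high", "coef upper 95%"])),
    )
    return KMStratification(
        curves=curves,
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hr_high_vs_low=hr,
        hr_ci=ci,
        threshold=thr,
        n_low=n_low,
        n_high=n_high,
    )
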