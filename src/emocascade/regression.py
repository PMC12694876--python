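"""Regression layer: propagation metrics as a function of emotions.

Every model shares one specification: the propagation measure (log
transformed where skewed) regressed on six dominant-emotion dummies with
neutral as the base category, event fixed effects, and author/text
controls,

    DV = b0 + b1a*Anger + b1b*Fear + b1c*Sadness + b1d*Joy
       + b1e*Surprise + b1f*Disgust + b2*Event + b3*CONTROLS + e.

Cascade size is a count and is fit by negative-binomial (NB2) regression
with the dispersion profiled by maximum likelihood (a Poisson fit is
available for comparison); the remaining measures are fit by OLS.
Standard errors come in two flavours: the model-based ones and a CR1
cluster-robust sandwich with clusters at the event level — with only a
handful of events, a small-G warning is emitted and inference uses a
t reference with G-1 degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .emotion import NON_NEUTRAL
from .ingest import build_cascades
from .metrics import summarize_features
from .simulate import ScenarioConfig, gen_event_stream

logger = logging.getLogger(__name__)

CONTROL_COLUMNS = (
    "log_followers",
    "log_friends",
    "log_statuses",
    "log_likes",
    "verified",
    "word_count",
    "has_hashtag",
)

#: Supported dependent variables and the feature column each transforms.
DVS = ("size", "log_lifetime", "log_median_delay", "log_time5rt", "cv")


class InsufficientDataError(ValueError):
    """Too few rows or clusters to identify the requested model."""


class ConvergenceError(RuntimeError):
    """The iterative fit did not converge within the iteration budget."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient (collinear columns named)."""


class SmallClusterWarning(UserWarning):
    """Cluster-robust inference with fewer than 10 clusters."""


@dataclass
class DesignMatrix:
    """Response, named regressor matrix and cluster labels for one model."""

    response: np.ndarray
    X: pd.DataFrame
    clusters: np.ndarray
    dv: str
    min_size: int
    include_emotions: bool
    n_dropped: int = 0
    dropped_columns: tuple[str, ...] = ()

    @property
    def n_obs(self) -> int:
        return len(self.response)


@dataclass
class FitResult:
    """Coefficients and inference for one fitted model."""

    dv: str
    family: str
    min_size: int
    include_emotions: bool
    params: pd.Series
    se_model: pd.Series
    pvalues_model: pd.Series
    n_obs: int
    theta: float | None = None
    loglik: float | None = None
    aic: float | None = None
    adj_r2: float | None = None
    resid: np.ndarray | None = None
    fitted: np.ndarray | None = None
    se_cluster: pd.Series | None = None
    pvalues_cluster: pd.Series | None = None
    n_clusters: int | None = None
    _scores: np.ndarray | None = field(default=None, repr=False)
    _bread: np.ndarray | None = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table (model and, when present, cluster columns)."""
        out = pd.DataFrame({
            "coef": self.params,
            "se_model": self.se_model,
            "p_model": self.pvalues_model,
        })
        if self.se_cluster is not None:
            out["se_cluster"] = self.se_cluster
            out["p_cluster"] = self.pvalues_cluster
        return out

    def label(self) -> str:
        emo = "emotions" if self.include_emotions else "controls-only"
        return f"{self.dv}|{self.family}|min_size={self.min_size}|{emo}"


def build_design(
    features: pd.DataFrame,
    dv: str,
    min_size: int = 2,
    include_emotions: bool = True,
    size_response: str = "size",
) -> DesignMatrix:
    """Assemble the named design matrix for one dependent variable.

    Durations enter as log(1+x) (lifetime in minutes, delays in seconds,
    matching the summary-table units); CV enters raw; size enters as an
    untransformed count. ``size_response`` selects the count actually
    modelled: the full ``size`` (default), ``retweets`` (size-1) or
    ``excess`` (size-2, the synthetic generator's NB channel). Rows with
    an undefined DV are dropped (count logged).
    """
    if dv not in DVS:
        raise ValueError(f"unknown dv {dv!r}; expected one of {DVS}")
    if size_response not in ("size", "retweets", "excess"):
        raise ValueError(f"unknown size_response {size_response!r}")
    sub = features.loc[features["size"] >= min_size].copy()
    if dv == "size":
        shift = {"size": 0, "retweets": 1, "excess": 2}[size_response]
        y = (sub["size"] - shift).to_numpy(dtype=float)
    elif dv == "log_lifetime":
        y = np.log1p(sub["lifetime_s"].to_numpy(dtype=float) / 60.0)
    elif dv == "log_median_delay":
        y = np.log1p(sub["median_delay_s"].to_numpy(dtype=float))
    elif dv == "log_time5rt":
        y = np.log1p(sub["time5rt_s"].to_numpy(dtype=float))
    else:  # cv
        y = sub["cv"].to_numpy(dtype=float)
    defined = np.isfinite(y)
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("dv=%s: dropped %d rows with undefined response", dv, n_dropped)
    sub = sub.loc[defined]
    y = y[defined]

    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    if include_emotions:
        for e in NON_NEUTRAL:
            X[f"emo_{e}"] = (sub["dominant_emotion"] == e).astype(float)
    labels = sorted(sub["event_label"].unique())
    for l in labels[1:]:  # first (sorted) event is the base category
        X[f"event_{l}"] = (sub["event_label"] == l).astype(float)
    for c in CONTROL_COLUMNS:
        X[c] = sub[c].astype(float)

    dropped = tuple(c for c in X.columns if c != "const" and (X[c] == 0.0).all())
    if dropped:
        logger.info("dv=%s: dropped all-zero columns %s", dv, dropped)
        X = X.drop(columns=list(dropped))

    clusters = sub["event_label"].to_numpy()
    if len(np.unique(clusters)) < 2:
        raise InsufficientDataError(
            f"dv={dv}, min_size={min_size}: fewer than 2 event clusters remain"
        )
    if len(y) < X.shape[1] + 2:
        raise InsufficientDataError(
            f"dv={dv}, min_size={min_size}: {len(y)} rows for {X.shape[1]} columns"
        )
    return DesignMatrix(
        response=y, X=X, clusters=clusters, dv=dv, min_size=min_size,
        include_emotions=include_emotions, n_dropped=n_dropped,
        dropped_columns=dropped,
    )


# ----------------------------------------------------------------------
# Count models
# ----------------------------------------------------------------------

def _glm_fit(y: np.ndarray, X: pd.DataFrame, family) -> sm.GLM:
    res = sm.GLM(y, X, family=family).fit(maxiter=100)
    if not res.converged:
        raise ConvergenceError(
            f"GLM ({family.__class__.__name__}) did not converge in 100 iterations; "
            f"deviance trace tail: {res.fit_history['deviance'][-5:]}"
        )
    return res


def fit_count_model(
    design: DesignMatrix, family: str = "negative_binomial"
) -> FitResult:
    """Log-link count regression (negative binomial or Poisson).

    The NB2 dispersion theta (variance mu + mu^2/theta) is estimated by
    profiling the likelihood over log(alpha) with alpha = 1/theta; each
    profile point is an IRLS fit with alpha held fixed, so the procedure
    alternates coefficient updates with a 1-D dispersion search. Standard
    errors condition on the profiled dispersion (the convention of the
    usual NB regression implementations).
    """
    y = design.response
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("count response must consist of non-negative integers")
    X = design.X
    if family == "poisson":
        res = _glm_fit(y, X, sm.families.Poisson())
        alpha = None
    elif family == "negative_binomial":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # profile points may touch boundaries
            def neg_llf(log_alpha: float) -> float:
                fam = sm.families.NegativeBinomial(alpha=float(np.exp(log_alpha)))
                return -sm.GLM(y, X, family=fam).fit(maxiter=100).llf
            opt = scipy.optimize.minimize_scalar(
                neg_llf, bounds=(-12.0, 5.0), method="bounded",
                options={"xatol": 1e-6},
            )
            if not opt.success:
                raise ConvergenceError(f"dispersion profile failed: {opt.message}")
            alpha = float(np.exp(opt.x))
            res = _glm_fit(y, X, sm.families.NegativeBinomial(alpha=alpha))
    else:
        raise ValueError(f"unknown count family {family!r}")

    mu = np.asarray(res.fittedvalues)
    if alpha is None:
        scores = X.to_numpy() * (y - mu)[:, None]
    else:
        scores = X.to_numpy() * ((y - mu) / (1.0 + alpha * mu))[:, None]
    k = X.shape[1] + (0 if alpha is None else 1)
    llf = float(res.llf)
    return FitResult(
        dv=design.dv,
        family=family,
        min_size=design.min_size,
        include_emotions=design.include_emotions,
        params=pd.Series(res.params, index=X.columns),
        se_model=pd.Series(res.bse, index=X.columns),
        pvalues_model=pd.Series(res.pvalues, index=X.columns),
        n_obs=len(y),
        theta=None if alpha is None else 1.0 / alpha,
        loglik=llf,
        aic=2 * k - 2 * llf,
        resid=y - mu,
        fitted=mu,
        _scores=scores,
        _bread=np.asarray(res.cov_params()),
    )


# ----------------------------------------------------------------------
# OLS
# ----------------------------------------------------------------------

def _collinear_columns(X: pd.DataFrame) -> list[str]:
    A = X.to_numpy(dtype=float)
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    bad: set[str] = set()
    tol = s[0] * max(A.shape) * np.finfo(float).eps * 10
    for i, sv in enumerate(s):
        if sv < tol:
            involved = np.abs(vt[i]) > 1e-8
            bad.update(X.columns[involved])
    return sorted(bad)


def fit_ols(design: DesignMatrix) -> FitResult:
    """Ordinary least squares with model-based (non-robust) errors."""
    X = design.X
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise RankDeficiencyError(
            f"design is rank deficient; collinear columns: {_collinear_columns(X)}"
        )
    res = sm.OLS(design.response, X).fit()
    e = np.asarray(res.resid)
    xtx_inv = np.linalg.inv(X.to_numpy().T @ X.to_numpy())
    return FitResult(
        dv=design.dv,
        family="ols",
        min_size=design.min_size,
        include_emotions=design.include_emotions,
        params=pd.Series(res.params, index=X.columns),
        se_model=pd.Series(res.bse, index=X.columns),
        pvalues_model=pd.Series(res.pvalues, index=X.columns),
        n_obs=len(e),
        adj_r2=float(res.rsquared_adj),
        resid=e,
        fitted=np.asarray(res.fittedvalues),
        _scores=X.to_numpy() * e[:, None],
        _bread=xtx_inv,
    )


# ----------------------------------------------------------------------
# Cluster-robust inference
# ----------------------------------------------------------------------

def cluster_robust_se(fit: FitResult, design: DesignMatrix) -> FitResult:
    """CR1 cluster-robust sandwich errors, clustered on the event label.

    The meat is the sum over clusters of outer products of within-cluster
    score sums; the bread is the model-based parameter covariance (for
    OLS, (X'X)^-1 up to the error scale; for count GLMs, the inverse
    information at the estimating-equation scores). The small-sample
    factor is G/(G-1) * (n-1)/(n-k). p-values use a t reference with G-1
    degrees of freedom. Warns when G < 10.
    """
    if fit._scores is None or fit._bread is None:
        raise ValueError("fit carries no scores; refit with this module's fitters")
    groups = np.asarray(design.clusters)
    uniq = np.unique(groups)
    G = len(uniq)
    if G < 2:
        raise InsufficientDataError("cluster-robust errors require >= 2 clusters")
    if G < 10:
        warnings.warn(
            f"only {G} clusters: cluster-robust errors may be optimistic",
            SmallClusterWarning,
            stacklevel=2,
        )
    n, k = fit._scores.shape
    meat = np.zeros((k, k))
    for g in uniq:
        s_g = fit._scores[groups == g].sum(axis=0)
        meat += np.outer(s_g, s_g)
    c = (G / (G - 1.0)) * ((n - 1.0) / (n - k))
    cov = c * fit._bread @ meat @ fit._bread
    se = pd.Series(np.sqrt(np.diag(cov)), index=fit.params.index)
    t = fit.params / se
    pvals = pd.Series(
        2.0 * scipy.stats.t.sf(np.abs(t), df=G - 1), index=fit.params.index
    )
    return dataclasses.replace(
        fit, se_cluster=se, pvalues_cluster=pvals, n_clusters=G
    )


# ----------------------------------------------------------------------
# Battery, sign patterns, recovery
# ----------------------------------------------------------------------

#: The model battery: (dv, family, min_size), each run with and without
#: emotion dummies -> 14 paired fits (the controls-only column next to
#: the full specification, for each outcome and size threshold).
BATTERY_SPECS: tuple[tuple[str, str, int], ...] = (
    ("size", "negative_binomial", 2),
    ("size", "negative_binomial", 3),
    ("log_lifetime", "ols", 2),
    ("log_lifetime", "ols", 3),
    ("log_median_delay", "ols", 6),
    ("log_time5rt", "ols", 6),
    ("cv", "ols", 6),
)


def run_model_battery(
    features: pd.DataFrame, size_response: str = "size"
) -> list[FitResult]:
    """Fit the full model battery with cluster-robust errors attached."""
    fits: list[FitResult] = []
    for dv, family, min_size in BATTERY_SPECS:
        for include_emotions in (False, True):
            design = build_design(
                features, dv, min_size=min_size,
                include_emotions=include_emotions, size_response=size_response,
            )
            if family == "ols":
                fit = fit_ols(design)
            else:
                fit = fit_count_model(design, family=family)
            fits.append(cluster_robust_se(fit, design))
    return fits


#: Summary-table rows: metric name -> (dv, min_size, invert sign?).
#: Speed is read off the median-delay model with the sign inverted
#: (a negative delay coefficient means faster resharing).
SIGN_PATTERN_SOURCES: dict[str, tuple[str, int, bool]] = {
    "size": ("size", 2, False),
    "lifetime": ("log_lifetime", 2, False),
    "speed": ("log_median_delay", 6, True),
    "burstiness": ("cv", 6, False),
}


def sign_pattern(fits: Sequence[FitResult], alpha: float = 0.05) -> pd.DataFrame:
    """Per-emotion (+)/(-)/(0) effect summary across the four dimensions.

    Signs come from the with-emotions fits' coefficients; significance
    from the cluster-robust p-values at level ``alpha``. Non-significant
    effects are reported as "0".
    """
    table = pd.DataFrame(index=list(NON_NEUTRAL), columns=list(SIGN_PATTERN_SOURCES))
    table.index.name = "emotion"
    for metric, (dv, min_size, invert) in SIGN_PATTERN_SOURCES.items():
        fit = next(
            (f for f in fits
             if f.dv == dv and f.min_size == min_size and f.include_emotions),
            None,
        )
        if fit is None:
            raise ValueError(f"battery output lacks the {dv} (min_size={min_size}) fit")
        pvals = fit.pvalues_cluster if fit.pvalues_cluster is not None else fit.pvalues_model
        for e in NON_NEUTRAL:
            name = f"emo_{e}"
            if name not in fit.params.index:
                table.loc[e, metric] = "0"
                continue
            coef = fit.params[name]
            if invert:
                coef = -coef
            table.loc[e, metric] = (
                "0" if pvals[name] >= alpha else ("+" if coef > 0 else "-")
            )
    return table


@dataclass
class RecoveryReport:
    """Monte-Carlo recovery of the generator's emotion coefficients."""

    n_reps: int
    n_cascades: int
    coefficients: pd.DataFrame  # index emo_*, columns true/mean/bias/sd/coverage95
    pooled_coverage95: float

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "n_cascades": self.n_cascades,
            "pooled_coverage95": self.pooled_coverage95,
            "coefficients": self.coefficients.to_dict(orient="index"),
        }


def recovery_experiment(
    config: ScenarioConfig, n_reps: int, seed: int = 0
) -> RecoveryReport:
    """Simulate -> assemble -> featurize -> fit, ``n_reps`` times.

    Each replicate regenerates a stream under ``config`` with a derived
    seed, rebuilds cascades and features, fits the NB size model on the
    generator's own count channel (size - 2) and records the emotion
    coefficients with cluster-robust 95% intervals. As everywhere else in
    this module, cluster inference uses a t reference with G-1 degrees of
    freedom — with a handful of clusters the normal critical value is
    known to undercover.
    """
    names = [f"emo_{e}" for e in NON_NEUTRAL]
    true = np.array([config.size_betas.get(n, 0.0) for n in names])
    estimates = np.full((n_reps, len(names)), np.nan)
    ses = np.full((n_reps, len(names)), np.nan)
    n_clusters = np.full(n_reps, 2, dtype=int)
    for rep in range(n_reps):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31)
        cfg = dataclasses.replace(config, seed=rep_seed)
        events, authors, _ = gen_event_stream(cfg)
        cascades = build_cascades(events, 0.0, cfg.window_days)
        features = summarize_features(cascades, authors)
        design = build_design(features, "size", min_size=2, size_response="excess")
        fit = fit_count_model(design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallClusterWarning)
            fit = cluster_robust_se(fit, design)
        n_clusters[rep] = fit.n_clusters
        for j, name in enumerate(names):
            if name in fit.params.index:
                estimates[rep, j] = fit.params[name]
                ses[rep, j] = fit.se_cluster[name]
    crit = scipy.stats.t.ppf(0.975, df=n_clusters - 1)[:, None]
    covered = np.abs(estimates - true[None, :]) <= crit * ses
    coef = pd.DataFrame({
        "true": true,
        "mean": np.nanmean(estimates, axis=0),
        "bias": np.nanmean(estimates, axis=0) - true,
        "sd": np.nanstd(estimates, axis=0, ddof=1),
        "coverage95": np.nanmean(covered.astype(float), axis=0),
    }, index=names)
    return RecoveryReport(
        n_reps=n_reps,
        n_cascades=config.n_cascades,
        coefficients=coef,
        pooled_coverage95=float(np.nanmean(covered.astype(float))),
    )
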