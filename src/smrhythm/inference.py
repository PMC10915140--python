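"""Bayesian regression analyses of signal features and clinical scores.

Two analyses are implemented:

1. feature ~ group + age + age^2 + sex + cortical thickness (+ two-way
   interactions), Gaussian for continuous features and Poisson with an
   exposure offset for the burst count, compared by sequentially adding
   predictors and converting BIC differences to Bayes factors.
2. symptom subscale ~ ten signal features + covariates in the PD group,
   with leave-one-predictor-out Bayes factors.

Bayes factors use the BIC approximation BF10 = exp((BIC0 - BIC1)/2), with
BF > 3 as the evidence cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sst

from .exceptions import (
    DegenerateDesignError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidTableError,
    UndefinedPercentError,
)
from .synthgen import (
    CLINICAL_COVARIATES,
    FEATURES,
    INTERACTION_PREDICTORS,
    MAIN_PREDICTORS,
)

__all__ = [
    "Design",
    "PredictorStat",
    "ModelComparisonResult",
    "prepare_design",
    "bic_bayes_factor",
    "sequential_bf",
    "percent_effect",
    "clinical_regression",
    "welch_t_test",
    "yates_chi_square",
    "DEFAULT_ORDER",
    "LOG_FEATURES",
]

LOG_FEATURES = ("burst_duration", "burst_interval", "burst_amplitude")
DEFAULT_ORDER = tuple(MAIN_PREDICTORS) + tuple(INTERACTION_PREDICTORS)

_Z95 = sst.norm.ppf(0.975)


@dataclass
class Design:
    """Prepared outcome/design for one regression."""

    outcome: str
    family: str  # "gaussian" or "poisson"
    y: np.ndarray
    X: pd.DataFrame  # named predictor columns, no intercept
    exposure: np.ndarray | None  # minutes, Poisson only
    scales: dict  # centring/scaling metadata for back-transforms
    index: pd.Index

    @property
    def n(self) -> int:
        return self.y.size


@dataclass(frozen=True)
class PredictorStat:
    estimate: float
    ci_low: float
    ci_high: float
    bf10: float


@dataclass
class ModelComparisonResult:
    outcome: str
    family: str
    order: tuple[str, ...]
    stats: dict[str, PredictorStat]
    n: int
    scales: dict = field(default_factory=dict)
    coef_names: tuple[str, ...] = ()
    coefs: np.ndarray | None = None  # full-model coefficients incl. intercept
    cov: np.ndarray | None = None

    def flagged(self, cutoff: float = 3.0) -> list[str]:
        """Predictors with substantial evidence (BF10 > cutoff)."""
        return [p for p, s in self.stats.items() if s.bf10 > cutoff]


def _encode_binary(series: pd.Series, mapping: dict) -> pd.Series:
    if series.dtype == object:
        bad = set(series.dropna()) - set(mapping)
        if bad:
            raise InvalidParameterError(f"unknown levels {sorted(bad)}")
        return series.map(mapping).astype(float)
    return series.astype(float)


def prepare_design(
    table: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...] = DEFAULT_ORDER,
) -> Design:
    """Centre/scale predictors, transform the outcome, drop missing rows.

    Continuous predictors (age, thickness) are centred and scaled to unit
    SD; age^2 is the square of centred/scaled age; group and sex are coded
    0/1 (reference: healthy control, female).  Gaussian outcomes are
    z-scored — burst duration/interval/amplitude after a natural-log
    transform — while the burst count outcome stays a count with exposure =
    analyzed minutes.
    """
    if outcome not in table.columns:
        raise InvalidParameterError(f"outcome '{outcome}' not in table")
    needed = ["group", "age", "sex", "cortical_thickness", outcome]
    if outcome == "burst_rate":
        needed += ["analyzed_s"]
    rows = table.dropna(subset=[c for c in needed if c in table.columns])
    if len(rows) < 10:
        raise InsufficientDataError(
            f"outcome '{outcome}' present for only {len(rows)} subjects"
        )

    group = _encode_binary(rows["group"], {"hc": 0.0, "pd": 1.0})
    sex = _encode_binary(rows["sex"], {"female": 0.0, "male": 1.0})
    age = rows["age"].astype(float)
    thickness = rows["cortical_thickness"].astype(float)
    for name, col in (("age", age), ("thickness", thickness), ("group", group), ("sex", sex)):
        if col.std(ddof=0) == 0.0:
            raise DegenerateDesignError(f"predictor '{name}' has zero variance")

    scales = {
        "age_mean": float(age.mean()),
        "age_sd": float(age.std(ddof=0)),
        "thickness_mean": float(thickness.mean()),
        "thickness_sd": float(thickness.std(ddof=0)),
    }
    age_z = (age - scales["age_mean"]) / scales["age_sd"]
    thick_z = (thickness - scales["thickness_mean"]) / scales["thickness_sd"]
    base = {"group": group, "age": age_z, "sex": sex, "thickness": thick_z}

    X = pd.DataFrame(index=rows.index)
    for name in predictors:
        if name in base:
            X[name] = base[name]
        elif name == "age2":
            X[name] = age_z**2
        elif ":" in name:
            a, b = name.split(":")
            if a not in base or b not in base:
                raise InvalidParameterError(f"unknown predictor '{name}'")
            X[name] = base[a] * base[b]
        else:
            raise InvalidParameterError(f"unknown predictor '{name}'")

    if outcome == "burst_rate":
        if "n_events" in rows.columns and rows["n_events"].notna().all():
            y = rows["n_events"].to_numpy(dtype=float)
        else:
            y = np.round(
                rows[outcome].to_numpy(dtype=float) * rows["analyzed_s"].to_numpy() / 60.0
            )
        exposure = rows["analyzed_s"].to_numpy(dtype=float) / 60.0
        family = "poisson"
    else:
        y = rows[outcome].to_numpy(dtype=float)
        if outcome in LOG_FEATURES:
            if np.any(y <= 0):
                raise InvalidParameterError(
                    f"'{outcome}' must be strictly positive for the log transform"
                )
            y = np.log(y)
        scales["y_mean"] = float(y.mean())
        scales["y_sd"] = float(y.std(ddof=0))
        if scales["y_sd"] == 0:
            raise DegenerateDesignError(f"outcome '{outcome}' has zero variance")
        y = (y - scales["y_mean"]) / scales["y_sd"]
        exposure = None
        family = "gaussian"

    return Design(
        outcome=outcome,
        family=family,
        y=y,
        X=X,
        exposure=exposure,
        scales=scales,
        index=rows.index,
    )


def bic_bayes_factor(bic_h0: float, bic_h1: float) -> float:
    """BF10 = exp((BIC0 - BIC1) / 2)."""
    if not (np.isfinite(bic_h0) and np.isfinite(bic_h1)):
        raise InvalidParameterError("BIC values must be finite")
    with np.errstate(over="ignore"):  # overwhelming evidence saturates to inf
        return float(np.exp((bic_h0 - bic_h1) / 2.0))


def _gaussian_fit(X: np.ndarray, y: np.ndarray):
    """Exact-likelihood least squares: (coefs, cov, bic)."""
    n, p = X.shape
    coefs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    rss = float(resid @ resid)
    rss = max(rss, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    bic = -2.0 * loglik + (p + 1) * np.log(n)  # +1 for the error variance
    dof = max(n - p, 1)
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    cov = sigma2 * xtx_inv
    return coefs, cov, bic


def _poisson_fit(X: np.ndarray, y: np.ndarray, exposure: np.ndarray, label: str):
    n, p = X.shape
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(exposure))
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:  # perfect separation, non-convergence, ...
        raise FitFailureError(f"Poisson fit failed at step '{label}': {exc}")
    if not res.converged:
        raise FitFailureError(f"Poisson fit did not converge at step '{label}'")
    bic = -2.0 * float(res.llf) + p * np.log(n)
    return res.params, res.cov_params(), bic


def _fit(design: Design, columns: list[str], label: str):
    X = np.column_stack(
        [np.ones(design.n)] + [design.X[c].to_numpy() for c in columns]
    )
    if design.family == "poisson":
        return _poisson_fit(X, design.y, design.exposure, label)
    return _gaussian_fit(X, design.y)


def sequential_bf(
    table: pd.DataFrame,
    outcome: str,
    order: tuple[str, ...] = DEFAULT_ORDER,
) -> ModelComparisonResult:
    """Sequential model comparison plus full-model coefficients.

    Predictors are added in ``order``; at each step BF10 compares the model
    with the new predictor (H1) against the previous model (H0) via the BIC
    approximation.  The full model provides standardized coefficients with
    95% Wald intervals.
    """
    design = prepare_design(table, outcome, predictors=tuple(order))

    bfs: dict[str, float] = {}
    included: list[str] = []
    _, _, bic_prev = _fit(design, included, "intercept")
    for name in order:
        included.append(name)
        _, _, bic_cur = _fit(design, included, name)
        bfs[name] = bic_bayes_factor(bic_prev, bic_cur)
        bic_prev = bic_cur

    coefs, cov, _ = _fit(design, list(order), "full")
    coef_names = ("intercept",) + tuple(order)
    se = np.sqrt(np.clip(np.diag(np.asarray(cov)), 0.0, None))
    stats = {}
    for i, name in enumerate(order, start=1):
        stats[name] = PredictorStat(
            estimate=float(coefs[i]),
            ci_low=float(coefs[i] - _Z95 * se[i]),
            ci_high=float(coefs[i] + _Z95 * se[i]),
            bf10=bfs[name],
        )
    return ModelComparisonResult(
        outcome=outcome,
        family=design.family,
        order=tuple(order),
        stats=stats,
        n=design.n,
        scales=design.scales,
        coef_names=coef_names,
        coefs=np.asarray(coefs, dtype=float),
        cov=np.asarray(cov, dtype=float),
    )


def _unit_scale(result: ModelComparisonResult, predictor: str) -> float:
    """Divisor taking a standardized coefficient to the original unit."""
    if predictor == "age":
        return result.scales.get("age_sd", 1.0)
    if predictor == "thickness":
        return result.scales.get("thickness_sd", 1.0)
    return 1.0  # binary predictors


def percent_effect(
    result: ModelComparisonResult,
    predictor: str,
    group: str | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percent change per original-scale unit of ``predictor`` with 95% CI.

    Poisson family: ``100 * (exp(beta) - 1)`` per unit, where beta combines
    the main effect with the group interaction when ``group='pd'``.
    Gaussian family: 100 x (fitted difference) / (fitted control mean at
    covariate means), interval by parametric resampling of the coefficient
    vector.
    """
    if predictor not in result.order:
        raise InvalidParameterError(f"predictor '{predictor}' not in model")
    names = list(result.coef_names)
    combo = np.zeros(len(names))
    unit = _unit_scale(result, predictor)
    combo[names.index(predictor)] = 1.0 / unit
    if group == "pd":
        for inter in (f"{predictor}:group", f"group:{predictor}"):
            if inter in names:
                combo[names.index(inter)] += 1.0 / unit

    if result.family == "poisson":
        beta = float(combo @ result.coefs)
        var = float(combo @ result.cov @ combo)
        se = np.sqrt(max(var, 0.0))
        pct = 100.0 * (np.exp(beta) - 1.0)
        lo = 100.0 * (np.exp(beta - _Z95 * se) - 1.0)
        hi = 100.0 * (np.exp(beta + _Z95 * se) - 1.0)
        return pct, lo, hi

    # Gaussian: percent of the control mean on the original outcome scale.
    y_mean, y_sd = result.scales["y_mean"], result.scales["y_sd"]

    def pct_of(coefs):
        control = y_mean + y_sd * coefs[0]  # covariates at their means
        diff = y_sd * float(combo @ coefs)
        if control <= 0:
            raise UndefinedPercentError(
                "fitted control mean is non-positive; percent change undefined"
            )
        return 100.0 * diff / control

    pct = pct_of(result.coefs)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(result.coefs, result.cov, size=n_draws)
    samples = []
    for d in draws:
        control = y_mean + y_sd * d[0]
        if control <= 0:
            continue
        samples.append(100.0 * y_sd * float(combo @ d) / control)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return pct, float(lo), float(hi)


def clinical_regression(
    pd_table: pd.DataFrame,
    symptom: str,
    features: tuple[str, ...] = FEATURES,
    covariates: tuple[str, ...] = CLINICAL_COVARIATES,
) -> ModelComparisonResult:
    """Symptom subscale ~ signal features + covariates in the PD group.

    All symptom ratings and continuous predictors except age are z-scored;
    leave-one-predictor-out Bayes factors compare the full model (H1)
    against the model without that predictor (H0).
    """
    rows = pd_table
    if "group" in rows.columns:
        grp = _encode_binary(rows["group"], {"hc": 0.0, "pd": 1.0})
        rows = rows[grp == 1.0]
    if symptom not in rows.columns:
        raise InvalidParameterError(f"symptom '{symptom}' not in table")

    predictors = list(features) + [c for c in covariates]
    col_map = {"thickness": "cortical_thickness"}
    used_cols = [col_map.get(p, p) for p in predictors]
    rows = rows.dropna(subset=[c for c in used_cols + [symptom] if c in rows.columns])
    n = len(rows)
    if n <= len(predictors) + 2:
        raise InsufficientDataError(
            f"n={n} too small for {len(predictors)} predictors"
        )

    def zscore(x):
        x = np.asarray(x, dtype=float)
        sd = x.std(ddof=0)
        if sd == 0.0:
            raise DegenerateDesignError("zero-variance predictor in clinical model")
        return (x - x.mean()) / sd

    X = pd.DataFrame(index=rows.index)
    for p in predictors:
        if p == "sex":
            X[p] = _encode_binary(rows["sex"], {"female": 0.0, "male": 1.0}).to_numpy()
        elif p == "age":
            X[p] = rows["age"].to_numpy(dtype=float)  # left unstandardized
        else:
            X[p] = zscore(rows[col_map.get(p, p)])
    y = zscore(rows[symptom])

    def fit(cols):
        M = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in cols])
        return _gaussian_fit(M, y)

    coefs, cov, bic_full = fit(predictors)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    stats = {}
    for i, name in enumerate(predictors, start=1):
        reduced = [p for p in predictors if p != name]
        _, _, bic_red = fit(reduced)
        stats[name] = PredictorStat(
            estimate=float(coefs[i]),
            ci_low=float(coefs[i] - _Z95 * se[i]),
            ci_high=float(coefs[i] + _Z95 * se[i]),
            bf10=bic_bayes_factor(bic_red, bic_full),
        )
    return ModelComparisonResult(
        outcome=symptom,
        family="gaussian",
        order=tuple(predictors),
        stats=stats,
        n=n,
        coef_names=("intercept",) + tuple(predictors),
        coefs=np.asarray(coefs, dtype=float),
        cov=np.asarray(cov, dtype=float),
    )


def welch_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Unequal-variance t test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("need at least two observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise InvalidParameterError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sst.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def yates_chi_square(table2x2) -> tuple[float, float]:
    """Continuity-corrected chi-square of independence for a 2x2 table.

    chi2 = sum over cells of max(|O - E| - 0.5, 0)^2 / E with df = 1.
    """
    obs = np.asarray(table2x2, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise InvalidTableError("expected a 2x2 table of non-negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise InvalidTableError("contingency table has a zero marginal")
    expected = np.outer(row, col) / total
    corrected = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float(np.sum(corrected**2 / expected))
    p = float(sst.chi2.sf(chi2, df=1))
    return chi2, p
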