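"""Cohort-level mixed-effects statistics on the per-trial decomposition.

Two nested linear mixed models of the angle between component directions
(delta-theta), both with a participant random intercept:

    model1: delta_theta ~ Vision + Phase + (1 | participant)
    model2: delta_theta ~ Vision + Phase + SD_H + H1 + H2 + (1 | participant)

plus the Vision x Phase interaction variant needed for nested-model
comparison.  With a single random intercept the (RE)ML criterion profiles
analytically down to one dimension -- the variance ratio tau^2/sigma^2 -- so
coefficients come from an exact profiled REML fit (1-D Brent search; the
test suite cross-checks it against lme4/lmerTest).  P-values use
Satterthwaite's approximation of the denominator degrees of freedom;
likelihood-ratio tests compare maximum-likelihood (not REML) refits, as
required for tests on fixed effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .synthetic import PHASE_LEVELS, VISION_LEVELS

__all__ = [
    "CohortTable",
    "MixedModelFit",
    "LrtResult",
    "build_cohort_table",
    "fit_model1",
    "fit_model2",
    "fit_interaction_model",
    "likelihood_ratio_test",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("participant", "vision", "phase", "delta_theta", "sd_h", "h1", "h2")

MODEL_TERMS = {
    "model1": ("Vision[EyesClosed]", "Phase[HeadRotation]", "Phase[After]"),
    "model2": (
        "Vision[EyesClosed]",
        "Phase[HeadRotation]",
        "Phase[After]",
        "SD_H",
        "H1",
        "H2",
    ),
    "model1_interaction": (
        "Vision[EyesClosed]",
        "Phase[HeadRotation]",
        "Phase[After]",
        "Vision[EyesClosed]:Phase[HeadRotation]",
        "Vision[EyesClosed]:Phase[After]",
    ),
}

CohortTable = pd.DataFrame  # tidy one-row-per-trial table, see build_cohort_table


@dataclass
class MixedModelFit:
    """Fixed-effect estimates with Satterthwaite p-values and log-likelihoods."""

    formula_id: str
    terms: pd.DataFrame  # index term; columns B, SE, t, df, p
    loglik_reml: float
    loglik_ml: float
    n_obs: int
    n_groups: int
    residual_var: float
    intercept_var: float

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return tuple(self.terms.index)

    @property
    def n_fixed(self) -> int:
        return len(self.terms)

    def to_dict(self) -> dict:
        return {
            "formula_id": self.formula_id,
            "coefficients": [
                {
                    "term": term,
                    "B": float(row["B"]),
                    "SE": float(row["SE"]),
                    "t": float(row["t"]),
                    "df": float(row["df"]),
                    "p": float(row["p"]),
                }
                for term, row in self.terms.iterrows()
            ],
            "log_likelihood_reml": self.loglik_reml,
            "log_likelihood_ml": self.loglik_ml,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "residual_var": self.residual_var,
            "intercept_var": self.intercept_var,
        }


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p}


def build_cohort_table(results) -> CohortTable:
    """One tidy row per trial from labelled OFSCA results.

    Degenerate (isotropy-flagged) trials carry no delta-theta and are
    excluded with a logged count.  Every result must be labelled with
    participant, vision and phase; factor levels are validated against the
    protocol's level sets.
    """
    rows = []
    n_degenerate = 0
    for res in results:
        meta = res.meta
        missing = [k for k in ("participant", "vision", "phase") if k not in meta]
        if missing:
            raise ValueError(f"result lacks metadata labels: {missing}")
        if res.degenerate:
            n_degenerate += 1
            continue
        rows.append(
            {
                "participant": meta["participant"],
                "vision": meta["vision"],
                "phase": meta["phase"],
                "delta_theta": res.delta_theta_deg,
                "sd_h": res.sd_h,
                "h1": res.h1,
                "h2": res.h2,
            }
        )
    if n_degenerate:
        logger.warning("excluded %d degenerate (isotropic) trial(s)", n_degenerate)
    table = pd.DataFrame(rows)
    _validate_table(table)
    return table


def _validate_table(
    table: pd.DataFrame, numeric: tuple[str, ...] = ("delta_theta", "sd_h", "h1", "h2")
) -> None:
    missing = [
        c for c in ("participant", "vision", "phase", *numeric) if c not in table.columns
    ]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    bad_vision = set(table["vision"]) - set(VISION_LEVELS)
    if bad_vision:
        raise ValueError(f"unknown vision level(s) {sorted(bad_vision)}; expected {VISION_LEVELS}")
    bad_phase = set(table["phase"]) - set(PHASE_LEVELS)
    if bad_phase:
        raise ValueError(f"unknown phase level(s) {sorted(bad_phase)}; expected {PHASE_LEVELS}")
    for col in numeric:
        if not np.all(np.isfinite(table[col].to_numpy(float))):
            raise ValueError(f"non-finite values in column {col!r}")


def _design_matrix(table: pd.DataFrame, formula_id: str) -> pd.DataFrame:
    """Treatment-coded fixed-effect design; baselines EyesOpen and Before."""
    numeric = ("delta_theta", "sd_h", "h1", "h2") if formula_id == "model2" else ("delta_theta",)
    _validate_table(table, numeric=numeric)
    x = pd.DataFrame(index=table.index)
    x["Intercept"] = 1.0
    x["Vision[EyesClosed]"] = (table["vision"] == "EyesClosed").astype(float)
    x["Phase[HeadRotation]"] = (table["phase"] == "HeadRotation").astype(float)
    x["Phase[After]"] = (table["phase"] == "After").astype(float)
    if formula_id == "model2":
        x["SD_H"] = table["sd_h"].to_numpy(float)
        x["H1"] = table["h1"].to_numpy(float)
        x["H2"] = table["h2"].to_numpy(float)
    elif formula_id == "model1_interaction":
        x["Vision[EyesClosed]:Phase[HeadRotation]"] = (
            x["Vision[EyesClosed]"] * x["Phase[HeadRotation]"]
        )
        x["Vision[EyesClosed]:Phase[After]"] = (
            x["Vision[EyesClosed]"] * x["Phase[After]"]
        )
    elif formula_id != "model1":
        raise ValueError(f"unknown formula_id {formula_id!r}")
    return x


# ---------------------------------------------------------------------------
# closed-form random-intercept (RE)ML machinery


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    _, inverse = np.unique(groups, return_inverse=True)
    return [np.flatnonzero(inverse == g) for g in range(inverse.max() + 1)]


def _gls_pieces(lam: float, y, X, idx):
    """GLS sufficient statistics under V* = I + lam * J per group.

    Woodbury: V*_g^-1 = I - lam/(1 + n_g lam) J.  Returns X'V*^-1X,
    X'V*^-1y, the GLS residual sum of squares r'V*^-1r and sum log|V*_g|.
    """
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for rows in idx:
        n_g = rows.size
        Xg, yg = X[rows], y[rows]
        w = lam / (1.0 + n_g * lam)
        sx, sy = Xg.sum(axis=0), yg.sum()
        xtvx += Xg.T @ Xg - w * np.outer(sx, sx)
        xtvy += Xg.T @ yg - w * sx * sy
        ytvy += yg @ yg - w * sy * sy
        logdet += np.log1p(n_g * lam)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = float(ytvy - beta @ xtvy)
    return xtvx, beta, rss, logdet


def _profiled_loglik(lam: float, y, X, idx, reml: bool) -> float:
    """Profile log-likelihood over beta and sigma^2 at variance ratio lam.

    Constants follow the lme4 conventions so the values are directly
    comparable with ``logLik(lmer(...))``.
    """
    n, p = X.shape
    xtvx, _, rss, logdet = _gls_pieces(lam, y, X, idx)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        _, logdet_x = np.linalg.slogdet(xtvx / sigma2)
        return -0.5 * (
            dof * np.log(2.0 * np.pi)
            + n * np.log(sigma2)
            + logdet
            + logdet_x
            + dof
        )
    sigma2 = rss / n
    return -0.5 * (n * np.log(2.0 * np.pi) + n * np.log(sigma2) + logdet + n)


def _fit_random_intercept(y, X, idx, reml: bool):
    """Exact profiled (RE)ML fit: 1-D Brent search on log variance ratio."""
    def negll(u):
        return -_profiled_loglik(np.exp(u), y, X, idx, reml)

    res = optimize.minimize_scalar(negll, bounds=(-20.0, 8.0), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    # compare against the tau^2 = 0 boundary (plain GLS = OLS)
    if -_profiled_loglik(0.0, y, X, idx, reml) < res.fun:
        lam = 0.0
    n, p = X.shape
    xtvx, beta, rss, _ = _gls_pieces(lam, y, X, idx)
    sigma2 = rss / (n - p) if reml else rss / n
    tau2 = lam * sigma2
    cov_beta = np.linalg.inv(xtvx) * sigma2
    loglik = _profiled_loglik(lam, y, X, idx, reml)
    return beta, cov_beta, sigma2, tau2, loglik


def _reml_quantities(theta, y, X, idx):
    """Profile REML log-likelihood and GLS pieces at (sigma2, tau2).

    For the random-intercept model V_g = sigma2 I + tau2 J, so
    V_g^-1 = (I - tau2/(sigma2 + n_g tau2) J) / sigma2 via Woodbury.
    """
    sigma2, tau2 = theta
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for rows in idx:
        n_g = rows.size
        Xg, yg = X[rows], y[rows]
        denom = sigma2 + n_g * tau2
        w = tau2 / denom
        sx, sy = Xg.sum(axis=0), yg.sum()
        xtvx += (Xg.T @ Xg - w * np.outer(sx, sx)) / sigma2
        xtvy += (Xg.T @ yg - w * sx * sy) / sigma2
        ytvy += (yg @ yg - w * sy * sy) / sigma2
        logdet += (n_g - 1) * np.log(sigma2) + np.log(denom)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - 2.0 * beta @ xtvy + beta @ xtvx @ beta
    sign, logdet_x = np.linalg.slogdet(xtvx)
    loglik = -0.5 * (logdet + logdet_x + rss)
    return loglik, xtvx, beta


def _satterthwaite_df(y, X, groups, sigma2, tau2):
    """Satterthwaite denominator df per fixed-effect coefficient.

    df_j = 2 g_j^2 / (grad_j' A grad_j), where g_j(theta) = [(X'V^-1 X)^-1]_jj
    and A is the asymptotic covariance of the variance parameters (inverse of
    the negative numerical Hessian of the REML log-likelihood).
    """
    idx = _group_indices(groups)
    theta = np.array([max(sigma2, 1e-10), max(tau2, 1e-10)], dtype=float)

    def cjj(th):
        _, xtvx, _ = _reml_quantities(th, y, X, idx)
        return np.diag(np.linalg.inv(xtvx))

    def loglik(th):
        return _reml_quantities(th, y, X, idx)[0]

    h = 1e-4 * np.maximum(theta, 1e-4)
    grad = np.empty((2, X.shape[1]))
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        grad[i] = (cjj(theta + e) - cjj(theta - e)) / (2.0 * h[i])

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei, ej = np.zeros(2), np.zeros(2)
            ei[i], ej[j] = h[i], h[j]
            hess[i, j] = (
                loglik(theta + ei + ej)
                - loglik(theta + ei - ej)
                - loglik(theta - ei + ej)
                + loglik(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        a = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        a = np.linalg.pinv(-hess)

    g = cjj(theta)
    df = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        gj = grad[:, j]
        denom = gj @ a @ gj
        df[j] = 2.0 * g[j] ** 2 / denom if denom > 0 else np.inf
    n, p = X.shape
    return np.clip(df, 1.0, 1e7), min(1e7, float(n - p))


def _fit(table: pd.DataFrame, formula_id: str) -> MixedModelFit:
    X = _design_matrix(table, formula_id)
    y = table["delta_theta"].to_numpy(float)
    groups = table["participant"].to_numpy()
    if np.unique(groups).size < 2:
        raise ValueError("need at least 2 participants for a random intercept")
    for col in ("vision", "phase"):
        if table[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels present")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]})"
        )

    xa = X.to_numpy()
    idx = _group_indices(groups)
    b, cov_beta, sigma2, tau2, ll_reml = _fit_random_intercept(y, xa, idx, reml=True)
    *_, ll_ml = _fit_random_intercept(y, xa, idx, reml=False)

    se = np.sqrt(np.diag(cov_beta))
    t = b / se
    df, df_fallback = _satterthwaite_df(y, xa, groups, sigma2, tau2)
    df = np.where(np.isfinite(df), df, df_fallback)
    p = 2.0 * sps.t.sf(np.abs(t), df)

    terms = pd.DataFrame(
        {"B": b, "SE": se, "t": t, "df": df, "p": p}, index=list(X.columns)
    )
    return MixedModelFit(
        formula_id=formula_id,
        terms=terms,
        loglik_reml=float(ll_reml),
        loglik_ml=float(ll_ml),
        n_obs=int(len(y)),
        n_groups=int(np.unique(groups).size),
        residual_var=sigma2,
        intercept_var=tau2,
    )


def fit_model1(table: CohortTable) -> MixedModelFit:
    """REML fit of delta_theta ~ Vision + Phase + (1 | participant)."""
    return _fit(table, "model1")


def fit_model2(table: CohortTable) -> MixedModelFit:
    """As model1 plus the continuous covariates SD_H, H1 and H2."""
    return _fit(table, "model2")


def fit_interaction_model(table: CohortTable) -> MixedModelFit:
    """Model1 plus the Vision x Phase interaction (for nested comparison)."""
    return _fit(table, "model1_interaction")


def likelihood_ratio_test(fit_small: MixedModelFit, fit_big: MixedModelFit) -> LrtResult:
    """Chi-squared LRT of nested fixed-effect structures on ML likelihoods."""
    small, big = set(fit_small.fixed_terms), set(fit_big.fixed_terms)
    if not small <= big:
        raise ValueError(
            "models are not nested: "
            f"{sorted(small - big)} only in the smaller model"
        )
    if fit_small.n_obs != fit_big.n_obs:
        raise ValueError("models were fitted on different numbers of observations")
    df = fit_big.n_fixed - fit_small.n_fixed
    chi2 = max(0.0, 2.0 * (fit_big.loglik_ml - fit_small.loglik_ml))
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LrtResult(chi2=chi2, df=df, p=p)
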