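"""Site-level statistics linking clonality to reproduction and connectivity.

Genotypic richness R is a proportion-like response, so its relationship to
seed density and propagule inflow is modelled by beta regression with a
logit link: R_i ~ Beta(mu_i * phi, (1 - mu_i) * phi) with
logit(mu_i) = x_i' beta and constant precision phi, fitted by maximum
likelihood. Goodness of fit uses the conventional pseudo-R²: the squared
Pearson correlation between the linear predictor and logit(y). Model
selection fits every predictor subset and ranks by AICc; collinear
predictors are screened out greedily beforehand.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "BetaRegFit",
    "pearson",
    "beta_regression",
    "pseudo_r2",
    "aicc",
    "all_subsets_select",
    "collinearity_screen",
    "squeeze_unit_interval",
]


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-tailed p (t-test, df = n - 2); NaN pairs dropped."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = _sps.pearsonr(x, y)
    return float(r), float(p)


def squeeze_unit_interval(y, n: int | None = None) -> np.ndarray:
    """Smithson-Verkuilen squeeze ``(y (n-1) + 0.5) / n`` pulling 0/1 into (0,1)."""
    y = np.asarray(y, float)
    n = n or len(y)
    return (y * (n - 1) + 0.5) / n


@dataclass
class BetaRegFit:
    """Logit-link beta regression fit (constant precision)."""

    predictors: list
    coef: pd.Series  # logit-scale mean coefficients incl. Intercept
    se: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    phi: float
    loglik: float
    nobs: int
    aic: float
    aicc: float
    pseudo_r2: float
    fitted: np.ndarray  # fitted means mu
    linear_predictor: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.coef) + 1  # + precision

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"estimate": self.coef, "se": self.se, "z": self.z_values, "p": self.p_values}
        )
        return (
            f"Beta regression (logit link), n={self.nobs}\n"
            f"{tab.to_string(float_format=lambda v: f'{v:.4f}')}\n"
            f"phi={self.phi:.3f}  logLik={self.loglik:.3f}  "
            f"AICc={self.aicc:.2f}  pseudo-R2={self.pseudo_r2:.3f}"
        )


def _design(predictors) -> tuple[np.ndarray, list]:
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(float)
    else:
        X = np.asarray(predictors, float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    return np.column_stack([np.ones(len(X)), X]), ["Intercept"] + names


def beta_regression(y, predictors, squeeze: bool = False) -> BetaRegFit:
    """Maximum-likelihood beta regression of y on predictors (logit link).

    ``y`` must lie strictly in (0, 1); set ``squeeze`` to apply the
    Smithson-Verkuilen boundary adjustment first. An intercept is always
    included; pass a DataFrame to keep predictor names.
    """
    from statsmodels.othermod.betareg import BetaModel

    y = np.asarray(y, float)
    if squeeze:
        y = squeeze_unit_interval(y)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("response must be strictly inside (0, 1); see squeeze")
    X, names = _design(predictors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BetaModel(y, X)
        res = model.fit(disp=False)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("beta regression failed to converge")
    mean_params = res.params[:-1]
    prec_param = res.params[-1]
    phi = float(model.link_precision.inverse(np.atleast_1d(prec_param))[0])
    eta = X @ mean_params
    mu = 1.0 / (1.0 + np.exp(-eta))
    r2 = pseudo_r2(eta, y)
    k = len(res.params)
    n = len(y)
    aic_val = -2.0 * res.llf + 2 * k
    idx = pd.Index(names)
    return BetaRegFit(
        predictors=names[1:],
        coef=pd.Series(mean_params, index=idx),
        se=pd.Series(res.bse[:-1], index=idx),
        z_values=pd.Series(res.tvalues[:-1], index=idx),
        p_values=pd.Series(res.pvalues[:-1], index=idx),
        phi=phi,
        loglik=float(res.llf),
        nobs=n,
        aic=float(aic_val),
        aicc=aicc(float(res.llf), k, n) if n - k - 1 > 0 else float("nan"),
        pseudo_r2=r2,
        fitted=mu,
        linear_predictor=eta,
    )


def pseudo_r2(linear_predictor, y) -> float:
    """Squared Pearson correlation of the linear predictor with logit(y)."""
    y = np.asarray(y, float)
    eta = np.asarray(linear_predictor, float)
    lt = np.log(y / (1.0 - y))
    if np.std(eta) == 0 or np.std(lt) == 0:
        return 0.0
    return float(np.corrcoef(eta, lt)[0, 1] ** 2)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n <= k + 1")
    return -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def all_subsets_select(
    data: pd.DataFrame,
    response: str,
    candidates: list,
    squeeze: bool = False,
) -> pd.DataFrame:
    """Fit every subset of candidate predictors; rank by AICc.

    Returns a table with one row per model (inclusion flags per candidate),
    logLik, k, AICc, delta AICc and Akaike weights, best first. Subsets with
    too few observations for AICc are skipped with a warning.
    """
    if len(candidates) > 10:
        raise ValueError("at most 10 candidate predictors")
    df = data.dropna(subset=[response] + list(candidates))
    y = df[response].to_numpy(float)
    rows = []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            k = len(subset) + 2  # intercept + precision
            if len(y) - k - 1 <= 0:
                warnings.warn(f"subset {subset}: too few observations, skipped")
                continue
            X = df[list(subset)] if subset else pd.DataFrame(index=df.index)
            try:
                fit = beta_regression(y, X, squeeze=squeeze)
            except (RuntimeError, ValueError) as exc:  # pragma: no cover
                warnings.warn(f"subset {subset} failed: {exc}")
                continue
            row = {c: c in subset for c in candidates}
            row.update(
                k=k, loglik=fit.loglik, aicc=fit.aicc, pseudo_r2=fit.pseudo_r2
            )
            rows.append(row)
    tab = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    w = np.exp(-0.5 * tab["delta_aicc"])
    tab["weight"] = w / w.sum()
    return tab


def collinearity_screen(
    predictors: pd.DataFrame, r_threshold: float = 0.7
) -> tuple[list, list]:
    """Greedy collinearity filter on pairwise |r|.

    While any pair exceeds the threshold, the member of the worst pair with
    the larger mean |r| to the remaining predictors is dropped. Returns the
    retained names and a log of exclusions.
    """
    if predictors.shape[1] < 2:
        raise ValueError("need at least two predictors")
    kept = list(predictors.columns)
    log = []
    while True:
        if len(kept) < 2:
            break
        corr = predictors[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        r = corr.loc[worst]
        if r < r_threshold:
            break
        a, b = worst
        mean_r = corr.mean()
        drop = a if mean_r[a] >= mean_r[b] else b
        keepmate = b if drop == a else a
        log.append(
            {"dropped": drop, "collinear_with": keepmate, "r": float(r)}
        )
        kept.remove(drop)
    return kept, log
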