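"""Phylogenetic generalized least squares with ML Pagel's lambda.

The residual covariance is V = sigma^2 C(lambda), where C is the Brownian
tree covariance with off-diagonals multiplied by lambda.  lambda is
profiled out by bounded scalar maximization of the concentrated ML
log-likelihood on [0, 1] with explicit endpoint checks (lambda-hat often
sits at 0 or 1); coefficient tests are two-sided t with n - p degrees of
freedom and an unbiased residual-variance estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .trees import Tree, phylo_vcv, prune_to_tips, tip_labels, transform_vcv

__all__ = ["PGLSFit", "fit_pgls", "fit_interaction_and_splits", "tidy_fits"]


@dataclass
class PGLSFit:
    """One fitted lambda-PGLS regression."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lam: float
    loglik: float
    n: int
    df_resid: int
    sigma2: float  # unbiased residual variance on the C(lambda) scale
    lambda_method: str  # "ML" or "fixed"
    model_id: str = "pgls"
    residuals: pd.Series = field(repr=False, default=None)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "lower": ci["lower"],
                "upper": ci["upper"],
                "lambda": self.lam,
                "model": self.model_id,
            }
        )


def _gls_profile(y: np.ndarray, X: np.ndarray, C0: np.ndarray, lam: float):
    """Concentrated ML pieces at a given lambda.

    Returns (loglik, beta, XtVinvX_inv, rss_gls) with V0 = C(lambda)
    unscaled; sigma^2 is concentrated out as rss/n.
    """
    n, p = X.shape
    V = C0 * lam
    np.fill_diagonal(V, np.diag(C0))
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance is not positive definite") from exc
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    sigma2_ml = rss / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
    return ll, beta, np.linalg.inv(XtViX), rss, r


def fit_pgls(
    response: pd.Series,
    design: pd.DataFrame,
    tree: Tree,
    lam: str | float = "ML",
    add_intercept: bool = True,
    model_id: str = "pgls",
) -> PGLSFit:
    """Fit a lambda-PGLS regression of ``response`` on ``design``.

    Rows are aligned to tree tips by label (the tree is pruned to the
    data if it carries extra tips).  ``lam`` is "ML" for profile-ML
    estimation on [0, 1], or a fixed value.
    """
    y = pd.Series(response).astype(float)
    X = pd.DataFrame(design).astype(float)
    if not y.index.equals(X.index):
        X = X.loc[y.index]
    labels = list(y.index)
    tree_labels = set(tip_labels(tree))
    if set(labels) - tree_labels:
        raise KeyError(
            f"species not in tree: {sorted(set(labels) - tree_labels)[:5]}"
        )
    if tree_labels - set(labels):
        tree = prune_to_tips(tree, labels)
    if add_intercept and "intercept" not in X.columns:
        X.insert(0, "intercept", 1.0)
    Xv = X.to_numpy()
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")
    C0 = phylo_vcv(tree).reindex(labels)
    d = np.diag(C0)
    if d.max() - d.min() > 1e-6 * max(d.max(), 1.0):
        # diagonal-preserving lambda transform is undefined otherwise
        raise ValueError("lambda-PGLS requires an ultrametric tree")
    yv = y.to_numpy()
    n, p = Xv.shape
    if lam == "ML":
        obj = lambda l: -_gls_profile(yv, Xv, C0, l)[0]
        res = minimize_scalar(obj, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        candidates = [float(res.x), 0.0, 1.0]
        lls = [-obj(l) for l in candidates]
        best = int(np.argmax(lls))
        # prefer the interior optimum when an endpoint ties within 1e-8
        if best != 0 and lls[best] - lls[0] < 1e-8:
            best = 0
        lam_hat = candidates[best]
        method = "ML"
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        method = "fixed"
    ll, beta, XtViX_inv, rss, resid = _gls_profile(yv, Xv, C0, lam_hat)
    df_resid = n - p
    sigma2 = rss / df_resid
    bse = np.sqrt(sigma2 * np.diag(XtViX_inv))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    cols = list(X.columns)
    return PGLSFit(
        params=pd.Series(beta, index=cols),
        bse=pd.Series(bse, index=cols),
        tvalues=pd.Series(tvals, index=cols),
        pvalues=pd.Series(pvals, index=cols),
        lam=lam_hat,
        loglik=float(ll),
        n=n,
        df_resid=df_resid,
        sigma2=float(sigma2),
        lambda_method=method,
        model_id=model_id,
        residuals=pd.Series(resid, index=labels),
    )


def fit_interaction_and_splits(
    frame: pd.DataFrame,
    tree: Tree,
    response: str,
    predictors: list[str],
    setting_col: str = "island",
    interact_with: list[str] | None = None,
    lam: str | float = "ML",
) -> dict[str, PGLSFit | None]:
    """Full model with setting x predictor interactions, plus island-only
    and continental-only refits on pruned trees.

    ``frame`` is a prepared model frame whose ``setting_col`` is a 0/1
    island indicator.  A split whose class holds fewer than p + 2 species
    is skipped with a warning and reported as None.
    """
    if interact_with is None:
        interact_with = list(predictors)
    flag = frame[setting_col].astype(float)
    if not set(np.unique(flag)) <= {0.0, 1.0}:
        raise ValueError(f"{setting_col!r} must be a 0/1 indicator")
    X = frame[predictors].copy()
    X[setting_col] = flag
    for pred in interact_with:
        X[f"{setting_col}:{pred}"] = flag * frame[pred]
    fits: dict[str, PGLSFit | None] = {}
    fits["full"] = fit_pgls(frame[response], X, tree, lam=lam, model_id="full")
    for name, mask in (("island", flag == 1.0), ("continental", flag == 0.0)):
        sub = frame.loc[mask]
        if len(sub) < len(predictors) + 3:
            warnings.warn(
                f"{name} split has too few species ({len(sub)}); skipped"
            )
            fits[name] = None
            continue
        subtree = prune_to_tips(tree, list(sub.index))
        fits[name] = fit_pgls(
            sub[response], sub[predictors], subtree, lam=lam, model_id=name
        )
    return fits


def tidy_fits(fits: dict[str, PGLSFit | None]) -> pd.DataFrame:
    """Stack fits into a tidy term/estimate/se/t/p/lambda/model table."""
    rows = []
    for name, fit in fits.items():
        if fit is None:
            continue
        frame = fit.summary_frame().reset_index(names="term")
        frame["model"] = name
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)
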