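"""Logistic-regression ranking of genes on network-centrality features.

A binary gene category (by default: radiation-induced membership) is
regressed on standardized centrality features — subgraph centrality,
closeness, total degree, PageRank, and eigenvector centrality — by
maximum likelihood (iteratively reweighted least squares).  Genes are then
ranked by their fitted log-odds; the model reports per-coefficient Wald
p-values and odds ratios.  Quasi-separation, common on small star-like
subnetworks, triggers a fallback to a lightly L2-regularized fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneCatalog
from .subnetworks import Subnetwork

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "subgraph_centrality",
    "closeness",
    "degree_total",
    "pagerank",
    "eigenvector",
]

SEPARATION_RIDGE = 1e-4
_COEF_BOUND = 30.0  # |beta| beyond this on standardized features => separation


class SeparationError(RuntimeError):
    pass


@dataclass
class FeatureTable:
    """Standardized feature matrix plus binary labels, one row per gene."""

    X: pd.DataFrame
    y: pd.Series
    dropped_features: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.X.index)


@dataclass
class LogisticModel:
    coefficients: pd.Series  # includes "intercept"
    std_errors: pd.Series
    p_values: pd.Series
    odds_ratios: pd.Series
    converged: bool
    n_iter: int
    ridge: float = 0.0
    covariance: pd.DataFrame | None = None

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.coefficients.index if c != "intercept"]


def build_features(
    subnet: Subnetwork,
    measures: pd.DataFrame,
    catalog: GeneCatalog | None = None,
    label: str = "radiation",
    label_set: set[str] | None = None,
) -> FeatureTable:
    """Assemble the standardized design matrix and labels for one subnetwork.

    ``label="radiation"`` uses the catalog's radiation-induced annotation;
    ``label="set-membership"`` flags membership of ``label_set``.  Features
    with zero variance across the subnetwork's genes are dropped (warned).
    """
    genes = sorted(subnet.member_genes)
    missing = [g for g in genes if g not in measures.index]
    if missing:
        raise ValueError(
            f"measure table does not cover {len(missing)} subnetwork gene(s): "
            f"{missing[:5]}"
        )
    X = measures.loc[genes, FEATURE_COLUMNS].astype(float).copy()

    if label == "radiation":
        if catalog is None:
            raise ValueError("label='radiation' requires a gene catalog")
        y = pd.Series(
            [catalog.is_radiation_induced(g) for g in genes], index=genes
        )
    elif label == "set-membership":
        if label_set is None:
            raise ValueError("label='set-membership' requires label_set")
        members = {g.upper() for g in label_set}
        y = pd.Series([g in members for g in genes], index=genes)
    else:
        raise ValueError("label must be 'radiation' or 'set-membership'")
    if y.nunique() < 2:
        raise ValueError(
            "labels are all one class; choose a different label or subnetwork"
        )

    dropped = []
    for col in list(X.columns):
        sd = X[col].std(ddof=0)
        if sd == 0.0 or not np.isfinite(sd):
            logger.warning("dropping constant feature %r", col)
            dropped.append(col)
            X = X.drop(columns=col)
        else:
            X[col] = (X[col] - X[col].mean()) / sd
    if X.shape[1] == 0:
        raise ValueError("all features are constant on this subnetwork")
    return FeatureTable(X=X, y=y.astype(bool), dropped_features=dropped)


def _irls(
    X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    n, k = X.shape
    beta = np.zeros(k)
    penalty = ridge * np.eye(k)
    penalty[0, 0] = 0.0  # never penalize the intercept
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        # working response
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + penalty
        beta_new = np.linalg.solve(H, XtW @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > _COEF_BOUND and ridge == 0.0:
            raise SeparationError("coefficients diverging: quasi-separation")
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv((X.T * w) @ X + penalty)
    return beta, cov, converged, it


def fit_logistic(
    features: FeatureTable, max_iter: int = 100, tol: float = 1e-8
) -> LogisticModel:
    """Maximum-likelihood fit with Wald inference; ridge fallback on
    separation."""
    y = features.y.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to fit")
    Xmat = np.column_stack(
        [np.ones(len(features.X)), features.X.to_numpy(dtype=float)]
    )
    names = ["intercept", *features.X.columns]
    ridge = 0.0
    try:
        beta, cov, converged, n_iter = _irls(Xmat, y, 0.0, max_iter, tol)
    except (SeparationError, np.linalg.LinAlgError):
        logger.warning(
            "separation detected; refitting with L2 ridge %g", SEPARATION_RIDGE
        )
        ridge = SEPARATION_RIDGE
        beta, cov, converged, n_iter = _irls(
            Xmat, y, SEPARATION_RIDGE, max_iter, tol
        )
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last coefficients: {dict(zip(names, beta))})"
        )
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    return LogisticModel(
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        p_values=pd.Series(pvals, index=names),
        odds_ratios=pd.Series(np.exp(beta), index=names),
        converged=converged,
        n_iter=n_iter,
        ridge=ridge,
        covariance=pd.DataFrame(cov, index=names, columns=names),
    )


def predict_scores(model: LogisticModel, features: FeatureTable) -> pd.Series:
    X = features.X[model.feature_names].to_numpy(dtype=float)
    beta = model.coefficients
    scores = beta["intercept"] + X @ beta[model.feature_names].to_numpy()
    return pd.Series(scores, index=features.X.index, name="linear_score")


def rank_genes(
    model: LogisticModel,
    features: FeatureTable,
    by: str = "score",
    catalog: GeneCatalog | None = None,
    top: int | None = None,
) -> pd.DataFrame:
    """Rank genes by fitted log-odds (descending; ties by gene ID).

    ``by="score"``/``"odds"``/``"probability"`` are monotone transforms of
    each other and give the same ordering; ``by="pvalue"`` orders by the
    Wald p-value of each gene's linear score (ascending), which also sorts
    by |score| relative to its standard error.
    """
    scores = predict_scores(model, features)
    prob = 1.0 / (1.0 + np.exp(-scores))
    table = pd.DataFrame(
        {
            "gene": scores.index,
            "linear_score": scores.to_numpy(),
            "probability": prob.to_numpy(),
            "odds": np.exp(scores.to_numpy()),
            "label": features.y.reindex(scores.index).to_numpy(),
        }
    )
    if by in ("score", "odds", "probability"):
        table = table.sort_values(
            ["linear_score", "gene"], ascending=[False, True]
        )
    elif by == "pvalue":
        X = features.X[model.feature_names].to_numpy(dtype=float)
        Xfull = np.column_stack([np.ones(len(X)), X])
        # per-gene Wald test of the linear score against 0
        names = ["intercept", *model.feature_names]
        if model.covariance is not None:
            cov = model.covariance.loc[names, names].to_numpy()
        else:
            cov = np.diag(model.std_errors[names].to_numpy() ** 2)
        var = np.einsum("ij,jk,ik->i", Xfull, cov, Xfull)
        z = scores.to_numpy() / np.sqrt(np.clip(var, 1e-300, None))
        table["score_p_value"] = 2.0 * stats.norm.sf(np.abs(z))
        table = table.sort_values(["score_p_value", "gene"])
    else:
        raise ValueError("by must be one of score|odds|probability|pvalue")
    table["rank"] = np.arange(1, len(table) + 1)
    if catalog is not None:
        table["radiation_induced"] = [
            catalog.is_radiation_induced(g) for g in table["gene"]
        ]
    if top is not None:
        table = table.head(top)
    return table.reset_index(drop=True)
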