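"""Phylogenetic generalized least squares under Brownian motion.

PGLS regresses one species-level trait on another while accounting for the
non-independence of related species: the residual covariance is taken
proportional to the Brownian-motion phylogenetic variance-covariance matrix
C, whose (a, b) entry is the shared root-path length of tips a and b.  With
C = I (a star phylogeny) the fit reduces exactly to ordinary least squares.

The slope test is an F test in the C^-1 metric:
F = (RSS0 - RSS1) / (RSS1 / (n - 2)), where RSS1 is the residual sum of
squares of the intercept+slope GLS fit and RSS0 that of the intercept-only
GLS fit, referred to F(1, n - 2).  Estimates, F and p are invariant to
scaling C by any positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .tree import PhyloTree, vcv_matrix

__all__ = ["PGLS", "PGLSResults", "pgls_fit", "pgls_battery"]


class PGLS:
    """Phylogenetic regression model y ~ intercept + slope * x.

    ``response`` and ``predictor`` are mappings (or Series) keyed by species;
    species are matched to the tree's tips exactly and case-sensitively, and
    the model is fit on the intersection (species lacking either value are
    dropped, with the count recorded on the results).
    """

    def __init__(self, tree: PhyloTree, response, predictor,
                 response_name: str = "y", predictor_name: str = "x") -> None:
        y = pd.Series(response, dtype=float)
        x = pd.Series(predictor, dtype=float)
        common = [sp for sp in tree.tip_labels
                  if sp in y.index and sp in x.index
                  and np.isfinite(y[sp]) and np.isfinite(x[sp])]
        if len(common) < 3:
            raise ValueError(f"PGLS needs >= 3 matched species, got {len(common)}")
        self.n_dropped = tree.n_tips - len(common)
        sub = tree.prune_to(common) if self.n_dropped else tree
        C, labels = vcv_matrix(sub)
        order = [labels.index(sp) for sp in common]
        self.C = C[np.ix_(order, order)]
        self.species = common
        self.y = y[common].to_numpy()
        self.x = x[common].to_numpy()
        self.response_name = response_name
        self.predictor_name = predictor_name

    def fit(self) -> "PGLSResults":
        n = len(self.y)
        try:
            Lc = linalg.cholesky(self.C, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular phylogenetic covariance matrix (zero-length branches "
                "between tips?); jitter zero-length terminal branches"
            ) from exc
        # whiten: solve L z = v, then OLS in the whitened space
        yw = linalg.solve_triangular(Lc, self.y, lower=True)
        X = np.column_stack([np.ones(n), self.x])
        Xw = linalg.solve_triangular(Lc, X, lower=True)
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < 2:
            raise ValueError("design matrix is rank deficient (constant predictor)")
        resid = yw - Xw @ beta
        rss1 = float(resid @ resid)
        # intercept-only GLS fit for the F test
        x0w = Xw[:, [0]]
        b0 = float((x0w[:, 0] @ yw) / (x0w[:, 0] @ x0w[:, 0]))
        r0 = yw - x0w[:, 0] * b0
        rss0 = float(r0 @ r0)
        df_resid = n - 2
        sigma2 = rss1 / df_resid
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        bse = np.sqrt(np.diag(XtX_inv) * sigma2)
        eps = 1e-12 * max(float(yw @ yw), 1.0)  # roundoff floor for zero-RSS cases
        if rss0 <= eps:
            F = 0.0  # nothing to explain (constant response)
        elif rss1 <= eps:
            F = np.inf  # perfect fit of a non-constant response
        else:
            F = max(rss0 - rss1, 0.0) / (rss1 / df_resid)
        p = float(stats.f.sf(F, 1, df_resid)) if np.isfinite(F) else 0.0
        return PGLSResults(
            model=self, params=beta, bse=bse, sigma2=sigma2,
            fvalue=float(F), pvalue=p, nobs=n, rss=rss1, rss_null=rss0,
        )


@dataclass
class PGLSResults:
    """PGLS estimates: intercept/slope, their SEs, residual variance, F test."""

    model: PGLS
    params: np.ndarray   # [intercept, slope]
    bse: np.ndarray
    sigma2: float        # residual variance rate in the C^-1 metric
    fvalue: float
    pvalue: float
    nobs: int
    rss: float
    rss_null: float

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """t-based confidence intervals, rows = (intercept, slope)."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.nobs - 2)
        return np.column_stack([self.params - tcrit * self.bse,
                                self.params + tcrit * self.bse])

    def summary(self) -> str:
        m = self.model
        ci = self.conf_int()
        return "\n".join([
            f"PGLS (Brownian motion): {m.response_name} ~ {m.predictor_name}",
            f"  n = {self.nobs} species" +
            (f" ({m.n_dropped} dropped for missing data)" if m.n_dropped else ""),
            f"  intercept = {self.intercept:.4f} (SE {self.bse[0]:.4f})",
            f"  slope     = {self.slope:.4f} (SE {self.bse[1]:.4f}, "
            f"95% CI [{ci[1, 0]:.4f}, {ci[1, 1]:.4f}])",
            f"  F(1, {self.nobs - 2}) = {self.fvalue:.2f},  P = {self.pvalue:.4g}",
        ])


def pgls_fit(tree: PhyloTree, response, predictor, **names) -> PGLSResults:
    """Functional wrapper: ``PGLS(tree, response, predictor).fit()``."""
    return PGLS(tree, response, predictor, **names).fit()


def pgls_battery(tree: PhyloTree, traits: pd.DataFrame,
                 response: str = "stripes",
                 predictors: tuple[str, ...] = ("n_hosts", "max_size", "elongation",
                                                "anterior_index", "posterior_index"),
                 ) -> pd.DataFrame:
    """One simple PGLS of stripe number per predictor.

    ``traits`` must be indexed by species or carry a ``species`` column.
    Stripe number is treated as a numeric 0-3 response.  Returns a table with
    X, Y, n, slope, F, p per regression; no multiple-testing correction is
    applied (none is used in the source analyses — interpret p-values
    accordingly).
    """
    df = traits.set_index("species") if "species" in traits.columns else traits
    rows = []
    for pred in predictors:
        res = PGLS(tree, df[response], df[pred],
                   response_name=response, predictor_name=pred).fit()
        rows.append({"X": pred, "Y": response, "n": res.nobs,
                     "slope": res.slope, "F": res.fvalue, "p": res.pvalue})
    return pd.DataFrame(rows)
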