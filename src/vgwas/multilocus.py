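"""Multi-locus model selection: L1 path, significance-constrained penalty
choice, and an unpenalized joint refit for effect sizes.

The selection rule mirrors how a multi-marker architecture is pinned down
from single-locus scans: along a descending penalty grid, the chosen
penalty is the smallest one whose set of non-zero markers is non-empty and
consists solely of markers that already reached genome-wide significance in
the single-locus mean or variance scans.  The selected markers are then
refitted jointly without penalty to obtain effects in trait units with
normal-theory confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import lasso_path as _sk_lasso_path

from .data import GenotypeMatrix

__all__ = ["LassoPath", "LambdaSelection", "SelectedModel",
           "lasso_path", "select_lambda", "joint_refit"]


@dataclass
class LassoPath:
    """Coordinate-descent solutions along a descending penalty grid.

    ``coefficients`` are on the original (unstandardized) predictor scale,
    shape (n_penalties, n_markers).  The penalty uses the 1/(2n) residual
    sum of squares convention, so the all-zero penalty is
    λ_max = max|X̃ᵀ ỹ|/n on the standardized, centered data.
    """

    lambda_grid: np.ndarray
    coefficients: np.ndarray
    marker_ids: list[str]

    def __post_init__(self):
        if np.any(np.diff(self.lambda_grid) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")

    @property
    def nonzero_sets(self) -> list[frozenset]:
        return [frozenset(mid for mid, b in zip(self.marker_ids, row) if b != 0.0)
                for row in self.coefficients]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coefficients, columns=self.marker_ids)
        df.insert(0, "lambda", self.lambda_grid)
        return df


def lasso_path(y_resid, X, marker_ids: Sequence[str] | None = None,
               grid: np.ndarray | None = None, n_grid: int = 100,
               grid_ratio: float = 1e-4) -> LassoPath:
    """L1-penalized path of a linear model of ``y_resid`` on candidate markers.

    Columns are standardized to unit variance internally and the intercept
    is unpenalized (both y and X are centered); coefficients are returned on
    the original scale.  The default grid is ``n_grid`` log-spaced penalties
    from λ_max (all-zero model) down to λ_max·``grid_ratio``.  Grid entries
    of exactly 0 are solved by ordinary least squares.
    """
    y = np.asarray(y_resid, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite inputs")
    n, m = X.shape
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(m)]
    yc = y - y.mean()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe

    lam_max = np.max(np.abs(Xs.T @ yc)) / n
    if grid is None:
        grid = np.logspace(np.log10(lam_max), np.log10(lam_max * grid_ratio), n_grid)
    grid = np.asarray(grid, dtype=float)

    pos = grid[grid > 0]
    coefs = np.zeros((grid.size, m))
    if pos.size:
        # sklearn wants a descending alpha sequence
        order = np.argsort(-pos)
        _, path_coefs, _ = _sk_lasso_path(Xs, yc, alphas=pos[order])
        back = np.empty_like(path_coefs)
        back[:, np.arange(pos.size)[order]] = path_coefs
        coefs[grid > 0] = back.T
    if np.any(grid == 0):
        ols = np.linalg.lstsq(Xs, yc, rcond=None)[0]
        coefs[grid == 0] = ols
    coefs = coefs / sd_safe
    coefs[:, sd == 0] = 0.0
    return LassoPath(grid, coefs, list(marker_ids))


class LambdaSelection(NamedTuple):
    penalty: float | None
    markers: frozenset
    admissible: bool


def select_lambda(path: LassoPath, significant) -> LambdaSelection:
    """Smallest grid penalty whose non-zero set is non-empty and contained
    in the genome-wide significant marker set.

    Returns an inadmissible result (penalty None, empty set) when no grid
    point qualifies.  The rule is monotone: enlarging ``significant`` never
    yields a larger selected penalty.
    """
    significant = frozenset(significant)
    best = None
    for lam, nz in zip(path.lambda_grid, path.nonzero_sets):
        if nz and nz <= significant:
            if best is None or lam < best[0]:
                best = (float(lam), nz)
    if best is None:
        return LambdaSelection(None, frozenset(), False)
    return LambdaSelection(best[0], best[1], True)


@dataclass
class SelectedModel:
    """Unpenalized joint fit of the selected markers.

    Effects are in trait units (µg/g when fitted on raw accession means)
    with normal-theory 95% confidence intervals.
    """

    markers: list[str]
    effects: pd.Series
    conf_int: pd.DataFrame
    p_values: pd.Series
    residual_variance: float
    results: object  # statsmodels RegressionResults

    def summary(self) -> str:
        lines = ["Joint multi-locus fit (OLS)", "=" * 46,
                 f"{'marker':<10}{'effect':>9}{'95% CI':>22}{'p':>12}"]
        for mid in self.markers:
            lo, hi = self.conf_int.loc[mid]
            lines.append(f"{mid:<10}{self.effects[mid]:>9.3f}"
                         f"   ({lo:>7.3f}, {hi:>7.3f}){self.p_values[mid]:>12.3g}")
        lines.append(f"residual variance {self.residual_variance:.4f}")
        return "\n".join(lines)


def joint_refit(y, g: GenotypeMatrix, markers: Sequence[str]) -> SelectedModel:
    """Multiple regression of the phenotype on the selected markers.

    ``y`` is typically the raw accession means so effects come out in µg/g.
    Collinear marker pairs raise a ValueError naming the pair.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(g.accession_ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    ids = g.marker_ids
    cols = {}
    for mid in markers:
        if mid not in ids:
            raise ValueError(f"marker {mid!r} not in genotype matrix")
        cols[mid] = g.imputed()[:, ids.index(mid)]
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
        markers_l = list(markers)
        for a in range(len(markers_l)):
            for b in range(a + 1, len(markers_l)):
                pair = np.column_stack([np.ones(len(y)), X[:, [a, b]]])
                if np.linalg.matrix_rank(pair) < 3:
                    raise ValueError(
                        f"collinear markers: {markers_l[a]!r} and {markers_l[b]!r}")
        raise ValueError("selected markers are collinear with the intercept")
    exog = sm.add_constant(pd.DataFrame(cols))
    res = sm.OLS(y, exog).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lo", "hi"]
    return SelectedModel(
        markers=list(markers),
        effects=res.params.drop("const"),
        conf_int=ci.drop("const"),
        p_values=res.pvalues.drop("const"),
        residual_variance=float(np.mean(res.resid**2)),
        results=res,
    )
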