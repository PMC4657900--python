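"""Polygenic mixed model on accession means, fitted by REML.

The model is ``ȳ = μ·1 + b + e`` with ``b ~ N(0, σ_b² K)`` and
``e ~ N(0, σ_e² I)``.  The variance ratio is profiled on the
eigendecomposition of K, which makes each likelihood evaluation O(n).  The
intra-class correlation r = σ_b²/(σ_b²+σ_e²) measures the share of the
accession-mean variance explained by kinship (the upper bound of narrow-
sense heritability on means).  The fitted residuals ``e = ȳ − μ̂ − b̂`` are
the GRAMMAR residuals used as structure-corrected phenotypes by the scan
and multi-locus stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinship import KinshipMatrix

__all__ = ["PolygenicModel", "PolygenicResults", "grammar_residuals"]


class PolygenicModel:
    """REML polygenic model for accession means against a kinship matrix.

    Parameters
    ----------
    endog : array-like or pandas Series
        Accession mean phenotypes, aligned with ``kinship.accession_ids``
        (a Series is re-indexed to the kinship order).
    kinship : KinshipMatrix
    """

    def __init__(self, endog, kinship: KinshipMatrix):
        if isinstance(endog, pd.Series):
            endog = endog.reindex(kinship.accession_ids)
            if endog.isna().any():
                raise ValueError("phenotype missing for some kinship accessions")
            y = endog.to_numpy(dtype=float)
        else:
            y = np.asarray(endog, dtype=float)
        if y.shape != (kinship.n,):
            raise ValueError("endog length does not match kinship")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite phenotype values")
        self.endog = y
        self.kinship = kinship
        d, U = np.linalg.eigh(kinship.values)
        if d.min() < -1e-8:
            warnings.warn("kinship not positive semidefinite; "
                          "bending by flooring eigenvalues at 0", UserWarning)
        self._d = np.clip(d, 0.0, None)
        self._U = U

    # profile REML log-likelihood at variance ratio lam = sigma_b2/sigma_e2
    def _profile(self, lam: float):
        d, U = self._d, self._U
        y = self.endog
        n = y.shape[0]
        yt = U.T @ y
        xt = U.T @ np.ones(n)
        w = 1.0 / (lam * d + 1.0)
        sxx = np.sum(w * xt * xt)
        mu = np.sum(w * xt * yt) / sxx
        r = yt - mu * xt
        rss = np.sum(w * r * r)
        sigma_e2 = rss / (n - 1)
        ll = -0.5 * ((n - 1) * np.log(2 * np.pi * sigma_e2)
                     + np.sum(np.log(lam * d + 1.0)) + np.log(sxx) + (n - 1))
        return ll, mu, sigma_e2, r, w

    def fit(self, h_max: float = 1.0 - 1e-6) -> "PolygenicResults":
        """Maximize the restricted likelihood over h = σ_b²/(σ_b²+σ_e²)."""

        def neg(h):
            lam = h / (1.0 - h)
            return -self._profile(lam)[0]

        res = minimize_scalar(neg, bounds=(1e-9, h_max), method="bounded",
                              options={"xatol": 1e-8})
        h = float(res.x)
        # parsimony tie-break: with an uninformative kinship (e.g. K = I) the
        # likelihood is flat in h; prefer the boundary sigma_b2 = 0 solution
        if neg(1e-12) <= res.fun + 1e-7:
            h = 0.0
        lam = h / (1.0 - h)
        ll, mu, sigma_e2, r, w = self._profile(lam)
        if not np.isfinite(ll):
            raise RuntimeError("non-finite REML likelihood")
        sigma_b2 = lam * sigma_e2
        d, U = self._d, self._U
        blup = U @ (lam * d * w * r)
        resid = U @ (w * r)
        return PolygenicResults(
            model=self, mu=float(mu), sigma_b2=float(sigma_b2),
            sigma_e2=float(sigma_e2), blup=blup, resid=resid,
            llf=float(ll), converged=bool(res.success or h == 0.0))


@dataclass
class PolygenicResults:
    """REML estimates, BLUPs and GRAMMAR residuals from a PolygenicModel."""

    model: PolygenicModel
    mu: float
    sigma_b2: float
    sigma_e2: float
    blup: np.ndarray
    resid: np.ndarray
    llf: float
    converged: bool

    @property
    def intra_class_r(self) -> float:
        tot = self.sigma_b2 + self.sigma_e2
        return self.sigma_b2 / tot if tot > 0 else 0.0

    def vinv_apply(self, M: np.ndarray) -> np.ndarray:
        """Apply V^{-1} = (σ_b² K + σ_e² I)^{-1} to a vector or matrix."""
        U, d = self.model._U, self.model._d
        v = 1.0 / (self.sigma_b2 * d + self.sigma_e2)
        Mt = U.T @ M
        return U @ (v[..., None] * Mt if M.ndim == 2 else v * Mt)

    def grammar_residuals(self, gamma_scale: bool = False) -> np.ndarray:
        """Structure-corrected phenotype ``y − μ̂ − b̂``.

        With ``gamma_scale=True`` the residuals are divided by the mean
        diagonal of σ_e²·V⁻¹ (a per-panel GRAMMAR-gamma style correction of
        the test-statistic scale); the plain residual is the default.
        """
        if gamma_scale:
            U, d = self.model._U, self.model._d
            gamma = np.mean(self.sigma_e2 / (self.sigma_b2 * d + self.sigma_e2))
            return self.resid / gamma
        return self.resid

    def summary(self) -> str:
        lines = [
            "Polygenic mixed model (REML)",
            "=" * 34,
            f"n accessions       {len(self.model.endog):>10d}",
            f"mu                 {self.mu:>10.4f}",
            f"sigma_b^2          {self.sigma_b2:>10.4f}",
            f"sigma_e^2          {self.sigma_e2:>10.4f}",
            f"intra-class r      {self.intra_class_r:>10.4f}",
            f"REML log-lik       {self.llf:>10.3f}",
            f"converged          {str(self.converged):>10s}",
        ]
        return "\n".join(lines)


def grammar_residuals(fit: PolygenicResults, gamma_scale: bool = False) -> np.ndarray:
    """Module-level convenience wrapper around ``fit.grammar_residuals``."""
    if not fit.converged:
        raise ValueError("polygenic fit did not converge")
    return fit.grammar_residuals(gamma_scale=gamma_scale)
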