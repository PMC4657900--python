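"""Genome scans: mixed-model score test for means, SVLM for variances.

The mean scan is the score ("mmscore") test computed against the fitted
polygenic covariance V = σ_b²K + σ_e²I:

    T = (sᵀ V⁻¹ ỹ)² / (sᵀ V⁻¹ s),   ỹ = y − μ̂,

with s the centered genotype vector and p from the χ²₁ upper tail.

The variance scan is SVLM (squared residual value linear modeling): per
marker the phenotype is first adjusted for the marker's mean effect by
ordinary regression, then the squared residuals are regressed on the marker
again; the stage-2 slope tests for variance heterogeneity.  Both scans take
GRAMMAR residuals as the structure-corrected phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix
from .polygenic import PolygenicResults

__all__ = [
    "ScanResult",
    "gwa_mmscore",
    "vgwa_svlm",
    "bonferroni_threshold",
    "inflation_factor",
    "qq_data",
]


@dataclass
class ScanResult:
    """Per-marker scan statistics plus scan-level threshold and inflation.

    ``table`` has one row per tested marker: marker_id, chrom, pos, effect,
    se, stat, p_mean and/or p_var, flag (empty string when the marker was
    tested normally).  Flagged markers keep their row with p = NaN rather
    than being silently dropped.
    """

    table: pd.DataFrame
    kind: str
    threshold: float | None = None
    inflation: float | None = None

    @property
    def pvalues(self) -> np.ndarray:
        col = "p_var" if self.kind == "variance" else "p_mean"
        p = self.table[col].to_numpy(dtype=float)
        return p[~np.isnan(p)]

    def significant(self, threshold: float | None = None) -> list[str]:
        thr = self.threshold if threshold is None else threshold
        if thr is None:
            raise ValueError("no threshold set")
        col = "p_var" if self.kind == "variance" else "p_mean"
        m = self.table[col] < thr
        return self.table.loc[m.fillna(False), "marker_id"].tolist()

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _marker_frame(g: GenotypeMatrix) -> pd.DataFrame:
    return pd.DataFrame({
        "marker_id": [m.marker_id for m in g.markers],
        "chrom": [m.chromosome for m in g.markers],
        "pos": [m.position for m in g.markers],
    })


def gwa_mmscore(y, g: GenotypeMatrix, fit: PolygenicResults,
                alpha: float = 0.05) -> ScanResult:
    """Mixed-model score test of each marker's mean effect.

    ``y`` are the accession means aligned with ``g.accession_ids`` (a Series
    is re-indexed).  Monomorphic markers are flagged with p absent.
    """
    if not fit.converged:
        raise ValueError("polygenic fit did not converge")
    if isinstance(y, pd.Series):
        y = y.reindex(g.accession_ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    ytil = y - fit.mu
    X = g.imputed()
    S = X - X.mean(axis=0)
    poly = X.std(axis=0) > 0

    VinvS = fit.vinv_apply(S)
    num = VinvS.T @ ytil
    den = np.einsum("ij,ij->j", S, VinvS)
    with np.errstate(invalid="ignore", divide="ignore"):
        effect = num / den
        se = 1.0 / np.sqrt(den)
        stat = num**2 / den
    p = stats.chi2.sf(stat, df=1)
    df = _marker_frame(g)
    df["effect"] = np.where(poly, effect, np.nan)
    df["se"] = np.where(poly, se, np.nan)
    df["stat"] = np.where(poly, stat, np.nan)
    df["p_mean"] = np.where(poly, p, np.nan)
    df["flag"] = np.where(poly, "", "monomorphic")
    res = ScanResult(df, kind="mean",
                     threshold=bonferroni_threshold(alpha, int(poly.sum()) or 1))
    pv = res.pvalues
    if pv.size >= 100:
        res.inflation = inflation_factor(pv)
    return res


def vgwa_svlm(y_resid, g: GenotypeMatrix, alpha: float = 0.05,
              min_class: int = 2) -> ScanResult:
    """SVLM variance-heterogeneity scan on a structure-corrected phenotype.

    Stage 1 regresses the phenotype on the marker and keeps the residuals r;
    stage 2 regresses r² on the marker.  The stage-2 slope (reported as
    ``effect``; its sign gives the minor-allele variance direction) is
    tested with the large-sample normal slope test.  Markers with fewer
    than ``min_class`` accessions in either genotype class are flagged.
    """
    if isinstance(y_resid, pd.Series):
        y_resid = y_resid.reindex(g.accession_ids).to_numpy(dtype=float)
    y = np.asarray(y_resid, dtype=float)
    n = y.shape[0]
    X = g.imputed()
    Xc = X - X.mean(axis=0)
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    counts1 = np.nansum(g.calls == 1.0, axis=0)
    counts0 = np.nansum(g.calls == 0.0, axis=0)
    ok = (counts1 >= min_class) & (counts0 >= min_class) & (ssx > 0)

    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        b1 = (Xc.T @ yc) / ssx
    r = yc[:, None] - Xc * b1          # stage-1 residuals per marker
    d = r * r
    dc = d - d.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        b2 = np.einsum("ij,ij->j", Xc, dc) / ssx
        rss2 = np.einsum("ij,ij->j", dc, dc) - b2**2 * ssx
        s2 = rss2 / max(n - 2, 1)
        se = np.sqrt(s2 / ssx)
        z = b2 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    # constant phenotype: slope 0 and no evidence either way -> p = 1
    p = np.where((np.abs(b2) < 1e-300) & (se < 1e-150), 1.0, p)

    df = _marker_frame(g)
    df["effect"] = np.where(ok, b2, np.nan)
    df["se"] = np.where(ok, se, np.nan)
    df["stat"] = np.where(ok, z, np.nan)
    df["p_var"] = np.where(ok, p, np.nan)
    df["flag"] = np.where(ok, "", "insufficient_class_count")
    res = ScanResult(df, kind="variance",
                     threshold=bonferroni_threshold(alpha, int(ok.sum()) or 1))
    pv = res.pvalues
    if pv.size >= 100:
        res.inflation = inflation_factor(pv)
    return res


def bonferroni_threshold(alpha: float, n_markers: int) -> float:
    """Genome-wide significance threshold alpha / n_markers (exact rational)."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    return float(Fraction(str(alpha)) / n_markers)


def inflation_factor(pvalues, method: str = "regression") -> float:
    """Genomic inflation factor λ from a set of p-values.

    ``regression`` (default): observed χ²₁ quantiles regressed on expected
    quantiles through the origin.  ``median``: median observed statistic
    divided by the χ²₁ median.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 100:
        warnings.warn("fewer than 100 p-values: inflation estimate is unstable",
                      UserWarning)
    obs = np.sort(stats.chi2.isf(p, df=1))
    n = p.size
    exp = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=1)
    if method == "regression":
        return float(np.sum(exp * obs) / np.sum(exp * exp))
    if method == "median":
        return float(np.median(obs) / stats.chi2.ppf(0.5, df=1))
    raise ValueError(f"unknown method {method!r}")


def qq_data(pvalues) -> pd.DataFrame:
    """Expected vs observed −log10 p quantiles for a QQ plot.

    Expected quantiles are the uniform order statistics i/(n+1).
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values")
    n = p.size
    exp = np.arange(1, n + 1) / (n + 1)
    return pd.DataFrame({
        "expected": -np.log10(exp),
        "observed": -np.log10(p),
    })
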