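"""Heritability estimates and the two-model variance decomposition.

Broad-sense heritability H² comes from a one-way ANOVA on the replicate
measurements (method-of-moments variance components with the unbalanced-
design coefficient).  The narrow-sense side uses the polygenic mixed model:
the intra-class correlation r of accession means against the genomic
kinship brackets h² on the raw scale via r·H² ≤ h² ≤ r.

The two-model decomposition converts a fixed-marker fit into fractions of
the kinship-explained variance: with r1 the intra-class correlation of the
null polygenic model, r2 that of the model with markers X as fixed effects
and R² the fraction of accession-mean variance explained by X,

    r2_tot = r2 (1 − R²)
    fraction of h² explained by X     = (r1 − r2_tot) / r1
    fraction of X's variance additive = (r1 − r2_tot) / R²

Per-locus mean/variance contributions use the mixture decomposition of the
phenotypic variance into between-genotype-mean and within-genotype-variance
parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import PhenotypeTable
from .kinship import KinshipMatrix
from .polygenic import PolygenicModel

__all__ = [
    "HeritabilityDecomposition",
    "LocusContribution",
    "broad_sense_H2",
    "narrow_sense_lower",
    "variance_explained_R2",
    "decompose",
    "locus_contribution",
]


def broad_sense_H2(p: PhenotypeTable) -> float:
    """Broad-sense heritability from the within/between accession ANOVA.

    Method-of-moments components: with a accessions, N total replicates and
    n0 = (N − Σ n_i²/N)/(a−1), σ²_between = (MSB − MSW)/n0 (truncated at 0
    with a warning if negative) and H² = σ²_b/(σ²_b + σ²_w).
    """
    df = p.df
    counts = df.groupby("accession_id")["value"].count()
    if (counts >= 2).sum() < 2 or len(counts) < 2:
        raise ValueError("need >= 2 accessions with >= 2 replicates")
    a = len(counts)
    N = counts.sum()
    grand = df["value"].mean()
    means = df.groupby("accession_id")["value"].mean()
    ssb = float((counts * (means - grand) ** 2).sum())
    ssw = float(((df["value"] - df["accession_id"].map(means)) ** 2).sum())
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    n0 = (N - (counts**2).sum() / N) / (a - 1)
    sigma_b2 = (msb - msw) / n0
    if sigma_b2 < 0:
        warnings.warn("negative between-accession variance estimate truncated at 0",
                      UserWarning)
        sigma_b2 = 0.0
    return float(sigma_b2 / (sigma_b2 + msw)) if (sigma_b2 + msw) > 0 else 0.0


def narrow_sense_lower(y_means, K: KinshipMatrix, H2: float | None = None
                       ) -> tuple[float, str]:
    """Intra-class correlation r of accession means and the h² lower bound.

    Returns ``(r, note)``; when H² is supplied the note reports the bracket
    r·H² ≤ h² ≤ r with the lower bound r·H² as the conservative estimate.
    """
    fit = PolygenicModel(y_means, K).fit()
    r = fit.intra_class_r
    if H2 is None:
        note = f"r = {r:.3f}; h2 <= r (replicate noise in means not removed)"
    else:
        note = f"bound {r * H2:.3f} = r*H2 <= h2 <= r = {r:.3f}"
    return float(r), note


def variance_explained_R2(y_means, X, beta) -> float:
    """R² = 1 − var(ȳ − Xβ)/var(ȳ), population-variance (divisor n) form."""
    y = np.asarray(y_means, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[1] != beta.shape[0]:
        raise ValueError("dimension mismatch")
    vy = np.var(y)
    if vy == 0:
        raise ValueError("zero phenotype variance")
    return float(1.0 - np.var(y - X @ beta) / vy)


@dataclass
class HeritabilityDecomposition:
    """Variance-decomposition report (all quantities are fractions).

    Raw (unclipped) values are retained in ``raw``; reported fields are
    clipped to [0, 1] with a warning when an estimate strays outside.
    """

    H2: float
    r: float
    R2: float
    r1: float
    r2: float
    r2_tot: float
    fraction_h2_explained: float | None
    fraction_additive: float | None
    raw: dict | None = None

    def to_dict(self) -> dict:
        return {
            "H2": self.H2, "r": self.r, "h2_lower": self.r * self.H2,
            "R2": self.R2, "r1": self.r1, "r2": self.r2, "r2_tot": self.r2_tot,
            "fraction_h2": self.fraction_h2_explained,
            "fraction_additive": self.fraction_additive,
        }


def _clip01(name: str, v: float | None) -> float | None:
    if v is None:
        return None
    if v < 0.0 or v > 1.0:
        warnings.warn(f"{name} = {v:.3f} outside [0,1]; clipped for reporting",
                      UserWarning)
    return float(np.clip(v, 0.0, 1.0))


def decompose(r1: float, r2: float, R2: float,
              H2: float = np.nan, r: float = np.nan) -> HeritabilityDecomposition:
    """Two-model decomposition: r2_tot = r2(1−R²) and the explained fractions."""
    for name, v in (("r1", r1), ("r2", r2), ("R2", R2)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0,1]")
    r2_tot = r2 * (1.0 - R2)
    frac_h2 = (r1 - r2_tot) / r1 if r1 > 0 else None
    frac_add = (r1 - r2_tot) / R2 if R2 > 0 else None
    raw = {"r2_tot": r2_tot, "fraction_h2": frac_h2, "fraction_additive": frac_add}
    return HeritabilityDecomposition(
        H2=H2, r=r, R2=R2, r1=r1, r2=r2, r2_tot=r2_tot,
        fraction_h2_explained=_clip01("fraction_h2", frac_h2),
        fraction_additive=_clip01("fraction_additive", frac_add),
        raw=raw)


@dataclass
class LocusContribution:
    """Percent of phenotypic variance contributed by one marker via its
    genotype mean difference (``mean_pct``) and via its genotype variance
    difference (``var_pct``)."""

    mean_pct: float
    var_pct: float


def locus_contribution(y, snp) -> LocusContribution:
    """Mixture decomposition of the phenotypic variance at a binary marker.

    With class frequencies f0, f1, class means µ0, µ1 and class variances
    v0, v1 (population form): total = f0·v0 + f1·v1 + f0(µ0−µ̄)² + f1(µ1−µ̄)²;
    mean_pct is the between-mean share, var_pct = f1·max(v1−v0, 0)/total
    with the minor class taken as the (candidate) high-variance class.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(snp, dtype=float)
    mask = ~np.isnan(x)
    y, x = y[mask], x[mask]
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("snp must be binary 0/1")
    n1 = int((x == 1).sum())
    n0 = int((x == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both genotype classes must be populated")
    f1, f0 = n1 / (n0 + n1), n0 / (n0 + n1)
    mu0, mu1 = y[x == 0].mean(), y[x == 1].mean()
    v0, v1 = np.var(y[x == 0]), np.var(y[x == 1])
    mbar = f0 * mu0 + f1 * mu1
    between = f0 * (mu0 - mbar) ** 2 + f1 * (mu1 - mbar) ** 2
    total = f0 * v0 + f1 * v1 + between
    if total == 0:
        return LocusContribution(0.0, 0.0)
    if n1 <= n0:
        var_excess = f1 * max(v1 - v0, 0.0)
    else:
        var_excess = f0 * max(v0 - v1, 0.0)
    return LocusContribution(mean_pct=100.0 * between / total,
                             var_pct=100.0 * var_excess / total)
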