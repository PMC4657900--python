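"""Pairwise linkage disequilibrium for inbred panels, LD tables, r²-bounded
candidate regions, and genotype-matrix block sorting.

Inbred accessions are treated as haploids, so genotype co-occurrence counts
are haplotype counts and no phasing is needed.  Missing calls are handled
by pairwise-complete deletion.  The characteristic signature of a rare
allele nested within a commoner haplotype is D' = 1 with r² < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

__all__ = ["LdStats", "ld_pair", "ld_table", "region_in_ld", "block_sort",
           "region_to_bed"]


@dataclass(frozen=True)
class LdStats:
    """Two-locus LD summary on minor-allele haplotype counts."""

    D: float
    Dprime: float
    r2: float
    pA: float
    pB: float


def ld_pair(a, b) -> LdStats:
    """LD between two 0/1 genotype vectors (minor-allele coding).

    p11 = freq(minor, minor); D = p11 − pA·pB; D' = |D|/Dmax with the
    sign-appropriate Dmax; r² = D²/(pA(1−pA)pB(1−pB)).  Monomorphic input
    (after pairwise-complete deletion) raises ValueError.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if a.size < 2:
        raise ValueError("need >= 2 pairwise-complete observations")
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic input")
    p11 = np.mean(a * b)
    D = p11 - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LdStats(D=float(D), Dprime=float(dprime), r2=float(r2),
                   pA=float(pA), pB=float(pB))


def ld_table(g: GenotypeMatrix, markers) -> pd.DataFrame:
    """Square LD table with r² above and D' below the diagonal (diagonal 1).

    Cells whose pair cannot be computed (e.g. monomorphic after missing-data
    deletion) are left absent (NaN).
    """
    ids = g.marker_ids
    for m in markers:
        if m not in ids:
            raise ValueError(f"marker {m!r} not in genotype matrix")
    k = len(markers)
    out = pd.DataFrame(np.ones((k, k)), index=markers, columns=markers)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                s = ld_pair(g.column(markers[i]), g.column(markers[j]))
                out.iloc[i, j] = s.r2
                out.iloc[j, i] = s.Dprime
            except ValueError:
                out.iloc[i, j] = np.nan
                out.iloc[j, i] = np.nan
    return out


def region_in_ld(g: GenotypeMatrix, lead: str, r2_min: float = 0.4
                 ) -> tuple[tuple[str, int, int], list[str]]:
    """Candidate region bounded by the furthest markers with r² > r2_min.

    Only markers on the lead's chromosome are considered; the inequality is
    strict.  Returns ((chrom, start, end), member marker ids); when no
    other marker exceeds the bound the interval degenerates to the lead
    position.
    """
    ids = g.marker_ids
    if lead not in ids:
        raise ValueError(f"lead marker {lead!r} not in genotype matrix")
    lead_info = g.markers[ids.index(lead)]
    x = g.column(lead)
    members: list[tuple[int, str]] = [(lead_info.position, lead)]
    for m in g.markers:
        if m.marker_id == lead or m.chromosome != lead_info.chromosome:
            continue
        try:
            s = ld_pair(x, g.column(m.marker_id))
        except ValueError:
            continue
        if s.r2 > r2_min:
            members.append((m.position, m.marker_id))
    members.sort()
    start, end = members[0][0], members[-1][0]
    return (lead_info.chromosome, start, end), [mid for _, mid in members]


def region_to_bed(region: tuple[str, int, int]) -> str:
    """Render a 1-based inclusive interval as a BED line (0-based half-open)."""
    chrom, start, end = region
    return f"{chrom}\t{start - 1}\t{end}"


def block_sort(g: GenotypeMatrix, lead: str, phenotype=None) -> pd.DataFrame:
    """Partition accessions by the lead-marker genotype (block visualization).

    Returns a DataFrame (accession_id, genotype, cls) sorted so one genotype
    class precedes the other with stable within-class order; accessions with
    a missing lead call are listed last with cls ``"missing"``.  When a
    per-accession phenotype is supplied, the class with the larger
    phenotypic variance is labelled ``"hv"`` and the other ``"lv"``;
    otherwise classes are named by genotype.
    """
    x = g.column(lead)
    labels = {0.0: "g0", 1.0: "g1"}
    if phenotype is not None:
        y = (phenotype.reindex(g.accession_ids).to_numpy(dtype=float)
             if isinstance(phenotype, pd.Series) else np.asarray(phenotype, dtype=float))
        v = {}
        for cls in (0.0, 1.0):
            sel = (x == cls) & ~np.isnan(y)
            v[cls] = np.var(y[sel]) if sel.sum() >= 2 else -np.inf
        hv = 1.0 if v[1.0] >= v[0.0] else 0.0
        labels = {hv: "hv", 1.0 - hv: "lv"}
    rows = []
    for order_cls in (1.0, 0.0):
        for i, acc in enumerate(g.accession_ids):
            if x[i] == order_cls:
                rows.append((acc, int(order_cls), labels[order_cls]))
    for i, acc in enumerate(g.accession_ids):
        if np.isnan(x[i]):
            rows.append((acc, -1, "missing"))
    return pd.DataFrame(rows, columns=["accession_id", "genotype", "cls"])
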