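"""Kinship matrices for inbred accession panels (IBS and genomic flavors)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

__all__ = ["KinshipMatrix", "kinship"]

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """n x n accession similarity matrix.

    ``ibs``: fraction of non-missing markers with identical calls (diagonal 1).
    ``genomic``: centered, standardized cross-product of calls divided by the
    number of informative markers (a GRM on haploid-equivalent 0/1 calls).
    """

    accession_ids: list[str]
    values: np.ndarray
    flavor: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.accession_ids),) * 2:
            raise ValueError("kinship shape does not match accession count")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("kinship entries must be finite")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.accession_ids,
                     columns=self.accession_ids).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, flavor: str = "ibs") -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(a) for a in df.index], df.to_numpy(dtype=float), flavor)


def kinship(g: GenotypeMatrix, flavor: str = "ibs",
            exclude_chromosome: str | None = None,
            exclude_region: tuple[str, float, float] | None = None) -> KinshipMatrix:
    """Compute an IBS or genomic kinship matrix from 0/1 inbred calls.

    Monomorphic (zero-variance) markers contribute nothing to the genomic
    flavor and are skipped with a log entry.  Missing calls are handled
    pairwise-complete for IBS and mean-imputed for the genomic flavor.

    ``exclude_chromosome`` drops one chromosome (leave-one-chromosome-out);
    ``exclude_region=(chrom, start, end)`` drops one interval (positions
    inclusive).  On genome-scale marker panels a single locus carries
    negligible kinship weight, but on small marker sets a strong focal
    region would otherwise dominate the relatedness estimate (proximal
    contamination) and be absorbed into the polygenic term.
    """
    if exclude_chromosome is not None or exclude_region is not None:
        def drop(m):
            if exclude_chromosome is not None and m.chromosome == exclude_chromosome:
                return True
            if exclude_region is not None:
                c, lo, hi = exclude_region
                if m.chromosome == c and lo <= m.position <= hi:
                    return True
            return False
        keep = [m.marker_id for m in g.markers if not drop(m)]
        if not keep:
            raise ValueError("exclusion removed every marker")
        g = g.subset_markers(keep)
    if g.n_accessions < 2 or g.n_markers < 1:
        raise ValueError("need >= 2 accessions and >= 1 marker")
    X = g.calls
    if flavor == "ibs":
        obs = ~np.isnan(X)
        A1 = np.where(obs, X, 0.0)
        A0 = np.where(obs, 1.0 - X, 0.0)
        matches = A1 @ A1.T + A0 @ A0.T
        denom = obs.astype(float) @ obs.astype(float).T
        with np.errstate(invalid="ignore", divide="ignore"):
            K = np.where(denom > 0, matches / np.maximum(denom, 1), 0.0)
        np.fill_diagonal(K, 1.0)
        return KinshipMatrix(list(g.accession_ids), (K + K.T) / 2, "ibs")
    if flavor == "genomic":
        Xi = g.imputed()
        mean = Xi.mean(axis=0)
        sd = Xi.std(axis=0)
        keep = sd > 0
        n_skip = int((~keep).sum())
        if n_skip:
            logger.info("kinship(genomic): skipped %d zero-variance markers", n_skip)
        if keep.sum() == 0:
            raise ValueError("no polymorphic markers for genomic kinship")
        Z = (Xi[:, keep] - mean[keep]) / sd[keep]
        K = Z @ Z.T / keep.sum()
        return KinshipMatrix(list(g.accession_ids), K, "genomic")
    raise ValueError(f"unknown kinship flavor {flavor!r}")
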