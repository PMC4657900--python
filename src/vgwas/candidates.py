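"""Candidate-gene evaluation statistics.

qRT-PCR relative expression: per-sample ΔCT = CT_target − mean(CT_reference),
per-accession ΔΔCT against a reference accession, fold change 2^−ΔΔCT, and
Fisher combination of per-replicate p-values.

T-DNA insertion-line assays: experimental blocks (cultivation trays) are
quality-controlled by requiring the known low-trait control mutant to sit
significantly below wild type within the block (one-sided Wilcoxon
rank-sum); genotype values are then normalized against the wild-type block
mean and pooled across passing blocks for a two-sided Wilcoxon rank-sum
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionAssay",
    "TdnaBlockData",
    "fold_change_ddct",
    "fisher_combine",
    "block_qc",
    "tdna_test",
]

logger = logging.getLogger(__name__)

WILD_TYPE = "Col-0"
DEFAULT_CONTROL = "mot1-1"


class ExpressionAssay:
    """qRT-PCR cycle-threshold records.

    Wraps a DataFrame with columns accession_id, replicate, ct_target,
    ct_reference (the reference value is the mean CT of the reference gene
    for that sample run).  Records with a missing reference CT are skipped
    with a log entry.
    """

    def __init__(self, df: pd.DataFrame):
        need = {"accession_id", "replicate", "ct_target", "ct_reference"}
        if not need <= set(df.columns):
            raise ValueError(f"expression table needs columns {sorted(need)}")
        n0 = len(df)
        df = df.dropna(subset=["ct_target", "ct_reference"]).copy()
        if len(df) < n0:
            logger.info("ExpressionAssay: skipped %d records with missing CT", n0 - len(df))
        for col in ("ct_target", "ct_reference"):
            v = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(v) & (v > 0)):
                raise ValueError(f"{col} values must be finite and > 0")
        self.df = df.reset_index(drop=True)

    def delta_ct(self) -> pd.Series:
        """Per-record ΔCT = CT_target − CT_reference."""
        return self.df["ct_target"] - self.df["ct_reference"]


def fold_change_ddct(a: ExpressionAssay, reference_accession: str) -> pd.Series:
    """Per-accession expression fold change 2^−ΔΔCT versus a reference line.

    ΔΔCT_i = mean ΔCT of accession i − mean ΔCT of the reference accession.
    The reference accession's own fold is exactly 1.
    """
    d = a.df.assign(dct=a.delta_ct())
    means = d.groupby("accession_id")["dct"].mean()
    if reference_accession not in means.index:
        raise ValueError(f"reference accession {reference_accession!r} absent")
    ddct = means - means[reference_accession]
    fold = np.power(2.0, -ddct)
    fold.name = "fold_change"
    return fold


def fisher_combine(pvalues) -> float:
    """Fisher's combined probability: X² = −2Σln p on χ² with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any(p <= 0):
        raise ValueError("p = 0 cannot be combined; floor p-values upstream")
    if np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    x2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x2, df=2 * p.size))


@dataclass
class TdnaBlockData:
    """One experimental block (cultivation tray) of the T-DNA assay.

    ``genotypes`` maps genotype id (including the wild type and the control
    mutant) to its replicate trait values in µg/g.
    """

    block_id: str
    genotypes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.genotypes = {k: np.asarray(v, dtype=float)
                          for k, v in self.genotypes.items()}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["TdnaBlockData"]:
        """Build blocks from a long table with columns block, genotype, value."""
        out = []
        for bid, sub in df.groupby("block", sort=False):
            geno = {g: s["value"].to_numpy(dtype=float)
                    for g, s in sub.groupby("genotype", sort=False)}
            out.append(cls(str(bid), geno))
        return out


def _rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Wilcoxon rank-sum p: exact for combined n <= 25, normal approximation
    with tie correction otherwise."""
    method = "exact" if (len(x) + len(y) <= 25 and
                         len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alternative,
                                    method=method).pvalue)


def block_qc(blocks: Sequence[TdnaBlockData], control: str = DEFAULT_CONTROL,
             alpha: float = 0.05) -> pd.DataFrame:
    """Per-block control check: pass iff the control mutant is significantly
    below the wild type (one-sided Wilcoxon rank-sum, p < alpha).

    Blocks without the control are marked unevaluable.  Results from
    genotypes that only occur in failing blocks should be treated as
    discarded (see :func:`tdna_test`).
    """
    rows = []
    for blk in blocks:
        if control not in blk.genotypes or WILD_TYPE not in blk.genotypes:
            rows.append((blk.block_id, np.nan, False, "unevaluable"))
            continue
        p = _rank_sum_p(blk.genotypes[control], blk.genotypes[WILD_TYPE], "less")
        rows.append((blk.block_id, p, p < alpha, ""))
    return pd.DataFrame(rows, columns=["block_id", "control_p", "passed", "flag"])


def tdna_test(blocks: Sequence[TdnaBlockData], genotype: str,
              control: str = DEFAULT_CONTROL, alpha: float = 0.05
              ) -> tuple[float, float, str]:
    """Pooled block-normalized comparison of a T-DNA genotype to wild type.

    Each replicate value is divided by its block's wild-type mean; the
    normalized genotype values from QC-passing blocks are pooled and tested
    two-sided against the pooled normalized wild-type values.  Returns
    ``(ratio, p, flag)`` where ratio is the mean normalized genotype value;
    the flag is ``"unusable"`` when the genotype occurs only in failing
    blocks.
    """
    qc = block_qc(blocks, control=control, alpha=alpha).set_index("block_id")
    geno_vals, wt_vals = [], []
    seen = False
    for blk in blocks:
        if genotype not in blk.genotypes:
            continue
        seen = True
        if not bool(qc.loc[blk.block_id, "passed"]):
            continue
        wt_mean = blk.genotypes[WILD_TYPE].mean()
        geno_vals.append(blk.genotypes[genotype] / wt_mean)
        wt_vals.append(blk.genotypes[WILD_TYPE] / wt_mean)
    if not seen:
        raise ValueError(f"genotype {genotype!r} absent from every block")
    if not geno_vals:
        return np.nan, np.nan, "unusable"
    gv = np.concatenate(geno_vals)
    wv = np.concatenate(wt_vals)
    p = _rank_sum_p(gv, wv, "two-sided")
    return float(gv.mean()), p, ""
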