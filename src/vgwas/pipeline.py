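"""End-to-end analysis convenience layer.

Chains the stages the way the full study design intends them to be used:
QC'd genotypes -> kinship -> polygenic REML fit -> GRAMMAR residuals ->
mean (score test) and variance (SVLM) scans -> significance-constrained
multi-locus selection -> joint refit -> heritability decomposition.

The kinship used for structure correction excludes the focal candidate
region (leave-region-out).  On a genome-scale marker panel the focal locus
carries negligible kinship weight and this makes no difference; on
desk-scale marker sets it prevents the focal region from dominating the
relatedness matrix and swallowing the very signal being scanned for
(proximal contamination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import accession_means
from .heritability import broad_sense_H2
from .kinship import KinshipMatrix, kinship
from .multilocus import joint_refit, lasso_path, select_lambda
from .polygenic import PolygenicModel, PolygenicResults
from .scan import ScanResult, gwa_mmscore, vgwa_svlm
from .simulate import SimPopulation, BLOCK_CHROM

#: candidate interval around the molybdate-transporter region (chrom 2)
FOCAL_REGION = (BLOCK_CHROM, 10.8e6, 11.6e6)


@dataclass
class PopulationAnalysis:
    """Fitted structure model and scans for one population."""

    means: pd.Series
    K_scan: KinshipMatrix
    K_h2: KinshipMatrix
    polygenic: PolygenicResults
    residuals: np.ndarray
    mean_scan: ScanResult
    var_scan: ScanResult
    H2: float


def analyze_population(pop: SimPopulation,
                       focal_region: tuple = FOCAL_REGION) -> PopulationAnalysis:
    """Run the structure-correction and single-locus scan stages.

    IBS kinship drives the GRAMMAR residualization and score test (the scan
    stages); the genomic kinship drives the heritability estimates.
    """
    g = pop.genotypes
    means = accession_means(pop.phenotypes)["mean"]
    K_scan = kinship(g, "ibs", exclude_region=focal_region)
    K_h2 = kinship(g, "genomic", exclude_region=focal_region)
    fit = PolygenicModel(means, K_scan).fit()
    resid = fit.grammar_residuals()
    mean_scan = gwa_mmscore(means, g, fit)
    var_scan = vgwa_svlm(resid, g)
    return PopulationAnalysis(
        means=means, K_scan=K_scan, K_h2=K_h2, polygenic=fit, residuals=resid,
        mean_scan=mean_scan, var_scan=var_scan, H2=broad_sense_H2(pop.phenotypes))


def select_architecture(pop: SimPopulation, analysis: PopulationAnalysis,
                        chromosome: str = BLOCK_CHROM):
    """Significance-constrained LASSO over one chromosome plus joint refit.

    Returns ``(selection, model_or_None)``.
    """
    g = pop.genotypes
    significant = (set(analysis.mean_scan.significant())
                   | set(analysis.var_scan.significant()))
    cand = [m.marker_id for m in g.markers if m.chromosome == chromosome]
    g2 = g.subset_markers(cand)
    path = lasso_path(analysis.residuals, g2.imputed(), g2.marker_ids)
    sel = select_lambda(path, significant)
    model = None
    if sel.admissible:
        model = joint_refit(analysis.means, g, sorted(sel.markers))
    return sel, model
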