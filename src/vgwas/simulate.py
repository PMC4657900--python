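"""Synthetic inbred-accession populations with a multi-allelic LD block.

The generator emulates the statistical structure this package's analyses
assume: a panel of ~340 inbred accessions genotyped at biallelic markers,
with

* an extended LD block ("vBLOCK") whose high-variance haplotype (frequency
  ~0.29) is represented by a set of perfectly correlated marker columns;
* several functional minor alleles nested on that haplotype with mixed-sign
  effects (a 53-bp promoter deletion at −2.6 µg/g, a promoter duplication at
  +2.8 µg/g, a downstream SNP at +0.8 µg/g) plus one independent locus
  (+1.0 µg/g);
* a polygenic background built from genome-wide small-effect markers, so the
  genomic kinship computed from those same markers captures it; and
* replicate-level environmental noise.

Deletion and duplication carriers are mutually exclusive (in the real panel
the deletion occurs only among low-molybdenum and the duplication only among
high-molybdenum accessions).  Carrier counts are fixed at their expected
values and assigned to random accessions, emulating a single population
sample of fixed composition; all stochastic draws come from one seeded
numpy Generator, so a given seed reproduces the population bit-for-bit.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .data import GenotypeMatrix, MarkerInfo, PhenotypeTable

__all__ = [
    "FunctionalLocus",
    "SimConfig",
    "SimPopulation",
    "ScenarioSample",
    "simulate_population",
    "simulate_scenario",
    "analytic_locus_variance",
]

BLOCK_CHROM = "2"
BLOCK_START = 10_890_000
BLOCK_END = 10_960_000


@dataclass(frozen=True)
class FunctionalLocus:
    """A functional minor allele with an additive effect on the trait.

    ``nesting`` controls how carriers relate to the high-variance block
    haplotype: ``"free"`` (independent of the block), ``"only_on_block"``
    (every carrier is on the block; such loci are mutually exclusive with
    each other), or a float in (0, 1] giving the fraction of carriers that
    sit on the block.
    """

    name: str
    maf: float
    effect: float
    nesting: str | float = "free"
    position: int = 0

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5] for {self.name}")
        if isinstance(self.nesting, float) and not (0.0 < self.nesting <= 1.0):
            raise ValueError(f"nesting fraction must be in (0,1] for {self.name}")
        if isinstance(self.nesting, str) and self.nesting not in ("free", "only_on_block"):
            raise ValueError(f"unknown nesting {self.nesting!r}")

    @property
    def block_fraction(self) -> float | None:
        """Fraction of carriers on the block (None if free)."""
        if self.nesting == "free":
            return None
        if self.nesting == "only_on_block":
            return 1.0
        return float(self.nesting)


def default_loci() -> list[FunctionalLocus]:
    """The four-locus architecture around the molybdate-transporter region."""
    return [
        FunctionalLocus("DEL", 0.04, -2.6, "only_on_block", position=10_934_564),
        FunctionalLocus("DUP", 0.03, +2.8, "only_on_block", position=10_934_814),
        FunctionalLocus("SNP1", 0.14, +0.8, 19 / 29, position=10_909_091),
        FunctionalLocus("SNP2", 0.19, +1.0, "free", position=11_528_777),
    ]


@dataclass
class SimConfig:
    """Configuration of a synthetic population.

    Variances are in (µg/g)².  ``block_frequency`` is the frequency of the
    high-variance haplotype.  Use :meth:`default` for a configuration
    calibrated so that broad-sense heritability H² and the kinship
    intra-class correlation r of accession means hit chosen targets
    (defaults 0.80 and 0.63).
    """

    n_accessions: int = 340
    n_background_markers: int = 500
    block_frequency: float = 0.29
    loci: list[FunctionalLocus] = field(default_factory=default_loci)
    polygenic_variance: float = 1.35
    env_variance_within: float = 0.51
    replicates: int = 6
    seed: int = 0
    baseline: float = 6.0
    n_block_markers: int = 12
    n_chromosomes: int = 5
    # global inbred panels are strongly structured; subpopulation
    # differentiation is what makes the kinship informative for REML
    structure: tuple[int, float] | None = (8, 0.2)  # (n_subpops, fst)

    def __post_init__(self):
        if self.polygenic_variance < 0 or self.env_variance_within < 0:
            raise ValueError("variances must be >= 0")
        if not (0.0 < self.block_frequency < 1.0):
            raise ValueError("block_frequency must be in (0,1)")
        for locus in self.loci:
            f = locus.block_fraction
            if f is not None and locus.maf * f > self.block_frequency + 1e-12:
                raise ValueError(
                    f"infeasible nesting: locus {locus.name} places maf*fraction "
                    f"{locus.maf * f:.3f} on a block of frequency {self.block_frequency}")

    @classmethod
    def default(cls, seed: int = 0, H2_target: float = 0.80, r_target: float = 0.63,
                **kwargs) -> "SimConfig":
        """Config with variances calibrated to the target H² and intra-class r.

        With locus variance V_L (analytic), polygenic variance V_P, within-
        replicate variance s², and m replicates:
        H² = (V_P+V_L)/(V_P+V_L+s²) and r = V_P/(V_P+V_L+s²/m).  Solving
        gives V_P = c·V_L/(1−c) with c = r(1+(1−H²)/(H² m)), and
        s² = (V_P+V_L)(1−H²)/H².
        """
        cfg = cls(seed=seed, polygenic_variance=0.0, env_variance_within=0.0, **kwargs)
        v_loci = analytic_locus_variance(cfg)
        m = cfg.replicates
        c = r_target * (1.0 + (1.0 - H2_target) / (H2_target * m))
        if not (0.0 < c < 1.0):
            raise ValueError("targets imply an infeasible polygenic share")
        v_poly = c * v_loci / (1.0 - c)
        s2 = (v_poly + v_loci) * (1.0 - H2_target) / H2_target
        cfg.polygenic_variance = v_poly
        cfg.env_variance_within = s2
        return cfg


@dataclass
class SimPopulation:
    """A simulated population together with its generating truth."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict
    config: SimConfig

    def write(self, directory: str | Path) -> None:
        """Write genotypes (CSV), phenotypes (TSV) and truth (JSON)."""
        from .data import write_genotypes_csv

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_genotypes_csv(self.genotypes, directory / "genotypes.csv")
        self.phenotypes.write_tsv(directory / "phenotypes.tsv")
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in self.truth.items()}
        (directory / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# analytic locus variance (used for calibration and as an R² oracle)
# ---------------------------------------------------------------------------

def analytic_locus_variance(cfg: SimConfig) -> float:
    """Exact variance of the summed functional-locus contribution.

    Enumerates the joint distribution implied by the generator's assignment
    scheme: block status is Bernoulli(block_frequency); ``only_on_block``
    loci are mutually exclusive categories within the block; nested/free
    binary loci are conditionally independent given block status.
    """
    p_b = cfg.block_frequency
    exclusive = [l for l in cfg.loci if l.nesting == "only_on_block"]
    others = [l for l in cfg.loci if l.nesting != "only_on_block"]
    # categories within block: each exclusive locus, or none
    cat_probs_block = [l.maf / p_b for l in exclusive]
    if sum(cat_probs_block) > 1.0 + 1e-12:
        raise ValueError("exclusive loci exceed block frequency")
    cat_probs_block.append(1.0 - sum(cat_probs_block))
    cat_effects = [l.effect for l in exclusive] + [0.0]

    def p_carrier(locus: FunctionalLocus, b: int) -> float:
        f = locus.block_fraction
        if f is None:
            return locus.maf
        on = locus.maf * f / p_b
        off = locus.maf * (1.0 - f) / (1.0 - p_b)
        return on if b else off

    mean = 0.0
    second = 0.0
    for b, pb in ((1, p_b), (0, 1.0 - p_b)):
        cats = zip(cat_effects, cat_probs_block) if b else [(0.0, 1.0)]
        for cat_eff, pc in cats:
            for states in itertools.product((0, 1), repeat=len(others)):
                p = pb * pc
                g = cat_eff
                for locus, s in zip(others, states):
                    q = p_carrier(locus, b)
                    p *= q if s else (1.0 - q)
                    g += locus.effect * s
                mean += p * g
                second += p * g * g
    return second - mean * mean


# ---------------------------------------------------------------------------
# population generator
# ---------------------------------------------------------------------------

def _assign_carriers(rng: np.random.Generator, cfg: SimConfig, n: int
                     ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Fixed-count random assignment of block and functional-locus carriers."""
    n_block = int(round(cfg.block_frequency * n))
    perm = rng.permutation(n)
    block = np.zeros(n, dtype=bool)
    block[perm[:n_block]] = True
    block_idx = perm[:n_block]
    off_idx = perm[n_block:]

    carriers: dict[str, np.ndarray] = {}
    # mutually exclusive block-only loci drawn from disjoint slices of block_idx
    cursor = 0
    order = rng.permutation(n_block)
    for locus in cfg.loci:
        if locus.nesting != "only_on_block":
            continue
        k = int(round(locus.maf * n))
        if cursor + k > n_block:
            raise ValueError(f"infeasible nesting for {locus.name}")
        sel = block_idx[order[cursor:cursor + k]]
        cursor += k
        x = np.zeros(n, dtype=float)
        x[sel] = 1.0
        carriers[locus.name] = x
    for locus in cfg.loci:
        f = locus.block_fraction
        if locus.nesting == "only_on_block":
            continue
        k = int(round(locus.maf * n))
        x = np.zeros(n, dtype=float)
        if f is None:
            sel = rng.choice(n, size=k, replace=False)
        else:
            k_on = min(int(round(k * f)), n_block)
            k_off = k - k_on
            sel_on = rng.choice(block_idx, size=k_on, replace=False)
            sel_off = rng.choice(off_idx, size=k_off, replace=False)
            sel = np.concatenate([sel_on, sel_off])
        x[sel] = 1.0
        carriers[locus.name] = x
    return block.astype(float), carriers


def _background_genotypes(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    m = cfg.n_background_markers
    mafs = rng.uniform(0.1, 0.5, size=m)
    if cfg.structure is None:
        return (rng.random((n, m)) < mafs).astype(float)
    k, fst = cfg.structure
    pops = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    a = mafs * (1.0 - fst) / fst
    b = (1.0 - mafs) * (1.0 - fst) / fst
    sub_freq = rng.beta(a, b, size=(k, m))
    return (rng.random((n, m)) < sub_freq[pops]).astype(float)


def simulate_population(cfg: SimConfig) -> SimPopulation:
    """Generate genotypes, replicate phenotypes and the generating truth.

    The trait for accession i, replicate j is
    ``baseline + Σ_l a_l x_il + poly_i + ε_ij`` with
    ``poly ~ N(0, V_P · ZZᵀ/M)`` built from the standardized background
    markers Z and ``ε ~ N(0, env_variance_within)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_accessions
    accession_ids = [f"acc{i:04d}" for i in range(n)]

    block, carriers = _assign_carriers(rng, cfg, n)
    bg = _background_genotypes(rng, cfg, n)

    # polygenic term from standardized background markers
    sd = bg.std(axis=0)
    keep = sd > 0
    Z = (bg[:, keep] - bg[:, keep].mean(axis=0)) / sd[keep]
    u = rng.standard_normal(Z.shape[1])
    poly = Z @ u
    # rescale so the realized population variance is exactly as configured
    if cfg.polygenic_variance > 0 and poly.std() > 0:
        poly *= np.sqrt(cfg.polygenic_variance) / poly.std()
    else:
        poly = np.zeros(n)

    locus_term = np.zeros(n)
    for locus in cfg.loci:
        locus_term += locus.effect * carriers[locus.name]
    genetic = cfg.baseline + locus_term + poly

    eps = rng.normal(0.0, np.sqrt(cfg.env_variance_within), size=(n, cfg.replicates))
    values = genetic[:, None] + eps

    # --- assemble marker set ------------------------------------------------
    markers: list[MarkerInfo] = []
    cols: list[np.ndarray] = []
    per_chrom = int(np.ceil(cfg.n_background_markers / cfg.n_chromosomes))
    for j in range(cfg.n_background_markers):
        chrom = str(j // per_chrom + 1)
        pos = 1_000_000 + (j % per_chrom) * 37_000
        if chrom == BLOCK_CHROM and BLOCK_START - 50_000 <= pos <= 11_600_000:
            pos = 11_700_000 + (j % per_chrom) * 11_000  # keep clear of the block region
        p = bg[:, j].mean()
        maf = min(p, 1 - p)
        markers.append(MarkerInfo(f"bg{j:04d}", chrom, pos, "A", "C", maf))
        cols.append(bg[:, j] if p <= 0.5 else 1.0 - bg[:, j])
    # block tag markers: perfectly correlated columns spanning the interval
    tag_pos = np.linspace(BLOCK_START, BLOCK_END, cfg.n_block_markers).astype(int)
    p_blk = block.mean()
    for t, pos in enumerate(tag_pos):
        markers.append(MarkerInfo(f"vB{t:02d}", BLOCK_CHROM, int(pos), "A", "G",
                                  min(p_blk, 1 - p_blk)))
        cols.append(block.copy())
    for locus in cfg.loci:
        p = carriers[locus.name].mean()
        markers.append(MarkerInfo(locus.name, BLOCK_CHROM, locus.position or 1,
                                  "ref", "alt", min(p, 1 - p)))
        cols.append(carriers[locus.name])

    genotypes = GenotypeMatrix(accession_ids, markers, np.column_stack(cols))
    records = [(accession_ids[i], j + 1, float(values[i, j]))
               for i in range(n) for j in range(cfg.replicates)]
    # Gaussian replicate noise can push a rare low-trait replicate below zero;
    # the concentration-positivity check is relaxed for synthetic data.
    phenotypes = PhenotypeTable(
        pd.DataFrame(records, columns=["accession_id", "replicate", "value"]),
        require_positive=False)

    v_loci = float(np.var(locus_term))
    truth = {
        "effects": {l.name: l.effect for l in cfg.loci},
        "carriers": {name: x.astype(int).tolist() for name, x in carriers.items()},
        "block": block.astype(int).tolist(),
        "block_markers": [m.marker_id for m in markers if m.marker_id.startswith("vB")],
        "polygenic_values": poly.tolist(),
        "var_components": {
            "locus_realized": v_loci,
            "locus_analytic": analytic_locus_variance(cfg),
            "polygenic_configured": cfg.polygenic_variance,
            "polygenic_realized": float(np.var(poly)),
            "env_within": cfg.env_variance_within,
        },
        "H2_configured": (cfg.polygenic_variance + analytic_locus_variance(cfg))
        / (cfg.polygenic_variance + analytic_locus_variance(cfg) + cfg.env_variance_within)
        if (cfg.polygenic_variance + analytic_locus_variance(cfg)
            + cfg.env_variance_within) > 0 else 0.0,
    }
    return SimPopulation(genotypes, phenotypes, truth, cfg)


# ---------------------------------------------------------------------------
# two-group marker scenarios (multi-allelic tagging thought experiments)
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSample:
    """Two-group sample for the multi-allelic tagging scenarios.

    ``x`` is the biallelic marker (0/1 per individual), ``y`` the trait.
    Scenario "a": the low/high functional alleles are split evenly across
    both marker alleles (no mean, no variance difference in expectation).
    Scenario "b": the marker alleles tag the low and high alleles separately
    (mean difference 2·effect, equal variances).  Scenario "c": one marker
    allele tags both the low and high alleles (equal means, variance excess
    effect² in the tagged group).
    """

    x: np.ndarray
    y: np.ndarray
    scenario: str
    effect: float


def simulate_scenario(which: str, n_per_group: int, effect: float, seed: int = 0,
                      noise_sd: float = 1.0) -> ScenarioSample:
    if which not in ("a", "b", "c"):
        raise ValueError("scenario must be 'a', 'b' or 'c'")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    n = n_per_group
    x = np.concatenate([np.zeros(n), np.ones(n)])
    half = n // 2
    mix = np.concatenate([np.full(half, -effect), np.full(n - half, +effect)])
    if which == "a":
        mu = np.concatenate([rng.permutation(mix), rng.permutation(mix)])
    elif which == "b":
        mu = np.concatenate([np.full(n, -effect), np.full(n, +effect)])
    else:  # c: only the minor marker allele carries the functional mixture
        mu = np.concatenate([np.zeros(n), rng.permutation(mix)])
    y = mu + rng.normal(0.0, noise_sd, size=2 * n)
    return ScenarioSample(x=x, y=y, scenario=which, effect=effect)
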