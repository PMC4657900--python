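"""Genotype, phenotype and structural-variant containers with readers and QC.

The data model targets panels of inbred accessions (e.g. the *A. thaliana*
HapMap collection): every line is effectively homozygous genome-wide, so
genotype calls are haploid-equivalent and coded ``0`` (major-allele
homozygote), ``1`` (minor-allele homozygote) or missing (NaN).  The minor
allele is always defined per marker as the less frequent allele in the data
at hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerInfo",
    "GenotypeMatrix",
    "PhenotypeTable",
    "StructuralVariantCall",
    "GenotypeParseError",
    "HeterozygoteError",
    "read_genotypes",
    "write_genotypes_csv",
    "qc_filter",
    "accession_means",
    "merge_structural",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed; names the offending line."""


class HeterozygoteError(ValueError):
    """Raised in strict-inbred mode when a heterozygous call is encountered."""


@dataclass(frozen=True)
class MarkerInfo:
    """Per-marker metadata.

    Positions are 1-based inclusive base pairs (TAIR10 convention).  ``maf``
    is the minor-allele frequency, always in [0, 0.5].
    """

    marker_id: str
    chromosome: str
    position: int
    major_allele: str
    minor_allele: str
    maf: float

    def __post_init__(self):
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"maf out of range for {self.marker_id}: {self.maf}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1 for {self.marker_id}")


class GenotypeMatrix:
    """Accessions x markers call matrix for inbred lines.

    Parameters
    ----------
    accession_ids : sequence of str
        Row labels, in input order.
    markers : sequence of MarkerInfo
        Column metadata, in input order.
    calls : ndarray of shape (n_accessions, n_markers)
        Float matrix over {0.0, 1.0, nan}.
    """

    def __init__(self, accession_ids: Sequence[str], markers: Sequence[MarkerInfo],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=float)
        if calls.shape != (len(accession_ids), len(markers)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(accession_ids)}, {len(markers)})")
        ok = np.isnan(calls) | (calls == 0.0) | (calls == 1.0)
        if not ok.all():
            raise ValueError("calls must be coded 0, 1 or NaN")
        ids = list(accession_ids)
        if len(set(m.marker_id for m in markers)) != len(markers):
            raise ValueError("marker ids must be unique")
        self.accession_ids: list[str] = ids
        self.markers: list[MarkerInfo] = list(markers)
        self.calls = calls
        self.filter_log: dict | None = None

    # -- basic geometry -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_ids.index(marker_id)]

    # -- per-marker statistics ------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, recomputed from the calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.calls, axis=0)
        freq = np.where(np.isnan(freq), 0.0, freq)
        return np.minimum(freq, 1.0 - freq)

    def imputed(self) -> np.ndarray:
        """Calls with missing values mean-imputed per marker (for regressions)."""
        out = self.calls.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_means = np.nanmean(out, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        idx = np.where(np.isnan(out))
        out[idx] = col_means[idx[1]]
        return out

    def subset_markers(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            cols = np.flatnonzero(keep)
        else:
            index = {mid: j for j, mid in enumerate(self.marker_ids)}
            cols = np.array([index[mid] for mid in keep], dtype=int)
        return GenotypeMatrix(self.accession_ids,
                              [self.markers[j] for j in cols],
                              self.calls[:, cols])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.accession_ids == other.accession_ids
                and self.markers == other.markers
                and np.array_equal(self.calls, other.calls, equal_nan=True))


@dataclass(frozen=True)
class StructuralVariantCall:
    """A structural-variant genotype call at a named locus (e.g. DEL, DUP)."""

    accession_id: str
    locus_name: str
    allele_label: str


class PhenotypeTable:
    """Replicate-level trait records (values in µg element / g dry weight).

    Wraps a DataFrame with columns ``accession_id``, ``replicate``, ``value``
    and optional ``block``.  Values must be finite and positive.
    """

    REQUIRED = ("accession_id", "replicate", "value")

    def __init__(self, df: pd.DataFrame, require_positive: bool = True):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        if "block" not in df.columns:
            df["block"] = pd.NA
        vals = df["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("phenotype values must be finite")
        if require_positive and not np.all(vals > 0):
            raise ValueError("phenotype values must be > 0")
        if len(df) == 0:
            raise ValueError("phenotype table is empty")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "PhenotypeTable":
        df = pd.DataFrame(records, columns=["accession_id", "replicate", "value"])
        return cls(df)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.df["accession_id"]))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA", "N", ".", "NAN", "./.", ".|."}


def _parse_cell(cell: str, line_no: int, col: str) -> tuple[str, ...] | None:
    """Split one CSV genotype cell into allele symbols (1 = haploid, 2 = diploid)."""
    s = str(cell).strip()
    if s.upper() in _MISSING_TOKENS:
        return None
    s = s.replace("|", "/")
    parts = tuple(p for p in s.split("/") if p != "")
    if not parts:
        return None
    if len(parts) == 1:
        s = parts[0]
        if len(s) == 2 and s.isalpha():  # "AG" style diploid cell
            return (s[0], s[1])
        return (s,)
    if len(parts) == 2:
        return parts
    raise GenotypeParseError(f"line {line_no}: cannot parse call {cell!r} at marker {col}")


def _code_column(cells: list[tuple[str, ...] | None], col: str, strict: bool,
                 line_offset: int = 2) -> tuple[np.ndarray, str, str, float]:
    """Turn allele-symbol cells into 0/1/NaN calls; returns (calls, major, minor, maf)."""
    counts: dict[str, int] = {}
    for i, cell in enumerate(cells):
        if cell is None:
            continue
        if len(set(cell)) > 1 and strict:
            raise HeterozygoteError(
                f"line {line_offset + i}: heterozygous call {'/'.join(cell)} "
                f"at marker {col} (strict inbred mode)")
        # allele frequencies count every observed allele, hets included
        for a in cell:
            counts[a] = counts.get(a, 0) + 1
    for i, cell in enumerate(cells):
        if cell is not None and len(set(cell)) > 1:
            cells[i] = None  # lenient mode: heterozygote becomes missing
    alleles = sorted(counts, key=lambda a: (-counts[a], a))
    if len(alleles) > 2:
        raise GenotypeParseError(f"marker {col} has >2 alleles: {alleles}")
    if not alleles:
        return np.full(len(cells), np.nan), "N", "N", 0.0
    major = alleles[0]
    minor = alleles[1] if len(alleles) == 2 else major
    total = sum(counts.values())
    maf = counts.get(minor, 0) / total if len(alleles) == 2 else 0.0
    calls = np.full(len(cells), np.nan)
    for i, cell in enumerate(cells):
        if cell is not None:
            calls[i] = 1.0 if cell[0] == minor and minor != major else 0.0
    return calls, major, minor, maf


def _read_csv_genotypes(path: Path, strict: bool) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"cannot parse {path}: {exc}") from exc
    accession_ids = [str(a) for a in df.index]
    markers: list[MarkerInfo] = []
    calls = np.empty((len(accession_ids), df.shape[1]))
    for j, col in enumerate(df.columns):
        cells = [_parse_cell(c, i + 2, col) for i, c in enumerate(df[col])]
        coded, major, minor, maf = _code_column(cells, col, strict)
        calls[:, j] = coded
        chrom, pos = _marker_id_coords(col, j)
        markers.append(MarkerInfo(col, chrom, pos, major, minor, maf))
    return GenotypeMatrix(accession_ids, markers, calls)


def _marker_id_coords(marker_id: str, index: int) -> tuple[str, int]:
    """Parse 'chr_pos' style marker ids; fall back to column order."""
    parts = str(marker_id).split("_")
    if len(parts) >= 2 and parts[-1].isdigit():
        return "_".join(parts[:-1]), int(parts[-1])
    return "un", index + 1


def _read_vcf_genotypes(path: Path, strict: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accession_ids = list(vcf.samples)
    markers: list[MarkerInfo] = []
    cols: list[np.ndarray] = []
    for variant in vcf:
        gt = np.array(variant.gt_types, dtype=float)  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        calls = np.full(gt.shape, np.nan)
        calls[gt == 0] = 0.0
        calls[gt == 3] = 1.0
        if np.any(gt == 1):
            if strict:
                raise HeterozygoteError(
                    f"heterozygous call at {variant.CHROM}:{variant.POS} (strict inbred mode)")
            # lenient: leave as missing
        alt = variant.ALT[0] if variant.ALT else "N"
        ref = variant.REF
        n_alt = np.nansum(calls)
        n_obs = np.sum(~np.isnan(calls))
        freq_alt = n_alt / n_obs if n_obs else 0.0
        if freq_alt > 0.5:
            calls = 1.0 - calls
            major, minor, maf = alt, ref, 1.0 - freq_alt
        else:
            major, minor, maf = ref, alt, freq_alt
        mid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}"
        markers.append(MarkerInfo(mid, str(variant.CHROM), int(variant.POS), major, minor, maf))
        cols.append(calls)
    calls = np.column_stack(cols) if cols else np.empty((len(accession_ids), 0))
    return GenotypeMatrix(accession_ids, markers, calls)


def read_genotypes(path: str | Path, format: str | None = None,
                   strict_inbred: bool = True) -> GenotypeMatrix:
    """Read a genotype matrix from CSV or VCF.

    CSV dialect: rows = accessions (first column = accession id), header =
    marker ids; cells hold allele symbols ("A", "AG", "A/G") or 0/1 codes.
    The minor allele is defined per marker as the less frequent allele
    (frequency ties broken toward the alphabetically later symbol).  In
    strict-inbred mode (default) any heterozygous call raises
    :class:`HeterozygoteError`; in lenient mode it becomes missing.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" or path.name.endswith(".vcf.gz") else "csv"
    if format == "csv":
        return _read_csv_genotypes(path, strict_inbred)
    if format == "vcf":
        return _read_vcf_genotypes(path, strict_inbred)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes_csv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an allele-symbol CSV that round-trips through
    :func:`read_genotypes` (calls, marker order and allele labels preserved)."""
    data = {}
    for j, m in enumerate(g.markers):
        col = []
        for v in g.calls[:, j]:
            if np.isnan(v):
                col.append("NA")
            else:
                col.append(m.minor_allele if v == 1.0 else m.major_allele)
        data[m.marker_id] = col
    pd.DataFrame(data, index=g.accession_ids).to_csv(path, index_label="accession_id")


# ---------------------------------------------------------------------------
# QC and aggregation
# ---------------------------------------------------------------------------

def qc_filter(g: GenotypeMatrix, maf_min: float = 0.05,
              callrate_min: float = 0.95) -> GenotypeMatrix:
    """Drop markers with MAF below ``maf_min`` or call rate below ``callrate_min``.

    Boundaries are inclusive (maf == maf_min is retained).  The returned
    matrix carries a ``filter_log`` dict with per-criterion removal counts.
    Marker order is preserved.
    """
    if g.n_markers == 0:
        raise ValueError("genotype matrix has no markers")
    maf = g.maf()
    cr = g.call_rate()
    low_maf = maf < maf_min
    low_cr = cr < callrate_min
    keep = ~(low_maf | low_cr)
    out = g.subset_markers(keep)
    out.filter_log = {
        "n_input": g.n_markers,
        "removed_maf": int(low_maf.sum()),
        "removed_callrate": int(low_cr.sum()),
        "removed_total": int((~keep).sum()),
        "n_retained": out.n_markers,
        "maf_min": maf_min,
        "callrate_min": callrate_min,
    }
    if out.n_markers == 0:
        warnings.warn("qc_filter removed every marker", UserWarning)
    return out


def accession_means(p: PhenotypeTable) -> pd.DataFrame:
    """Per-accession mean trait value and replicate count.

    Returns a DataFrame indexed by accession_id with columns ``mean`` and
    ``n``, in first-appearance order.
    """
    grp = p.df.groupby("accession_id", sort=False)["value"]
    out = pd.DataFrame({"mean": grp.mean(), "n": grp.size()})
    out.index.name = "accession_id"
    return out


def merge_structural(g: GenotypeMatrix,
                     sv: Sequence[StructuralVariantCall],
                     coding: Mapping[str, Mapping[str, int]],
                     positions: Mapping[str, tuple[str, int]] | None = None,
                     ) -> GenotypeMatrix:
    """Append structural-variant loci as binary pseudo-marker columns.

    ``coding`` maps each locus name to its allele_label -> {0, 1} coding
    (e.g. DUP326 -> 1 vs {DUP322, reference} -> 0).  Accessions without a
    call at a locus get a missing value.  An allele label outside a locus's
    declared coding raises ``ValueError``.
    """
    if not sv:
        return g
    known = set(g.accession_ids)
    loci = list(dict.fromkeys(call.locus_name for call in sv))
    for call in sv:
        if call.accession_id not in known:
            raise ValueError(f"structural-variant accession {call.accession_id!r} not in genotypes")
        if call.locus_name not in coding:
            raise ValueError(f"no coding declared for locus {call.locus_name!r}")
        if call.allele_label not in coding[call.locus_name]:
            raise ValueError(
                f"unknown allele label {call.allele_label!r} for locus {call.locus_name!r}")
    row_index = {a: i for i, a in enumerate(g.accession_ids)}
    new_cols = []
    new_markers = []
    for locus in loci:
        col = np.full(g.n_accessions, np.nan)
        for call in sv:
            if call.locus_name != locus:
                continue
            col[row_index[call.accession_id]] = float(coding[locus][call.allele_label])
        n_obs = np.sum(~np.isnan(col))
        freq = np.nansum(col) / n_obs if n_obs else 0.0
        chrom, pos = (positions or {}).get(locus, ("SV", g.n_markers + len(new_markers) + 1))
        present = [lab for lab, v in coding[locus].items() if v == 1]
        absent = [lab for lab, v in coding[locus].items() if v == 0]
        new_markers.append(MarkerInfo(locus, chrom, pos,
                                      major_allele=absent[0] if absent else "ref",
                                      minor_allele=present[0] if present else "alt",
                                      maf=min(freq, 1 - freq)))
        new_cols.append(col)
    calls = np.column_stack([g.calls] + new_cols)
    return GenotypeMatrix(g.accession_ids, g.markers + new_markers, calls)


def read_structural_tsv(path: str | Path) -> list[StructuralVariantCall]:
    """Read structural-variant calls from a TSV with columns accession_id, locus, allele."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [StructuralVariantCall(r.accession_id, r.locus, r.allele)
            for r in df.itertuples(index=False)]
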