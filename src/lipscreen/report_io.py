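"""Peptide-report data model, readers/writers and sequence-level annotation.

The canonical in-memory representation of a peptide report is a long-format
:class:`pandas.DataFrame` with one row per (precursor, dose, replicate)
measurement and the columns listed in :data:`REPORT_COLUMNS`.  Missing
intensities are ``NaN`` in memory and ``"."`` on disk.  Helper converters to
and from :class:`IntensityRecord` objects are provided for code that prefers
typed records.

Peptide/protein coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TrypticType",
    "IntensityRecord",
    "SiteAnnotation",
    "ScreenConfig",
    "SchemaError",
    "ParseError",
    "LocalizationError",
    "REPORT_COLUMNS",
    "read_peptide_report",
    "write_peptide_report",
    "records_to_frame",
    "iter_records",
    "read_fasta",
    "read_site_annotations",
    "classify_tryptic_type",
    "locate_peptide",
]

#: Required columns of the long-format peptide report.
REPORT_COLUMNS = [
    "protein_id",
    "peptide_seq",
    "precursor_id",
    "dose",
    "replicate",
    "intensity",
]

#: Optional columns carried through when present.
OPTIONAL_COLUMNS = ["tryptic_type", "proteotypic"]

MISSING_TOKEN = "."


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names the offending row."""


class LocalizationError(ValueError):
    """A peptide could not be located on the stated protein sequence."""


class TrypticType(str, Enum):
    """Peptide end classification.

    FT (fully tryptic): both ends produced by trypsin (or a protein
    terminus); ST (semi-tryptic): exactly one such end, the other produced
    by the limited-proteolysis protease.
    """

    FT = "FT"
    ST = "ST"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class IntensityRecord:
    """One measured peptide-precursor intensity in one run."""

    protein_id: str
    peptide_seq: str
    precursor_id: str
    dose: float
    replicate: int
    intensity: float | None = None
    tryptic_type: TrypticType = TrypticType.UNKNOWN
    proteotypic: bool = True

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if not self.peptide_seq:
            raise ValueError("peptide_seq must be non-empty")
        if self.intensity is not None and not np.isnan(self.intensity):
            if self.intensity <= 0:
                raise ValueError(f"intensity must be > 0, got {self.intensity}")


@dataclass(frozen=True)
class SiteAnnotation:
    """A named interval (e.g. an antigenic site) on a protein, 1-based inclusive."""

    protein_id: str
    site_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"require 1 <= start <= end, got [{self.start}, {self.end}]"
            )


@dataclass
class ScreenConfig:
    """Thresholds and switches of a screening run.

    Defaults are the published analysis cutoffs: dose-responsive peptides
    require sigmoid correlation r > 0.85 and ANOVA q < 0.01; differential
    peptides require |log2 FC| > 0.75 (lysate mode) with moderated-t
    q < 0.01; precursors must be measured in >= 3 replicates in >= 5 dose
    conditions and proteins need >= 2 surviving precursors.
    """

    mode: str = "dose_response"  # dose_response | single_dose | protein_abundance
    fc_threshold: float = 0.75  # log2 scale
    q_threshold: float = 0.01
    r_threshold: float = 0.85
    anova_q_threshold: float = 0.01
    min_precursors_per_protein: int = 2
    min_replicates: int = 3
    min_conditions: int = 5
    normalization: str = "median_log2"  # median_log2 | vst
    outlier_multiplier: float = 1.5
    coverage_scope: str = "per_condition"  # per_condition | global
    near_window: int = 10
    site_mode: str = "overlap"  # overlap | containment
    q_floor: float = 1e-15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("dose_response", "single_dose", "protein_abundance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        for name in ("q_threshold", "r_threshold", "anova_q_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.near_window < 0:
            raise ValueError("near_window must be >= 0")
        if self.normalization not in ("median_log2", "vst"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------


def _coerce_report(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: required column {col!r} is missing")
    out = df.copy()
    # parse intensity, reporting the first bad row by number (1-based data rows)
    raw = out["intensity"].astype(object)
    raw = raw.replace({MISSING_TOKEN: np.nan, "": np.nan, None: np.nan})
    parsed = pd.to_numeric(raw, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric intensity {raw.iloc[i]!r} at data row {i + 1}"
        )
    out["intensity"] = parsed.astype(float)
    try:
        out["dose"] = pd.to_numeric(out["dose"])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric dose value: {exc}") from exc
    out["replicate"] = out["replicate"].astype(int)
    if "tryptic_type" not in out.columns:
        out["tryptic_type"] = TrypticType.UNKNOWN.value
    if "proteotypic" not in out.columns:
        out["proteotypic"] = True
    else:
        out["proteotypic"] = out["proteotypic"].map(
            lambda v: str(v).strip().lower() in ("true", "1")
        )
    if (out["dose"] < 0).any():
        raise ParseError(f"{path}: negative dose encountered")
    return out[REPORT_COLUMNS + OPTIONAL_COLUMNS]


def read_peptide_report(
    path: str | Path, dialect: str = "long_tsv", sep: str | None = None
) -> pd.DataFrame:
    """Read a peptide report into the canonical long-format frame.

    ``dialect="long_tsv"`` expects one row per measurement.  In
    ``dialect="wide_tsv"`` every run is one column named ``<dose>_<replicate>``
    and rows are precursors; the wide table is melted to long form.
    Missing intensities (empty cells or ``"."``) are preserved as NaN, never
    dropped.  A zero-dose condition is the control.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False)
    if dialect == "long_tsv":
        return _coerce_report(df, path)
    if dialect == "wide_tsv":
        id_cols = [c for c in ("protein_id", "peptide_seq", "precursor_id",
                               "tryptic_type", "proteotypic") if c in df.columns]
        for col in ("protein_id", "peptide_seq", "precursor_id"):
            if col not in id_cols:
                raise SchemaError(f"{path}: required column {col!r} is missing")
        run_cols = [c for c in df.columns if c not in id_cols]
        if not run_cols:
            raise SchemaError(f"{path}: no run columns found in wide table")
        long = df.melt(id_vars=id_cols, value_vars=run_cols,
                       var_name="_run", value_name="intensity")
        try:
            parts = long["_run"].str.rsplit("_", n=1, expand=True)
            long["dose"] = pd.to_numeric(parts[0])
            long["replicate"] = parts[1].astype(int)
        except (ValueError, TypeError, KeyError) as exc:
            raise ParseError(
                f"{path}: wide run columns must be named '<dose>_<replicate>': {exc}"
            ) from exc
        long = long.drop(columns="_run")
        return _coerce_report(long, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_peptide_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format report as TSV; missing intensities become ``"."``."""
    out = df[REPORT_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]].copy()
    out["intensity"] = out["intensity"].map(
        lambda v: MISSING_TOKEN if pd.isna(v) else repr(float(v))
    )
    out.to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[IntensityRecord]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": r.protein_id,
            "peptide_seq": r.peptide_seq,
            "precursor_id": r.precursor_id,
            "dose": r.dose,
            "replicate": r.replicate,
            "intensity": np.nan if r.intensity is None else r.intensity,
            "tryptic_type": (
                r.tryptic_type.value
                if isinstance(r.tryptic_type, TrypticType)
                else str(r.tryptic_type)
            ),
            "proteotypic": r.proteotypic,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS + OPTIONAL_COLUMNS)


def iter_records(df: pd.DataFrame) -> Iterator[IntensityRecord]:
    for row in df.itertuples(index=False):
        yield IntensityRecord(
            protein_id=row.protein_id,
            peptide_seq=row.peptide_seq,
            precursor_id=row.precursor_id,
            dose=float(row.dose),
            replicate=int(row.replicate),
            intensity=None if pd.isna(row.intensity) else float(row.intensity),
            tryptic_type=TrypticType(getattr(row, "tryptic_type", "unknown")),
            proteotypic=bool(getattr(row, "proteotypic", True)),
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by the first token of the FASTA header."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_site_annotations(path: str | Path) -> list[SiteAnnotation]:
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "site_name", "start", "end"):
        if col not in df.columns:
            raise SchemaError(f"{path}: required column {col!r} is missing")
    return [
        SiteAnnotation(str(r.protein_id), str(r.site_name), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# sequence-level annotation
# ---------------------------------------------------------------------------


def classify_tryptic_type(
    protein_seq: str, peptide_seq: str, position: tuple[int, int]
) -> tuple[TrypticType, bool]:
    """Classify a localized peptide as fully (FT) or semi-tryptic (ST).

    An end is tryptic iff the residue N-terminal of the peptide is K or R
    (or the peptide starts at position 1), respectively the peptide's last
    residue is K or R (or it reaches the protein C-terminus).  K/R followed
    by proline still counts as tryptic (Trypsin/P convention).  Returns the
    class together with a ``non_tryptic`` flag that is True for the
    undefined zero-tryptic-ends case, which is conservatively classed ST.
    """
    start, end = position
    n = len(protein_seq)
    if not (1 <= start <= end <= n) or protein_seq[start - 1 : end] != peptide_seq:
        raise LocalizationError(
            f"peptide {peptide_seq!r} does not occur at positions [{start}, {end}]"
        )
    n_term_tryptic = start == 1 or protein_seq[start - 2] in "KR"
    c_term_tryptic = end == n or peptide_seq[-1] in "KR"
    if n_term_tryptic and c_term_tryptic:
        return TrypticType.FT, False
    if n_term_tryptic or c_term_tryptic:
        return TrypticType.ST, False
    return TrypticType.ST, True


def locate_peptide(protein_seq: str, peptide_seq: str) -> tuple[int, int]:
    """1-based inclusive interval of the first occurrence of the peptide.

    Multiple occurrences trigger a warning and the first is returned.
    """
    if not protein_seq or not peptide_seq:
        raise ValueError("protein_seq and peptide_seq must be non-empty")
    idx = protein_seq.find(peptide_seq)
    if idx < 0:
        raise LocalizationError(f"peptide {peptide_seq!r} not found in protein")
    if protein_seq.find(peptide_seq, idx + 1) >= 0:
        warnings.warn(
            f"peptide {peptide_seq!r} occurs more than once; using first occurrence",
            stacklevel=2,
        )
    return idx + 1, idx + len(peptide_seq)
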