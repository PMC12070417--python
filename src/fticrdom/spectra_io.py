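"""Peak-list data model and CSV readers/writers.

The ingestion boundary is a centroided peak list — a CSV of (m/z,
intensity) rows — plus sample metadata from a manifest.  Raw transients
and vendor files are out of scope; everything upstream of the centroid
list belongs to instrument software.

CSV dialects
------------
Peak list:   header ``mz,intensity``; UTF-8, decimal point; m/z printed
             with 6 decimal places on write.
Manifest:    ``sample_id,path,site_id,collection_date,sample_type,
             acquisition_date`` with ISO-8601 dates and sample_type in
             {sample, blank}.
Assignments: ``mz,calibrated_mz,intensity,formula,ppm_error,n_candidates,
             class,dbe,ai,nosc,h_c,o_c``; formula is a Hill string,
             empty for unassigned peaks; round-trips at 1e-9.

Lines starting with ``#`` are provenance comments and are skipped on read.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    MolecularFormula,
    compute_indices,
)

logger = logging.getLogger("fticrdom")

ASSIGNMENT_COLUMNS = [
    "mz", "calibrated_mz", "intensity", "formula", "ppm_error",
    "n_candidates", "class", "dbe", "ai", "nosc", "h_c", "o_c",
]

MANIFEST_COLUMNS = [
    "sample_id", "path", "site_id", "collection_date", "sample_type",
    "acquisition_date",
]


class FormatError(ValueError):
    """Malformed input file (missing columns, bad manifest)."""


class EmptyInputError(ValueError):
    """A file or collection that must contain data is empty."""


def _parse_date(value) -> _dt.date | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class SampleMetadata:
    """Identity and provenance of one acquired spectrum."""

    sample_id: str
    site_id: str = ""
    collection_date: _dt.date | None = None
    sample_type: str = "sample"
    acquisition_date: _dt.date | None = None
    path: str = ""

    def __post_init__(self) -> None:
        if self.sample_type not in ("sample", "blank"):
            raise FormatError(f"sample_type must be 'sample' or 'blank', got {self.sample_type!r}")


@dataclass(frozen=True)
class Peak:
    """One centroided observation."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if not (self.intensity >= 0):
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")


@dataclass
class PeakList:
    """A sample's canonical peak table plus metadata.

    ``df`` has columns ``mz`` and ``intensity`` (and ``calibrated_mz``
    after recalibration), strictly increasing in m/z; duplicate m/z rows
    are merged by intensity sum at construction.
    """

    df: pd.DataFrame
    meta: SampleMetadata

    def __post_init__(self) -> None:
        self.df = canonicalize(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mz(self) -> np.ndarray:
        return self.df["mz"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.df["intensity"].to_numpy()

    @property
    def effective_mz(self) -> np.ndarray:
        """Calibrated m/z when present, raw m/z otherwise."""
        col = "calibrated_mz" if "calibrated_mz" in self.df.columns else "mz"
        return self.df[col].to_numpy()

    @property
    def base_peak_intensity(self) -> float:
        if len(self.df) == 0:
            return 0.0
        return float(self.df["intensity"].max())

    def with_df(self, df: pd.DataFrame) -> "PeakList":
        return PeakList(df=df.reset_index(drop=True), meta=self.meta)

    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.df["mz"], self.df["intensity"])]


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by m/z and merge duplicate m/z rows by intensity sum.

    Idempotent; preserves a ``calibrated_mz`` column if present (first
    value per duplicate group, which is well-defined because calibration
    is a function of m/z).
    """
    if not {"mz", "intensity"} <= set(df.columns):
        raise FormatError("peak table requires 'mz' and 'intensity' columns")
    agg = {"intensity": "sum"}
    if "calibrated_mz" in df.columns:
        agg["calibrated_mz"] = "first"
    out = df.groupby("mz", as_index=False, sort=True).agg(agg)
    cols = ["mz", "intensity"] + (["calibrated_mz"] if "calibrated_mz" in df.columns else [])
    return out[cols].reset_index(drop=True)


def read_peaklist(path: str | Path, metadata: SampleMetadata) -> PeakList:
    """Read a (mz, intensity) CSV into a canonical :class:`PeakList`.

    Rows with non-numeric or non-positive m/z (or non-numeric intensity)
    are rejected and their count logged.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    missing = {"mz", "intensity"} - set(raw.columns)
    if missing:
        raise FormatError(f"{path} lacks required column(s): {sorted(missing)}")
    if len(raw) == 0:
        raise EmptyInputError(f"{path} contains no peaks")
    mz = pd.to_numeric(raw["mz"], errors="coerce")
    intensity = pd.to_numeric(raw["intensity"], errors="coerce")
    ok = mz.notna() & intensity.notna() & (mz > 0) & (intensity >= 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: rejected %d malformed peak row(s)", path.name, n_bad)
    df = pd.DataFrame({"mz": mz[ok].astype(float), "intensity": intensity[ok].astype(float)})
    if len(df) == 0:
        raise EmptyInputError(f"{path} contains no valid peaks")
    return PeakList(df=df, meta=replace(metadata, path=str(path)))


def write_peaklist(peaklist: PeakList, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write the peak-list CSV dialect (m/z at 6 decimal places)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("mz,intensity\n")
        for m, i in zip(peaklist.df["mz"], peaklist.df["intensity"]):
            fh.write(f"{m:.6f},{i!r}\n")


# --------------------------------------------------------------------------
# Assigned peaks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AssignedPeak:
    """A peak joined to its best candidate formula (or left unassigned)."""

    mz: float
    intensity: float
    calibrated_mz: float
    formula: MolecularFormula | None = None
    ppm_error: float = float("nan")
    n_candidates: int = 0

    @property
    def assigned(self) -> bool:
        return self.formula is not None


@dataclass
class AssignedSample:
    """All of one sample's peaks after formula assignment."""

    meta: SampleMetadata
    peaks: list[AssignedPeak] = field(default_factory=list)

    @property
    def assigned_peaks(self) -> list[AssignedPeak]:
        return [p for p in self.peaks if p.assigned]

    def formulas(self) -> set[MolecularFormula]:
        return {p.formula for p in self.peaks if p.assigned}

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)


def assignments_frame(sample: AssignedSample, class_table=None) -> pd.DataFrame:
    """Tabulate an :class:`AssignedSample` in the assignments CSV layout.

    ``class_table`` is a :class:`~fticrdom.dom_metrics.ClassBoundaryTable`;
    when omitted the class column is left empty.
    """
    rows = []
    for p in sample.peaks:
        if p.assigned:
            idx = compute_indices(p.formula)
            label = class_table.classify(p.formula) if class_table is not None else ""
            rows.append((p.mz, p.calibrated_mz, p.intensity, p.formula.hill(),
                         p.ppm_error, p.n_candidates, label,
                         idx.dbe, idx.ai, idx.nosc, idx.h_c, idx.o_c))
        else:
            rows.append((p.mz, p.calibrated_mz, p.intensity, "",
                         np.nan, p.n_candidates, "",
                         np.nan, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def write_assignments(
    sample: AssignedSample,
    path: str | Path,
    class_table=None,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the assignments CSV; numeric fields keep full precision."""
    df = assignments_frame(sample, class_table)
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_assignments(path: str | Path, metadata: SampleMetadata | None = None) -> AssignedSample:
    """Read an assignments CSV back into an :class:`AssignedSample`."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", keep_default_na=False,
                     na_values=[""], dtype={"formula": str, "class": str})
    missing = set(ASSIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path} lacks required column(s): {sorted(missing)}")
    peaks = []
    for row in df.itertuples(index=False):
        formula_text = row.formula if isinstance(row.formula, str) else ""
        formula = MolecularFormula.from_hill(formula_text) if formula_text else None
        peaks.append(AssignedPeak(
            mz=float(row.mz), intensity=float(row.intensity),
            calibrated_mz=float(row.calibrated_mz), formula=formula,
            ppm_error=float(row.ppm_error) if formula else float("nan"),
            n_candidates=int(row.n_candidates),
        ))
    meta = metadata or SampleMetadata(sample_id=path.stem)
    return AssignedSample(meta=meta, peaks=peaks)


# --------------------------------------------------------------------------
# Manifests
# --------------------------------------------------------------------------


def read_manifest(path: str | Path) -> list[SampleMetadata]:
    """Read the sample manifest CSV (one row per acquired spectrum)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path} lacks required column(s): {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(SampleMetadata(
            sample_id=row.sample_id, site_id=row.site_id,
            collection_date=_parse_date(row.collection_date or None),
            sample_type=row.sample_type,
            acquisition_date=_parse_date(row.acquisition_date or None),
            path=row.path,
        ))
    if not out:
        raise EmptyInputError(f"{path} lists no samples")
    return out


def write_manifest(entries: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = [
        (m.sample_id, m.path, m.site_id,
         m.collection_date.isoformat() if m.collection_date else "",
         m.sample_type,
         m.acquisition_date.isoformat() if m.acquisition_date else "")
        for m in entries
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
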