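"""Tabular and config I/O: compound library, sample metadata, peak tables,
pipeline configuration.

Conventions (stated once, used everywhere): retention times in minutes,
CSV is UTF-8 comma-separated with a header row and "." decimals, empty
cells are missing values and are distinct from literal 0, and literal 0
areas are treated as missing at analysis time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundEntry",
    "SampleMeta",
    "PeakTable",
    "PipelineConfig",
    "SAMPLE_TYPES",
    "read_library",
    "write_library",
    "read_sample_meta",
    "write_sample_meta",
    "read_peak_table",
    "write_peak_table",
]

SAMPLE_TYPES = ("study", "pool", "pool_dilution", "blank", "mock", "standard")


@dataclass
class CompoundEntry:
    """One library compound targeted for extraction."""

    compound_id: str
    name: str = ""
    formula: str | None = None
    adduct: str | None = None
    target_mz: float | None = None
    rt: float = 1.0
    rt_tol: float = 0.5
    is_internal_standard: bool = False
    is_pair: str | None = None  # analyte -> compound_id of its paired IS

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError(
                f"compound {self.compound_id!r}: expected RT must be > 0"
            )
        if self.target_mz is None and not (self.formula and self.adduct):
            raise ValueError(
                f"compound {self.compound_id!r}: need target_mz or "
                "formula + adduct"
            )

    def mz(self) -> float:
        """Target m/z; an explicit target_mz overrides formula + adduct."""
        if self.target_mz is not None:
            if self.formula:
                logger.warning(
                    "compound %s: both target_mz and formula given; "
                    "target_mz wins", self.compound_id,
                )
            return float(self.target_mz)
        return chem.resolve_mz(self.formula, self.adduct)


@dataclass
class SampleMeta:
    """Per-injection metadata."""

    sample_id: str
    group: str = ""
    sample_type: str = "study"
    dilution_factor: float = 1.0
    injection_order: int = 0
    volume_ul: float = 1.0

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample {self.sample_id!r}: sample_type {self.sample_type!r} "
                f"not in {SAMPLE_TYPES}"
            )
        if not (0 < self.dilution_factor <= 1):
            raise ValueError(
                f"sample {self.sample_id!r}: dilution_factor must be in (0, 1]"
            )
        if self.sample_type == "pool_dilution" and self.dilution_factor >= 1:
            raise ValueError(
                f"sample {self.sample_id!r}: pool_dilution requires "
                "dilution_factor < 1"
            )


class PeakTable:
    """Samples x compounds matrix of integrated peak areas.

    Missing values are NaN. Sample metadata and the compound library are
    carried alongside when available.
    """

    def __init__(
        self,
        areas: pd.DataFrame,
        samples: list[SampleMeta] | None = None,
        compounds: list[CompoundEntry] | None = None,
    ) -> None:
        if areas.index.duplicated().any():
            dupes = sorted(areas.index[areas.index.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        if areas.columns.duplicated().any():
            dupes = sorted(areas.columns[areas.columns.duplicated()].unique())
            raise ValueError(f"duplicate compound ids: {dupes}")
        values = areas.astype(float)
        with np.errstate(invalid="ignore"):
            if (values.to_numpy() < 0).any():
                raise ValueError("peak areas must be >= 0 where present")
        self.areas = values
        self.samples = list(samples) if samples is not None else None
        self.compounds = list(compounds) if compounds is not None else None
        self._check_labels()

    def _check_labels(self) -> None:
        if self.samples is not None:
            ids = [s.sample_id for s in self.samples]
            if set(ids) != set(self.areas.index):
                raise ValueError("sample metadata ids do not match table rows")
            self.areas = self.areas.loc[ids]
        if self.compounds is not None:
            ids = [c.compound_id for c in self.compounds]
            if set(ids) != set(self.areas.columns):
                raise ValueError("library ids do not match table columns")
            self.areas = self.areas[ids]

    # -- convenience -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.areas.columns)

    def meta(self, sample_id: str) -> SampleMeta:
        if self.samples is None:
            raise ValueError("no sample metadata attached")
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def samples_of_type(self, *types: str) -> list[str]:
        if self.samples is None:
            raise ValueError("no sample metadata attached")
        return [s.sample_id for s in self.samples if s.sample_type in types]

    def entry(self, compound_id: str) -> CompoundEntry:
        if self.compounds is None:
            raise ValueError("no compound library attached")
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)

    def is_compound_ids(self) -> list[str]:
        if self.compounds is None:
            return []
        return [c.compound_id for c in self.compounds
                if c.is_internal_standard]

    def with_areas(self, areas: pd.DataFrame) -> "PeakTable":
        return PeakTable(areas, self.samples, self.compounds)

    def copy(self) -> "PeakTable":
        return PeakTable(self.areas.copy(), self.samples, self.compounds)


# -- CSV I/O ---------------------------------------------------------------

_LIB_COLUMNS = [
    "compound_id", "name", "formula", "adduct", "target_mz",
    "rt_min", "rt_tol_min", "internal_standard", "is_pair",
]


def read_library(path: str) -> list[CompoundEntry]:
    """Read a compound-library CSV.

    Columns: compound_id, name, formula, adduct, target_mz, rt_min,
    rt_tol_min, internal_standard (0/1), is_pair. Either target_mz or
    formula + adduct must resolve; when both are present target_mz wins
    and a warning is logged.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    missing = {"compound_id", "rt_min"} - set(df.columns)
    if missing:
        raise ValueError(f"library {path!r} missing columns {sorted(missing)}")
    dupes = df["compound_id"][df["compound_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate compound ids in library: {sorted(set(dupes))}")
    entries = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def _get(key, default=None):
            v = d.get(key, default)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return default
            return v

        entries.append(CompoundEntry(
            compound_id=str(d["compound_id"]),
            name=str(_get("name", "") or ""),
            formula=_get("formula"),
            adduct=_get("adduct"),
            target_mz=(None if _get("target_mz") is None
                       else float(_get("target_mz"))),
            rt=float(d["rt_min"]),
            rt_tol=float(_get("rt_tol_min", 0.5)),
            is_internal_standard=bool(int(_get("internal_standard", 0))),
            is_pair=(None if _get("is_pair") is None else str(_get("is_pair"))),
        ))
    return entries


def write_library(entries: list[CompoundEntry], path: str) -> None:
    rows = []
    for e in entries:
        rows.append({
            "compound_id": e.compound_id, "name": e.name,
            "formula": e.formula or "", "adduct": e.adduct or "",
            "target_mz": "" if e.target_mz is None else e.target_mz,
            "rt_min": e.rt, "rt_tol_min": e.rt_tol,
            "internal_standard": int(e.is_internal_standard),
            "is_pair": e.is_pair or "",
        })
    pd.DataFrame(rows, columns=_LIB_COLUMNS).to_csv(path, index=False)


_META_COLUMNS = [
    "sample_id", "group", "sample_type", "dilution_factor",
    "injection_order", "volume_ul",
]


def read_sample_meta(path: str) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    missing = {"sample_id", "sample_type"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path!r} missing columns {sorted(missing)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sample ids in metadata: {sorted(set(dupes))}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        group = d.get("group", "")
        out.append(SampleMeta(
            sample_id=str(d["sample_id"]),
            group="" if pd.isna(group) else str(group),
            sample_type=str(d["sample_type"]),
            dilution_factor=float(d.get("dilution_factor", 1.0)),
            injection_order=int(d.get("injection_order", 0)),
            volume_ul=float(d.get("volume_ul", 1.0)),
        ))
    return out


def write_sample_meta(samples: list[SampleMeta], path: str) -> None:
    rows = [dataclasses.asdict(s) for s in samples]
    df = pd.DataFrame(rows)
    df.columns = _META_COLUMNS
    df.to_csv(path, index=False)


def read_peak_table(
    path: str,
    samples: list[SampleMeta] | None = None,
    compounds: list[CompoundEntry] | None = None,
) -> PeakTable:
    """Read a peak-area CSV: first column sample ids, header compound ids.

    Empty cells become NaN (missing), never 0.
    """
    import csv

    with open(path, encoding="utf-8") as fh:
        header = next(csv.reader(fh))[1:]  # pandas mangles duplicates
    dupes = [c for c in header if header.count(c) > 1]
    if dupes:
        raise ValueError(f"duplicate compound ids: {sorted(set(dupes))}")
    df = pd.read_csv(path, index_col=0, dtype=str)
    dupes = [i for i in df.index if list(df.index).count(i) > 1]
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
    values = df.apply(pd.to_numeric, errors="raise").astype(float)
    return PeakTable(values, samples=samples, compounds=compounds)


def write_peak_table(table: PeakTable, path: str) -> None:
    """Write areas as CSV; NaN serializes to an empty cell."""
    out = table.areas.copy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="")


# -- pipeline configuration ------------------------------------------------


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; defaults follow the published method
    (5 ppm extraction tolerance, dilution RSQ > 0.95, pooled CV < 30%,
    full scan m/z 70-1000, narrow thyroid-hormone scan 600-800)."""

    ppm_tol: float = 5.0
    rt_tol: float = 0.5
    rsq_cutoff: float = 0.95
    cv_cutoff: float = 30.0
    lod_rsq_min: float = 0.99
    scan_range_full: tuple[float, float] = (70.0, 1000.0)
    scan_range_narrow: tuple[float, float] = (600.0, 800.0)
    log_base: float = 10.0
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scan_range_full"] = list(self.scan_range_full)
        d["scan_range_narrow"] = list(self.scan_range_narrow)
        return d

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("scan_range_full", "scan_range_narrow"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def warn_and_log(msg: str) -> None:
    """Emit both a logging record and a warning (tests watch warnings)."""
    logger.warning(msg)
    warnings.warn(msg, UserWarning, stacklevel=2)
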