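"""Linear dynamic range and limit of detection from standard dilution series.

Two LOD readouts are reported because "linear limit of detection" admits
both readings: the blank + 3 sigma crossing constrained to the linear
segment (``lod``), and the lowest concentration of the linear segment
itself (``lowest_linear``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DilutionSeries", "CalibrationResult", "fit_linear_range"]


@dataclass
class DilutionSeries:
    """Replicate areas measured over a concentration ladder (nM).

    ``concentration`` and ``area`` are parallel replicate-level arrays;
    concentration 0 rows are blanks.
    """

    compound_id: str
    concentration: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.concentration.shape != self.area.shape:
            raise ValueError("concentration and area must be equal length")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def levels(self) -> np.ndarray:
        """Ascending distinct non-zero concentrations."""
        return np.unique(self.concentration[self.concentration > 0])

    def level_means(self) -> pd.Series:
        conc = self.concentration[self.concentration > 0]
        area = self.area[self.concentration > 0]
        return pd.Series(area).groupby(pd.Series(conc)).mean()

    def level_cv(self) -> pd.Series:
        conc = self.concentration[self.concentration > 0]
        area = self.area[self.concentration > 0]
        g = pd.Series(area).groupby(pd.Series(conc))
        return 100.0 * g.std(ddof=1) / g.mean()

    def blanks(self) -> np.ndarray:
        return self.area[self.concentration == 0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       compound_id: str | None = None) -> "DilutionSeries":
        """Build from a long table: compound, concentration_nM, area."""
        if compound_id is not None:
            df = df[df["compound"] == compound_id]
        else:
            ids = df["compound"].unique()
            if len(ids) != 1:
                raise ValueError(f"expected one compound, found {list(ids)}")
            compound_id = ids[0]
        return cls(
            compound_id=str(compound_id),
            concentration=df["concentration_nM"].to_numpy(float),
            area=df["area"].to_numpy(float),
        )


@dataclass
class CalibrationResult:
    compound_id: str
    slope: float | None
    intercept: float | None
    rsq: float | None
    linear_range: tuple[float, float] | None
    lod: float | None
    lod_status: str  # "in_range", "above_range", "no_linear_range"
    lowest_linear: float | None
    blank_mean: float
    blank_sd: float
    level_cv: dict[float, float]

    def to_dict(self) -> dict:
        d = {
            "compound_id": self.compound_id,
            "slope": self.slope,
            "intercept": self.intercept,
            "rsq": self.rsq,
            "linear_range_nM": list(self.linear_range)
            if self.linear_range else None,
            "lod_nM": self.lod,
            "lod_status": self.lod_status,
            "lowest_linear_nM": self.lowest_linear,
            "blank_mean": self.blank_mean,
            "blank_sd": self.blank_sd,
            "level_cv_percent": {str(k): (None if np.isnan(v) else float(v))
                                 for k, v in self.level_cv.items()},
        }
        return d


def _ols_rsq(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rsq = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return float(coef[0]), float(coef[1]), rsq


def fit_linear_range(
    series: DilutionSeries, rsq_min: float = 0.99, min_levels: int = 4
) -> CalibrationResult:
    """Find the linear segment and the LOD of a dilution series.

    The linear segment is the longest contiguous run of concentration
    levels whose OLS fit of mean area vs concentration reaches
    ``rsq_min``; ties prefer the run reaching the highest concentration,
    so saturated top levels are excluded exactly when dropping them buys
    a longer linear stretch. The LOD is the lowest level inside that
    segment whose mean area exceeds blank mean + 3 * blank sd (unbiased);
    with no qualifying level the LOD is reported as above range.
    Deterministic; scale-invariant in the areas.
    """
    levels = series.levels
    if levels.size < min_levels:
        raise ValueError(
            f"need >= {min_levels} non-zero concentration levels, "
            f"found {levels.size}"
        )
    blanks = series.blanks()
    if blanks.size < 2:
        raise ValueError(
            "need >= 2 blank replicates to estimate the blank noise floor"
        )
    means = series.level_means()  # indexed by ascending concentration
    blank_mean = float(np.mean(blanks))
    blank_sd = float(np.std(blanks, ddof=1))
    level_cv = series.level_cv().to_dict()

    chosen: np.ndarray | None = None
    fit: tuple[float, float, float] | None = None
    # longest contiguous run first; ties prefer the higher top concentration
    for length in range(levels.size, min_levels - 1, -1):
        for start in range(levels.size - length, -1, -1):
            run = levels[start:start + length]
            s, i, r = _ols_rsq(run, means[run].to_numpy())
            if not np.isnan(r) and r >= rsq_min:
                chosen = run
                fit = (s, i, r)
                break
        if chosen is not None:
            break
    if chosen is None:
        return CalibrationResult(
            compound_id=series.compound_id, slope=None, intercept=None,
            rsq=None, linear_range=None, lod=None,
            lod_status="no_linear_range", lowest_linear=None,
            blank_mean=blank_mean, blank_sd=blank_sd, level_cv=level_cv,
        )
    threshold = blank_mean + 3.0 * blank_sd
    detectable = [c for c in chosen if means[c] > threshold]
    if detectable:
        lod = float(min(detectable))
        status = "in_range"
    else:
        lod = None
        status = "above_range"
    slope, intercept, rsq = fit
    return CalibrationResult(
        compound_id=series.compound_id, slope=slope, intercept=intercept,
        rsq=rsq, linear_range=(float(chosen.min()), float(chosen.max())),
        lod=lod, lod_status=status, lowest_linear=float(chosen.min()),
        blank_mean=blank_mean, blank_sd=blank_sd, level_cv=level_cv,
    )
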