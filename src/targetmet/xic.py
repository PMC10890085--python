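"""Targeted quantification: XIC extraction at ppm tolerance, RT-window
peak integration, per-run peak-table assembly, and MS2 cosine similarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msio import CompoundEntry, PeakTable, PipelineConfig, SampleMeta
from .mzml import MSRun, Spectrum

__all__ = [
    "Chromatogram",
    "IntegratedPeak",
    "extract_xic",
    "integrate_peak",
    "quantify_run",
    "ms2_cosine",
]


@dataclass
class Chromatogram:
    """Summed intensity within an m/z window per MS1 spectrum."""

    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative chromatogram intensity")


@dataclass
class IntegratedPeak:
    compound_id: str
    apex_rt: float
    rt_start: float
    rt_end: float
    area: float  # intensity * minutes
    apex_intensity: float


def extract_xic(run: MSRun, target_mz: float, ppm_tol: float) -> Chromatogram:
    """Extract an ion chromatogram for ``target_mz``.

    The window is symmetric and inclusive: centroids with
    ``|mz - target| / target * 1e6 <= ppm_tol`` are summed per MS1
    spectrum; spectra with no matching centroid contribute intensity 0.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    ms1 = run.ms1
    if not ms1:
        raise ValueError("run contains no MS1 spectra")
    half = target_mz * ppm_tol * 1e-6
    lo, hi = target_mz - half, target_mz + half
    rts = np.empty(len(ms1))
    intensities = np.zeros(len(ms1))
    for i, spec in enumerate(ms1):
        rts[i] = spec.rt
        a = np.searchsorted(spec.mz, lo, side="left")
        b = np.searchsorted(spec.mz, hi, side="right")
        if b > a:
            intensities[i] = spec.intensity[a:b].sum()
    return Chromatogram(rt=rts, intensity=intensities)


def integrate_peak(
    chrom: Chromatogram,
    expected_rt: float,
    rt_tol: float,
    compound_id: str = "",
) -> IntegratedPeak | None:
    """Integrate the peak nearest ``expected_rt`` within ``+-rt_tol``.

    The apex is the maximum intensity inside the window (ties broken by
    proximity to the expected RT, then earlier RT); integration bounds
    walk outward from the apex to the nearest local minimum or window
    edge; the area is the trapezoidal integral. Returns None ("missing")
    when the window is empty or the apex intensity is 0. No baseline
    subtraction is applied.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be > 0")
    if chrom.rt.size == 0:
        return None
    mask = (chrom.rt >= expected_rt - rt_tol) & (chrom.rt <= expected_rt + rt_tol)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    rt = chrom.rt[idx]
    y = chrom.intensity[idx]
    peak_max = y.max()
    if peak_max <= 0:
        return None
    # deterministic apex: max intensity, closest to expected RT, earliest RT
    candidates = np.flatnonzero(y == peak_max)
    apex = min(candidates, key=lambda i: (abs(rt[i] - expected_rt), rt[i]))
    left = apex
    while left > 0 and y[left - 1] <= y[left]:
        left -= 1
    right = apex
    while right < y.size - 1 and y[right + 1] <= y[right]:
        right += 1
    if right == left:
        area = 0.0
    else:
        area = float(np.trapezoid(y[left:right + 1], rt[left:right + 1]))
    return IntegratedPeak(
        compound_id=compound_id,
        apex_rt=float(rt[apex]),
        rt_start=float(rt[left]),
        rt_end=float(rt[right]),
        area=area,
        apex_intensity=float(peak_max),
    )


def quantify_run(
    run: MSRun,
    library: list[CompoundEntry],
    config: PipelineConfig | None = None,
    sample_id: str | None = None,
) -> pd.Series:
    """Quantify every library compound in one run.

    Returns a Series indexed by compound id: integrated area, or NaN for
    compounds with no detectable peak.
    """
    if not library:
        raise ValueError("empty compound library")
    ids = [c.compound_id for c in library]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate compound ids in library: {dupes}")
    config = config or PipelineConfig()
    areas = {}
    for entry in library:
        chrom = extract_xic(run, entry.mz(), config.ppm_tol)
        rt_tol = entry.rt_tol if entry.rt_tol > 0 else config.rt_tol
        peak = integrate_peak(chrom, entry.rt, rt_tol, entry.compound_id)
        areas[entry.compound_id] = peak.area if peak is not None else np.nan
    return pd.Series(areas, name=sample_id or run.run_id)


def quantify_runs(
    runs: list[MSRun],
    library: list[CompoundEntry],
    config: PipelineConfig | None = None,
    samples: list[SampleMeta] | None = None,
) -> PeakTable:
    """Stack :func:`quantify_run` rows into a :class:`PeakTable`."""
    rows = [quantify_run(run, library, config) for run in runs]
    df = pd.DataFrame(rows)
    df.index = [run.run_id for run in runs]
    return PeakTable(df, samples=samples, compounds=library)


def ms2_cosine(a: Spectrum, b: Spectrum, frag_tol: float = 0.01) -> float:
    """Cosine similarity between two MS2 spectra.

    Fragments are matched greedily one-to-one, best (highest intensity
    product, then smallest m/z difference) pairs first, within
    ``frag_tol`` Da. Unmatched fragments pair with zero. Symmetric in its
    arguments and bounded in [0, 1].
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be > 0")
    for spec in (a, b):
        if spec.ms_level != 2:
            raise ValueError("ms2_cosine requires MS2 spectra")
    if a.mz.size == 0 or b.mz.size == 0:
        warnings.warn("empty MS2 spectrum; cosine similarity is 0",
                      UserWarning, stacklevel=2)
        return 0.0
    pairs = []
    for i in range(a.mz.size):
        for j in range(b.mz.size):
            d = abs(a.mz[i] - b.mz[j])
            if d <= frag_tol:
                pairs.append((a.intensity[i] * b.intensity[j], -d, i, j))
    pairs.sort(key=lambda p: (-p[0], -p[1], p[2], p[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for product, _negd, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += product
    norm = math.sqrt(float(np.sum(a.intensity ** 2))) * \
        math.sqrt(float(np.sum(b.intensity ** 2)))
    if norm == 0:
        warnings.warn("zero-intensity MS2 spectrum; cosine similarity is 0",
                      UserWarning, stacklevel=2)
        return 0.0
    return min(1.0, dot / norm)
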