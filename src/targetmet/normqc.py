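"""Normalization and quality control.

The four-step procedure applied to assembled peak tables, in fixed order:

1. combine per-run peak areas (done upstream in :mod:`targetmet.xic`);
2. normalize each sample by an averaged factor over mean-centered
   internal-standard areas;
3. filter compounds on pooled-reinjection CV and pool-dilution linearity
   (strict cutoffs, default CV < 30%, R^2 > 0.95);
4. normalize for biological material amount by total integrated area of
   the compounds that survived filtering.

Thyroid-hormone relative abundance is computed separately as the
analyte / paired-isotope-labeled-IS area ratio, which cancels per-sample
multiplicative matrix effects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msio import PeakTable, PipelineConfig, warn_and_log

__all__ = [
    "NormalizationFactors",
    "QCReport",
    "is_factors",
    "apply_factors",
    "pooled_cv",
    "dilution_linearity",
    "qc_filter",
    "total_signal_normalize",
    "th_relative_abundance",
]

#: sample types that define the run-wide mean for IS mean-centering and
#: the target mean total signal; blanks/mocks/standards never contribute.
_CENTERING_TYPES = ("study", "pool")


@dataclass
class NormalizationFactors:
    """Per-sample IS normalization factors (divide areas by ``factors``)."""

    factors: pd.Series
    is_used: list[str]
    is_means: dict[str, float]

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("normalization factors must be finite and > 0")
        if not self.is_used:
            raise ValueError("at least one internal standard required")


@dataclass
class QCReport:
    """Per-compound QC metrics and the filtering outcome."""

    cv: dict[str, float]
    rsq: dict[str, float]
    passed: dict[str, bool]
    reason: dict[str, str]
    cv_cutoff: float
    rsq_cutoff: float
    n_kept: int = 0
    n_dropped: int = 0
    is_compounds: list[str] = field(default_factory=list)
    factors: dict[str, float] | None = None

    def to_json(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["cv"] = {k: (None if np.isnan(v) else v) for k, v in self.cv.items()}
        d["rsq"] = {k: (None if np.isnan(v) else v) for k, v in self.rsq.items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


def _centering_samples(table: PeakTable) -> list[str]:
    if table.samples is None:
        return table.sample_ids
    ids = table.samples_of_type(*_CENTERING_TYPES)
    return ids if ids else table.sample_ids


def is_factors(table: PeakTable) -> NormalizationFactors:
    """Per-sample normalization factors from internal-standard areas.

    For IS compound s and sample j, ``r_sj = area_sj / mean_s`` where
    ``mean_s`` is the arithmetic mean of s over study + pool samples;
    ``f_j`` is the arithmetic mean of ``r_sj`` over usable IS. IS with
    any missing value are dropped with a warning.
    """
    is_ids = table.is_compound_ids()
    if not is_ids:
        raise ValueError("no internal-standard compounds in library")
    center_ids = _centering_samples(table)
    usable: list[str] = []
    for cid in is_ids:
        col = table.areas[cid]
        if col.isna().any() or (col <= 0).any():
            warn_and_log(
                f"internal standard {cid!r} has missing/zero areas; "
                "dropped from normalization"
            )
            continue
        usable.append(cid)
    if not usable:
        raise ValueError("no internal standard is complete across samples")
    sub = table.areas[usable]
    means = sub.loc[center_ids].mean(axis=0)
    ratios = sub / means
    factors = ratios.mean(axis=1)
    return NormalizationFactors(
        factors=factors,
        is_used=usable,
        is_means={cid: float(means[cid]) for cid in usable},
    )


def apply_factors(table: PeakTable, factors: NormalizationFactors) -> PeakTable:
    """Divide every area in sample j by its factor f_j."""
    normalized = table.areas.div(factors.factors, axis=0)
    return table.with_areas(normalized)


def pooled_cv(table: PeakTable) -> pd.Series:
    """Percent CV of each compound over undiluted pool reinjections.

    CV = 100 * unbiased-sd / mean over non-missing pool areas; NaN
    (compound will fail QC) when fewer than two values remain or the
    mean is 0.
    """
    pool_ids = table.samples_of_type("pool")
    if len(pool_ids) < 2:
        raise ValueError(
            f"need >= 2 undiluted pool injections, found {len(pool_ids)}"
        )
    sub = table.areas.loc[pool_ids]
    out = {}
    for cid in table.compound_ids:
        vals = sub[cid].dropna()
        vals = vals[vals != 0]
        if len(vals) < 2 or vals.mean() == 0:
            out[cid] = np.nan
        else:
            out[cid] = 100.0 * vals.std(ddof=1) / vals.mean()
    return pd.Series(out)


def dilution_linearity(table: PeakTable) -> pd.Series:
    """R^2 of OLS (with intercept) of area on relative pool concentration.

    Pool samples count as relative concentration 1; pool dilutions use
    their dilution factor (e.g. 1/3, 1/10). NaN when the response is
    constant or fewer than 3 points remain.
    """
    ids = table.samples_of_type("pool", "pool_dilution")
    conc = pd.Series(
        {sid: table.meta(sid).dilution_factor for sid in ids}, dtype=float
    )
    if conc.nunique() < 3:
        raise ValueError(
            f"need >= 3 distinct relative concentrations, found {conc.nunique()}"
        )
    sub = table.areas.loc[ids]
    out = {}
    for cid in table.compound_ids:
        y = sub[cid].dropna()
        x = conc[y.index]
        if len(y) < 3 or x.nunique() < 3 or y.nunique() == 1:
            out[cid] = np.nan
            continue
        xv = x.to_numpy()
        yv = y.to_numpy()
        design = np.column_stack([xv, np.ones_like(xv)])
        coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
        resid = yv - design @ coef
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        if ss_tot == 0:
            out[cid] = np.nan
            continue
        out[cid] = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return pd.Series(out)


def qc_filter(
    table: PeakTable,
    cv: pd.Series,
    rsq: pd.Series,
    config: PipelineConfig | None = None,
) -> tuple[PeakTable, QCReport]:
    """Keep compounds with CV < cutoff and R^2 > cutoff (strict, both
    computable). Internal standards are always retained but flagged, and
    never count as kept metabolites."""
    config = config or PipelineConfig()
    missing = (set(table.compound_ids) - set(cv.index)) | \
        (set(table.compound_ids) - set(rsq.index))
    if missing:
        raise ValueError(f"QC metrics missing for compounds: {sorted(missing)}")
    is_ids = set(table.is_compound_ids())
    passed: dict[str, bool] = {}
    reason: dict[str, str] = {}
    for cid in table.compound_ids:
        c, r = cv[cid], rsq[cid]
        problems = []
        if np.isnan(c):
            problems.append("CV not computable")
        elif c >= config.cv_cutoff:
            problems.append(f"CV {c:.1f}% >= {config.cv_cutoff:g}%")
        if np.isnan(r):
            problems.append("dilution R^2 not computable")
        elif r <= config.rsq_cutoff:
            problems.append(f"R^2 {r:.3f} <= {config.rsq_cutoff:g}")
        passed[cid] = not problems
        reason[cid] = "ok" if not problems else "; ".join(problems)
        if cid in is_ids:
            reason[cid] += " [internal standard: retained]"
    keep = [cid for cid in table.compound_ids
            if passed[cid] or cid in is_ids]
    kept_lib = None
    if table.compounds is not None:
        kept_lib = [c for c in table.compounds if c.compound_id in keep]
    kept = PeakTable(table.areas[keep], table.samples, kept_lib)
    n_kept = sum(1 for cid in keep if cid not in is_ids)
    report = QCReport(
        cv={k: float(v) for k, v in cv.items()},
        rsq={k: float(v) for k, v in rsq.items()},
        passed=passed,
        reason=reason,
        cv_cutoff=config.cv_cutoff,
        rsq_cutoff=config.rsq_cutoff,
        n_kept=n_kept,
        n_dropped=len([c for c in table.compound_ids if c not in is_ids])
        - n_kept,
        is_compounds=sorted(is_ids),
    )
    return kept, report


def total_signal_normalize(
    table: PeakTable, kept_ids: list[str] | None = None
) -> PeakTable:
    """Scale each sample so totals over kept non-IS compounds are equal.

    ``t_j`` is the sum of kept non-IS areas in sample j (missing values
    excluded); sample j is multiplied by ``mean(t) / t_j`` where the mean
    runs over study + pool samples. Samples with ``t_j = 0`` are flagged
    and left unscaled.
    """
    is_ids = set(table.is_compound_ids())
    if kept_ids is None:
        kept_ids = [c for c in table.compound_ids if c not in is_ids]
    signal_ids = [c for c in kept_ids if c not in is_ids]
    if not signal_ids:
        raise ValueError("no kept non-IS compounds to normalize on")
    totals = table.areas[signal_ids].sum(axis=1, skipna=True)
    center_ids = _centering_samples(table)
    ref = totals.loc[center_ids]
    ref = ref[ref > 0]
    if ref.empty:
        raise ValueError("all sample totals are zero")
    target = ref.mean()
    scale = target / totals
    bad = totals == 0
    if bad.any():
        warn_and_log(
            f"samples with zero total signal left unscaled: "
            f"{sorted(totals.index[bad])}"
        )
        scale[bad] = 1.0
    return table.with_areas(table.areas.mul(scale, axis=0))


def th_relative_abundance(
    table: PeakTable, analyte_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-sample analyte / paired-IS area ratios (isotope dilution).

    Requires each analyte's library entry to name its isotope-labeled IS
    via ``is_pair`` and all compared samples to share the same injection
    volume. Zero or missing areas propagate as missing ratios (never 0).
    """
    if table.compounds is None:
        raise ValueError("compound library required for IS pairing")
    if analyte_ids is None:
        analyte_ids = [
            c.compound_id for c in table.compounds
            if c.is_pair and not c.is_internal_standard
        ]
    if not analyte_ids:
        raise ValueError("no analytes with an IS pairing in the library")
    if table.samples is not None:
        vols = {s.volume_ul for s in table.samples
                if s.sample_type == "study"}
        if len(vols) > 1:
            raise ValueError(
                f"equal-volume comparison required; volumes seen: {sorted(vols)}"
            )
    out = {}
    for aid in analyte_ids:
        entry = table.entry(aid)
        if not entry.is_pair:
            raise ValueError(f"analyte {aid!r} has no paired internal standard")
        pair = table.entry(entry.is_pair)
        if not pair.is_internal_standard:
            raise ValueError(
                f"{aid!r} pairs to {entry.is_pair!r} which is not IS-flagged"
            )
        analyte = table.areas[aid].replace(0, np.nan)
        ref = table.areas[entry.is_pair].replace(0, np.nan)
        if ref.isna().any():
            warn_and_log(
                f"IS {entry.is_pair!r} missing in samples "
                f"{sorted(ref.index[ref.isna()])}; ratios flagged missing"
            )
        out[aid] = analyte / ref
    return pd.DataFrame(out)
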