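"""Synthetic-study generator with serialized ground truth.

Emulates the structure of a targeted small-volume biofluid study:
per-sample multiplicative matrix factors, isotope-labeled internal
standards spiked at constant level per injection, pooled-QC reinjections
with 3-/10-fold dilutions, blanks/mocks, planted group effects
(embryo-elevated T3, pregnancy-elevated T4, freeze-labile
nucleotide-salvage metabolites) and planted QC failures (high pool CV,
saturating dilution response). Everything is reproducible from the seed
and the serialized :class:`StudyTruth`.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DilutionSeries
from .msio import CompoundEntry, PeakTable, SampleMeta
from .mzml import MSRun, Spectrum

__all__ = [
    "ScenarioConfig",
    "StudyTruth",
    "default_library",
    "simulate_study",
    "simulate_dilution_series",
    "simulate_run_from_areas",
]

# mass shift of six 13C substitutions, used for the labeled T3/T4 IS targets
_13C6_SHIFT = 6 * 1.0033548378


@dataclass
class ScenarioConfig:
    """Knobs of the simulated study; defaults mirror the study scale."""

    groups: dict[str, int] = field(default_factory=lambda: {
        "embryo": 6, "adult_male": 6, "adult_female": 6, "pregnant": 6,
    })
    n_metabolites: int = 200          # well-behaved metabolites
    n_is: int = 15                    # amino-acid-style IS panel
    n_bad_cv: int = 0                 # planted high-pool-CV compounds
    n_bad_linear: int = 0             # planted saturating-dilution compounds
    n_pools: int = 5
    dilution_factors: tuple[float, ...] = (1 / 3, 1 / 10)
    dilution_replicates: int = 2
    n_blanks: int = 2
    n_mocks: int = 2
    noise_cv: float = 0.05            # lognormal multiplicative CV
    matrix_sd: float = 0.25           # sdlog of matrix factors
    baseline: float = 0.0             # additive baseline scale
    missing_rate: float = 0.0
    t3_embryo_fold: float = 5.0
    t4_pregnant_fold: float = 3.0
    labile_fold: float = 4.0          # frozen-sample salvage-metabolite shift
    n_labile: int = 8
    peak_sigma: float = 0.05          # minutes, for raw-run synthesis
    scan_dt: float = 0.01             # minutes between MS1 scans
    volume_ul: float = 5.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.groups.values()):
            raise ValueError("every group needs at least one sample")
        if not all(0 < f <= 1 for f in self.dilution_factors):
            raise ValueError("dilution factors must be in (0, 1]")


@dataclass
class StudyTruth:
    """Ground truth sufficient to recompute every expected output."""

    seed: int
    base_conc: dict[str, float]               # compound -> baseline conc
    group_effect: dict[str, dict[str, float]]  # group -> compound -> fold
    matrix_factors: dict[str, float]          # sample -> m_j
    is_spikes: dict[str, float]               # IS compound -> spike level
    pool_conc: dict[str, float]               # compound -> pooled conc
    labile: list[str]
    bad_cv: list[str]
    bad_linear: list[str]
    noise_cv: float
    baseline: float

    def true_conc(self, group: str, compound: str) -> float:
        eff = self.group_effect.get(group, {}).get(compound, 1.0)
        return self.base_conc[compound] * eff

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "StudyTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def default_library(config: ScenarioConfig, rng: np.random.Generator
                    ) -> list[CompoundEntry]:
    """Compound library: T3/T4 + labeled IS pairs, an IS panel, metabolites
    and any planted QC-failure compounds."""
    from . import chem

    t3_mz = chem.resolve_mz("C15H12I3NO4", "[M+H]+")
    t4_mz = chem.resolve_mz("C15H11I4NO4", "[M+H]+")
    entries = [
        CompoundEntry("T3", name="triiodothyronine", formula="C15H12I3NO4",
                      adduct="[M+H]+", rt=9.0, rt_tol=0.4, is_pair="T3_IS"),
        CompoundEntry("T4", name="thyroxine", formula="C15H11I4NO4",
                      adduct="[M+H]+", rt=9.6, rt_tol=0.4, is_pair="T4_IS"),
        CompoundEntry("T3_IS", name="13C6-T3", target_mz=t3_mz + _13C6_SHIFT,
                      rt=9.0, rt_tol=0.4, is_internal_standard=True),
        CompoundEntry("T4_IS", name="13C6-T4", target_mz=t4_mz + _13C6_SHIFT,
                      rt=9.6, rt_tol=0.4, is_internal_standard=True),
    ]
    used_mz = [t3_mz, t4_mz, t3_mz + _13C6_SHIFT, t4_mz + _13C6_SHIFT]

    def fresh_mz() -> float:
        while True:
            mz = float(rng.uniform(80.0, 900.0))
            if all(abs(mz - u) / u > 50e-6 for u in used_mz):
                used_mz.append(mz)
                return mz

    def fresh_rt() -> float:
        return float(rng.uniform(1.0, 18.0))

    for i in range(config.n_is):
        entries.append(CompoundEntry(
            f"is_{i + 1:02d}", name=f"labeled IS {i + 1}",
            target_mz=fresh_mz(), rt=fresh_rt(), rt_tol=0.4,
            is_internal_standard=True,
        ))
    for i in range(config.n_metabolites):
        entries.append(CompoundEntry(
            f"met_{i + 1:03d}", name=f"metabolite {i + 1}",
            target_mz=fresh_mz(), rt=fresh_rt(), rt_tol=0.4,
        ))
    for i in range(config.n_bad_cv):
        entries.append(CompoundEntry(
            f"bad_cv_{i + 1:02d}", name=f"unstable compound {i + 1}",
            target_mz=fresh_mz(), rt=fresh_rt(), rt_tol=0.4,
        ))
    for i in range(config.n_bad_linear):
        entries.append(CompoundEntry(
            f"bad_lin_{i + 1:02d}", name=f"saturating compound {i + 1}",
            target_mz=fresh_mz(), rt=fresh_rt(), rt_tol=0.4,
        ))
    return entries


def _sample_plan(config: ScenarioConfig) -> list[SampleMeta]:
    samples: list[SampleMeta] = []
    order = 0
    for group, size in config.groups.items():
        for i in range(size):
            order += 1
            samples.append(SampleMeta(
                sample_id=f"{group}_{i + 1:02d}", group=group,
                sample_type="study", injection_order=order,
                volume_ul=config.volume_ul,
            ))
    for i in range(config.n_pools):
        order += 1
        samples.append(SampleMeta(
            sample_id=f"pool_{i + 1:02d}", group="pool", sample_type="pool",
            injection_order=order, volume_ul=config.volume_ul,
        ))
    for f in config.dilution_factors:
        for i in range(config.dilution_replicates):
            order += 1
            samples.append(SampleMeta(
                sample_id=f"pool_d{round(1 / f)}_{i + 1:02d}", group="pool",
                sample_type="pool_dilution", dilution_factor=f,
                injection_order=order, volume_ul=config.volume_ul,
            ))
    for i in range(config.n_blanks):
        order += 1
        samples.append(SampleMeta(
            sample_id=f"blank_{i + 1:02d}", group="blank",
            sample_type="blank", injection_order=order,
            volume_ul=config.volume_ul,
        ))
    for i in range(config.n_mocks):
        order += 1
        samples.append(SampleMeta(
            sample_id=f"mock_{i + 1:02d}", group="mock", sample_type="mock",
            injection_order=order, volume_ul=config.volume_ul,
        ))
    return samples


def simulate_study(
    config: ScenarioConfig, seed: int
) -> tuple[PeakTable, StudyTruth]:
    """Generate a full study peak table plus its ground truth.

    Areas follow ``true_conc * matrix_factor * dilution * lognormal-noise
    + baseline``; analyte/IS pairs share the sample's matrix factor, so
    isotope-dilution ratios cancel it. The embryo group gets elevated T3,
    the pregnant group elevated T4, and any group whose name ends in
    ``_frozen`` gets the labile (nucleotide-salvage-like) compounds
    shifted by ``labile_fold``.
    """
    rng = np.random.default_rng(seed)
    library = default_library(config, rng)
    samples = _sample_plan(config)
    compound_ids = [c.compound_id for c in library]
    is_ids = {c.compound_id for c in library if c.is_internal_standard}
    met_ids = [c for c in compound_ids if c not in is_ids]

    base_conc = {
        cid: float(10 ** rng.uniform(3.5, 6.0)) for cid in met_ids
    }
    labile = [f"met_{i + 1:03d}"
              for i in range(min(config.n_labile, config.n_metabolites))]
    group_effect: dict[str, dict[str, float]] = {}
    for group in config.groups:
        eff: dict[str, float] = {}
        if group == "embryo":
            eff["T3"] = config.t3_embryo_fold
        if group == "pregnant":
            eff["T4"] = config.t4_pregnant_fold
        if group.endswith("_frozen"):
            for cid in labile:
                eff[cid] = config.labile_fold
        group_effect[group] = eff

    # always draw so the rng stream is identical across matrix_sd settings
    matrix_factors = {
        s.sample_id: float(rng.lognormal(0.0, config.matrix_sd))
        for s in samples
    }
    is_spikes = {cid: float(10 ** rng.uniform(4.0, 5.0)) for cid in is_ids}

    # pooled aliquot: sample-size-weighted mean of group concentrations
    total_n = sum(config.groups.values())
    pool_conc = {}
    for cid in met_ids:
        acc = 0.0
        for group, size in config.groups.items():
            acc += size * base_conc[cid] * group_effect[group].get(cid, 1.0)
        pool_conc[cid] = acc / total_n

    sdlog = np.sqrt(np.log1p(config.noise_cv ** 2)) if config.noise_cv else 0.0

    def noise(extra_sdlog: float = 0.0) -> float:
        s = np.sqrt(sdlog ** 2 + extra_sdlog ** 2)
        return float(rng.lognormal(0.0, s)) if s > 0 else 1.0

    bad_cv = [c for c in compound_ids if c.startswith("bad_cv_")]
    bad_linear = [c for c in compound_ids if c.startswith("bad_lin_")]

    rows = {}
    for s in samples:
        m = matrix_factors[s.sample_id]
        row = {}
        for cid in compound_ids:
            extra = 0.8 if cid in bad_cv else 0.0
            if cid in is_ids:
                # IS spiked at reconstitution: constant per injection
                area = is_spikes[cid] * m * noise()
            elif s.sample_type == "study":
                conc = base_conc[cid] * group_effect[s.group].get(cid, 1.0)
                area = conc * m * noise(extra)
                if (config.missing_rate > 0 and cid.startswith("met_")
                        and rng.uniform() < config.missing_rate):
                    area = np.nan
            elif s.sample_type in ("pool", "pool_dilution"):
                if cid in bad_linear:
                    # detector saturation: flat response across dilutions
                    area = pool_conc[cid] * m * noise()
                else:
                    area = (pool_conc[cid] * s.dilution_factor * m
                            * noise(extra))
            else:  # blank / mock: carryover-free background
                area = config.baseline * float(rng.uniform(0.0, 1.0)) \
                    if config.baseline > 0 else np.nan
            if config.baseline > 0 and np.isfinite(area) \
                    and s.sample_type not in ("blank", "mock"):
                area += config.baseline * float(rng.uniform(0.0, 1.0))
            row[cid] = area
        rows[s.sample_id] = row

    areas = pd.DataFrame.from_dict(rows, orient="index")
    areas = areas.loc[[s.sample_id for s in samples], compound_ids]
    table = PeakTable(areas, samples=samples, compounds=library)
    truth = StudyTruth(
        seed=seed,
        base_conc=base_conc,
        group_effect=group_effect,
        matrix_factors=matrix_factors,
        is_spikes=is_spikes,
        pool_conc=pool_conc,
        labile=labile,
        bad_cv=bad_cv,
        bad_linear=bad_linear,
        noise_cv=config.noise_cv,
        baseline=config.baseline,
    )
    return table, truth


def simulate_dilution_series(
    lod_nM: float,
    noise_sigma: float,
    levels: np.ndarray | list[float] | None = None,
    replicates: int = 5,
    seed: int = 0,
    slope: float | None = None,
    blank_mean: float = 50.0,
    compound_id: str = "standard",
) -> DilutionSeries:
    """Dilution series with a planted detection limit.

    Above ``lod_nM`` the response is linear (``blank + slope * conc``);
    below it the signal collapses to blank level. Additive Gaussian noise
    of standard deviation ``noise_sigma`` applies everywhere. Blanks are
    generated with ``replicates`` injections at concentration 0.
    """
    if lod_nM <= 0:
        raise ValueError("lod_nM must be > 0")
    rng = np.random.default_rng(seed)
    if levels is None:
        levels = lod_nM * 2.0 ** np.arange(-3, 6)  # 2-fold ladder
    levels = np.asarray(sorted(levels), dtype=float)
    if levels.size < 5 or levels.min() >= lod_nM or levels.max() <= lod_nM:
        raise ValueError(
            "need >= 5 levels spanning above and below the planted LOD"
        )
    if slope is None:
        # signal at the LOD sits 20 noise-sd above blank (or unit if exact)
        slope = (20.0 * noise_sigma if noise_sigma > 0 else 1.0) / lod_nM
    concs = []
    areas = []
    for _ in range(replicates):
        concs.append(0.0)
        areas.append(blank_mean + rng.normal(0.0, noise_sigma)
                     if noise_sigma > 0 else blank_mean)
    for c in levels:
        for _ in range(replicates):
            signal = slope * c if c >= lod_nM else 0.0
            a = blank_mean + signal
            if noise_sigma > 0:
                a += rng.normal(0.0, noise_sigma)
            concs.append(float(c))
            areas.append(float(a))
    return DilutionSeries(
        compound_id=compound_id,
        concentration=np.array(concs),
        area=np.array(areas),
    )


def _ms2_fragments(precursor_mz: float, collision_energy: float,
                   n: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pseudo-fragment spectrum for a precursor."""
    fracs = np.linspace(0.15, 0.92, n)
    mz = precursor_mz * fracs
    # harder fragmentation pushes intensity to low-mass fragments
    weight = np.exp(-fracs * collision_energy / 20.0)
    intensity = 1000.0 * weight / weight.max()
    return mz, intensity


def simulate_run_from_areas(
    areas: pd.Series | dict[str, float],
    library: list[CompoundEntry],
    peak_sigma: float = 0.05,
    scan_dt: float = 0.01,
    seed: int = 0,
    run_id: str = "sim",
    mz_jitter_ppm: float = 0.3,
    baseline_peaks: int = 3,
    baseline_intensity: float = 5.0,
    add_ms2: bool = False,
    ms2_energies: tuple[float, float] = (20.0, 40.0),
) -> MSRun:
    """Write a centroided MS1 run whose integrated peaks match ``areas``.

    Each compound elutes as a Gaussian of width ``peak_sigma`` centered
    at its library RT, with apex m/z jittered by ``mz_jitter_ppm``;
    low-intensity random baseline centroids are sprinkled per scan.
    Compounds within 5 ppm and overlapping RT trigger a warning (planted
    isomer stress test). With ``add_ms2`` two MS2 spectra per compound
    are appended at its apex RT, one per collision energy.
    """
    rng = np.random.default_rng(seed)
    areas = pd.Series(areas, dtype=float)
    lib = {c.compound_id: c for c in library}
    missing = set(areas.index) - set(lib)
    if missing:
        raise ValueError(f"areas given for unknown compounds: {sorted(missing)}")
    active = [(lib[cid], float(areas[cid])) for cid in areas.index
              if np.isfinite(areas[cid]) and areas[cid] > 0]
    for i in range(len(active)):
        for j in range(i + 1, len(active)):
            a, b = active[i][0], active[j][0]
            if (abs(a.mz() - b.mz()) / a.mz() * 1e6 <= 5.0
                    and abs(a.rt - b.rt) <= 4 * peak_sigma):
                warnings.warn(
                    f"compounds {a.compound_id!r} and {b.compound_id!r} "
                    "overlap within 5 ppm and retention time",
                    UserWarning, stacklevel=2,
                )
    rts = [e.rt for e, _ in active] or [c.rt for c in library]
    t0 = max(0.0, min(rts) - 6 * peak_sigma - 0.1)
    t1 = max(rts) + 6 * peak_sigma + 0.1
    grid = np.arange(t0, t1 + scan_dt / 2, scan_dt)
    spectra: list[Spectrum] = []
    sqrt2pi = np.sqrt(2.0 * np.pi)
    for t in grid:
        mzs: list[float] = []
        ints: list[float] = []
        for entry, area in active:
            dt = t - entry.rt
            if abs(dt) > 5 * peak_sigma:
                continue
            amp = area / (peak_sigma * sqrt2pi)
            y = amp * np.exp(-0.5 * (dt / peak_sigma) ** 2)
            jitter = rng.normal(0.0, mz_jitter_ppm) * 1e-6
            mzs.append(entry.mz() * (1.0 + jitter))
            ints.append(float(y))
        for _ in range(baseline_peaks):
            mzs.append(float(rng.uniform(70.0, 1000.0)))
            ints.append(float(rng.exponential(baseline_intensity)))
        order = np.argsort(mzs)
        mz_arr = np.asarray(mzs)[order]
        int_arr = np.asarray(ints)[order]
        # merge (vanishingly rare) centroid collisions to keep mz strict
        keep_mz: list[float] = []
        keep_int: list[float] = []
        for mz, inten in zip(mz_arr, int_arr):
            if keep_mz and mz <= keep_mz[-1]:
                keep_int[-1] += inten
            else:
                keep_mz.append(float(mz))
                keep_int.append(float(inten))
        spectra.append(Spectrum(
            rt=float(t), ms_level=1, mz=np.array(keep_mz),
            intensity=np.array(keep_int), polarity="+",
        ))
    if add_ms2:
        ms2: list[Spectrum] = []
        for entry, _area in active:
            for ce in ms2_energies:
                mz, inten = _ms2_fragments(entry.mz(), ce)
                ms2.append(Spectrum(
                    rt=entry.rt, ms_level=2, mz=mz, intensity=inten,
                    polarity="+", precursor_mz=entry.mz(),
                    collision_energy=ce,
                ))
        spectra = sorted(spectra + ms2, key=lambda s: s.rt)
    return MSRun(run_id=run_id, spectra=spectra, polarity="+")
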