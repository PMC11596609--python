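"""Synthetic honey-adulteration cohort: compound libraries, mixtures, devices, runs.

The study design this emulates: a few dozen authentic honeys, each
blended with three sugar syrups — rice, beet and high-fructose corn
syrup (HFCS) — at 5/10/20/50/80 % v/v, every blend acquired on one of
three LC-HRMS devices in two chromatographic modes (HILIC negative, RP
positive). Because the real measurements are proprietary, this module
generates a compound-level stand-in with the features that make the
problem what it is:

* a shared-sugar block: glucose/fructose-like compounds that dominate
  both honey and HFCS (~35 % of abundance mass each) but are minor in
  rice and beet syrup (~5 %) — the compositional-similarity gradient
  that makes HFCS the hard adulterant;
* honey-specific compounds with per-honey log-normal abundance
  variation (the natural diversity of authentic honeys);
* syrup-specific blocks: strong for rice and beet, weak and
  near-the-noise-floor for HFCS, whose practical signature is mostly a
  shift in composition rather than unique markers;
* ubiquitous background compounds present in everything;
* device effects (retention-time shift, intensity gain, m/z offset)
  strong enough to dominate unsupervised structure, plus run-level
  multiplicative noise, RT jitter and random noise peaks.

Mixing is linear in abundance: the samples are equal-concentration
solutions blended by volume, so a p-mixture's compound abundances are
``(1-p)*honey + p*syrup`` exactly.

Every run is rendered independently from a seed derived from (cohort
seed, scenario, sample, mode), so a run's spectra never depend on what
else is in the batch, and regeneration is reproducible file-by-file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .spectra_io import CANONICAL_WINDOWS, MODES, CentroidSpectrum, LcmsRun, write_run

__all__ = [
    "Compound",
    "CompoundProfile",
    "DeviceEffect",
    "CohortDesign",
    "Library",
    "make_library",
    "mix_profiles",
    "render_run",
    "sample_table",
    "iter_runs",
    "make_cohort",
    "paper_design",
    "ci_small_design",
]


@dataclass(frozen=True)
class Compound:
    """One ionizable compound: its m/z, per-mode elution apex, width and abundance."""

    id: str
    mz: float
    rt_mode: Mapping[str, float]  # mode -> apex seconds
    peak_sd: float  # chromatographic sd, seconds
    base_abundance: float  # arbitrary units


@dataclass
class CompoundProfile:
    """Per-sample compound abundances (arbitrary units)."""

    sample_id: str
    abundances: dict[str, float]


@dataclass(frozen=True)
class DeviceEffect:
    """Systematic distortions of one acquisition device."""

    device_id: str
    rt_shift: float = 0.0  # seconds
    rt_stretch: float = 1.0
    intensity_gain: float = 1.0
    mz_offset_ppm: float = 0.0
    noise_floor: float = 1000.0  # typical intensity of spurious peaks


IDENTITY_DEVICE = DeviceEffect(device_id="identity")

#: Template composition (fraction of total abundance mass per block).
_HONEY_BLOCKS = {"shared": 0.35, "honey": 0.45, "ubiquitous": 0.20}
#: Syrup-specific (unique-marker) mass fraction per syrup; the remainder
#: beyond the shared-sugar fraction goes to the ubiquitous block. HFCS is
#: glucose/fructose plus oligosaccharides honey also carries - it has no
#: unique markers, only a compositional shift.
_SYRUP_UNIQUE = {"rice": 0.75, "beet": 0.75, "hfcs": 0.0}


@dataclass
class CohortDesign:
    """The study design and all generator knobs.

    ``similarity`` is the shared-sugar abundance fraction of each syrup
    (HFCS honey-like at ~0.35, rice/beet ~0.05). The acquisition scale
    (RT spans, scan interval, library size) defaults to a desk-scale
    setting that preserves the design's structure at a fraction of the
    paper-scale RT span; spans are multiples of the 20 s bucket width.
    """

    n_honeys: int = 34
    syrups: tuple[str, ...] = ("rice", "beet", "hfcs")
    proportions: tuple[float, ...] = (5.0, 10.0, 20.0, 50.0, 80.0)
    n_devices: int = 3
    modes: tuple[str, ...] = MODES
    similarity: Mapping[str, float] = field(
        default_factory=lambda: {"rice": 0.05, "beet": 0.05, "hfcs": 0.35}
    )
    seed: int = 0

    # acquisition scale
    rt_span: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"HILIC_neg": (0.0, 200.0), "RP_pos": (0.0, 240.0)}
    )
    scan_interval: float = 1.0
    mz_range: tuple[float, float] = (100.0, 1500.0)

    # library sizes per block (compounds are shared across modes)
    n_shared: int = 60
    n_honey_block: int = 120
    n_syrup_block: int = 60
    n_ubiquitous: int = 60

    # variability
    honey_variation_sd: float = 0.4  # log-scale, honey-block compounds
    context_variation_sd: float = 0.2  # log-scale, shared/ubiquitous in honeys
    block_scale_sd: float = 0.15  # log-scale, per-honey whole-block composition
    run_noise_sd: float = 0.15  # log-scale multiplicative, per compound per run
    rt_jitter_sd: float = 1.0  # seconds, per compound per run
    mz_jitter_ppm: float = 1.5
    n_noise_peaks: int = 50
    min_intensity: float = 200.0  # rendering/detection cutoff, counts
    total_abundance: float = 1e8

    # optional features
    render_ms2: bool = False
    plant_empty_rp: bool = False  # render one 50 %-level RP run signal-free

    def device_effects(self) -> list[DeviceEffect]:
        """Three archetypal devices; cycled if ``n_devices`` differs."""
        base = [
            DeviceEffect("dev1", rt_shift=-15.0, intensity_gain=0.7, mz_offset_ppm=-3.0),
            DeviceEffect("dev2", rt_shift=0.0, intensity_gain=1.0, mz_offset_ppm=0.0),
            DeviceEffect("dev3", rt_shift=15.0, intensity_gain=1.4, mz_offset_ppm=3.0),
        ]
        return [replace(base[i % 3], device_id=f"dev{i + 1}") for i in range(self.n_devices)]

    def validate(self) -> None:
        if not all(0 < p < 100 for p in self.proportions):
            raise ValueError("proportions must lie strictly between 0 and 100 % v/v")
        others = [self.similarity[s] for s in self.syrups if s != "hfcs"]
        if "hfcs" in self.syrups and others and self.similarity["hfcs"] <= max(others):
            raise ValueError("similarity(hfcs) must exceed similarity of rice/beet")


def paper_design(seed: int = 0, **overrides) -> CohortDesign:
    """The full 34-honey design at desk-scale acquisition."""
    return replace(CohortDesign(seed=seed), **overrides)


def ci_small_design(seed: int = 0, **overrides) -> CohortDesign:
    """A small fast preset: 6 honeys, 2 levels, short runs, small library."""
    small = CohortDesign(
        n_honeys=6,
        proportions=(10.0, 50.0),
        seed=seed,
        rt_span={"HILIC_neg": (0.0, 100.0), "RP_pos": (0.0, 120.0)},
        n_shared=15,
        n_honey_block=30,
        n_syrup_block=15,
        n_ubiquitous=15,
        n_noise_peaks=15,
    )
    return replace(small, **overrides)


@dataclass
class Library:
    """Generated compound library plus per-sample-source profiles."""

    compounds: list[Compound]
    honey_profiles: dict[str, CompoundProfile]  # honey id -> profile
    syrup_profiles: dict[str, CompoundProfile]  # syrup name -> profile
    blocks: dict[str, list[str]]  # block name -> compound ids

    def shared_mass(self, a: CompoundProfile, b: CompoundProfile) -> float:
        """Abundance mass of ``a`` carried by compounds also present in ``b``."""
        common = {c for c, v in b.abundances.items() if v > 0}
        return sum(v for c, v in a.abundances.items() if v > 0 and c in common)


def _draw_mzs(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """m/z positions with a minimum 0.05 Da separation (avoids ROI collisions)."""
    mzs: list[float] = []
    while len(mzs) < n:
        cand = rng.uniform(lo + 5.0, hi - 5.0, size=n)
        for m in cand:
            if len(mzs) >= n:
                break
            if all(abs(m - x) > 0.05 for x in mzs):
                mzs.append(float(m))
    return np.array(sorted(mzs))


def make_library(design: CohortDesign) -> Library:
    """Generate compounds and honey/syrup composition templates.

    Block mass fractions: honeys put ~35 % on shared sugars, ~45 % on
    honey-specific compounds and ~20 % on ubiquitous background; each
    syrup puts its similarity fraction on shared sugars, its unique
    fraction (strong for rice/beet, marginal for HFCS) on its own block
    and the remainder on the ubiquitous block. Within a block,
    compound weights are log-normal; honeys additionally vary compound
    by compound, which is what creates honey diversity.
    """
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 101]))
    blocks: dict[str, int] = {"shared": design.n_shared, "ubiquitous": design.n_ubiquitous,
                              "honey": design.n_honey_block}
    for s in design.syrups:
        blocks[f"syrup_{s}"] = design.n_syrup_block
    n_total = sum(blocks.values())
    mzs = _draw_mzs(rng, n_total, *design.mz_range)
    rng.shuffle(mzs)

    margin = 20.0
    compounds: list[Compound] = []
    block_ids: dict[str, list[str]] = {}
    k = 0
    for name, count in blocks.items():
        ids = []
        for _ in range(count):
            cid = f"{name}_{len(ids):03d}"
            rt_mode = {
                mode: float(rng.uniform(design.rt_span[mode][0] + margin,
                                        design.rt_span[mode][1] - margin - 5.0))
                for mode in design.modes
            }
            compounds.append(
                Compound(
                    id=cid,
                    mz=float(mzs[k]),
                    rt_mode=rt_mode,
                    peak_sd=float(rng.uniform(1.5, 3.0)),
                    base_abundance=float(rng.lognormal(0.0, 0.5)),
                )
            )
            ids.append(cid)
            k += 1
        block_ids[name] = ids

    by_id = {c.id: c for c in compounds}

    def template(fractions: Mapping[str, float]) -> dict[str, float]:
        out: dict[str, float] = {}
        for bname, frac in fractions.items():
            ids = block_ids[bname]
            w = np.array([by_id[c].base_abundance for c in ids])
            w = w / w.sum() * frac * design.total_abundance
            out.update(zip(ids, w))
        return out

    honey_template = template(_HONEY_BLOCKS)
    honey_profiles: dict[str, CompoundProfile] = {}
    for h in range(design.n_honeys):
        hid = f"H{h + 1:02d}"
        hrng = np.random.default_rng(np.random.SeedSequence([design.seed, 202, h]))
        # honeys differ both compound-by-compound and in whole-block
        # composition (overall sugar vs background balance)
        block_scale = {
            b: float(hrng.lognormal(0.0, design.block_scale_sd)) for b in _HONEY_BLOCKS
        }
        ab = {}
        for cid, base in honey_template.items():
            block = cid.rsplit("_", 1)[0]
            sd = design.honey_variation_sd if block == "honey" else design.context_variation_sd
            ab[cid] = base * block_scale[block] * float(hrng.lognormal(0.0, sd))
        honey_profiles[hid] = CompoundProfile(sample_id=hid, abundances=ab)

    syrup_profiles: dict[str, CompoundProfile] = {}
    for s in design.syrups:
        shared = design.similarity[s]
        unique = _SYRUP_UNIQUE.get(s, 0.5)
        fractions = {"shared": shared, f"syrup_{s}": unique,
                     "ubiquitous": 1.0 - shared - unique}
        syrup_profiles[s] = CompoundProfile(sample_id=s, abundances=template(fractions))

    return Library(compounds=compounds, honey_profiles=honey_profiles,
                   syrup_profiles=syrup_profiles, blocks=block_ids)


def mix_profiles(honey: CompoundProfile, syrup: CompoundProfile, p: float) -> CompoundProfile:
    """Volume-fraction mixture: ``(1-p)*honey + p*syrup`` per compound."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("mixing fraction must lie in [0, 1]")
    ids = set(honey.abundances) | set(syrup.abundances)
    ab = {
        c: (1.0 - p) * honey.abundances.get(c, 0.0) + p * syrup.abundances.get(c, 0.0)
        for c in ids
    }
    return CompoundProfile(sample_id=f"{honey.sample_id}+{syrup.sample_id}@{p:g}", abundances=ab)


def _fragment_mzs(mz: float, window) -> list[float]:
    """Two deterministic pseudo-fragments inside the window's detection range."""
    lo, hi = window.fragment_low, window.fragment_high
    return [lo + 0.31 * (mz - lo), lo + 0.73 * (mz - lo)] if mz > lo else [lo + 1.0, lo + 2.0]


def render_run(
    profile: CompoundProfile,
    mode: str,
    device: DeviceEffect,
    design: CohortDesign,
    library: Library,
    seed: int = 0,
    noise: bool = True,
    sample_id: str | None = None,
) -> LcmsRun:
    """Render a compound profile into a full synthetic LC-MS run.

    MS1 scans are emitted at ``design.scan_interval`` over the mode's RT
    span. Each compound with nonzero abundance elutes as a Gaussian
    centred at ``rt_stretch * rt + rt_shift`` (plus run-level jitter),
    apex intensity ``intensity_gain * abundance`` (times log-normal run
    noise); centroid m/z carries the device ppm offset plus per-scan
    ppm jitter. Centroids below ``design.min_intensity`` are not
    recorded. Random noise peaks (short Gaussians around the device
    noise floor) are added per run. With ``noise=False`` all stochastic
    contributions (jitter, run noise, noise peaks) are disabled and the
    rendering is an exact deterministic function of the profile.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 303]))
    t0, t1 = design.rt_span[mode]
    times = np.arange(t0, t1, design.scan_interval)
    by_id = {c.id: c for c in library.compounds}

    # per-compound elution parameters for this run
    comp_mz, comp_rt, comp_sd, comp_apex = [], [], [], []
    for cid, abundance in sorted(profile.abundances.items()):
        if abundance <= 0 or cid not in by_id:
            continue
        c = by_id[cid]
        apex = abundance * device.intensity_gain
        rt_c = device.rt_stretch * c.rt_mode[mode] + device.rt_shift
        if noise:
            apex *= float(rng.lognormal(0.0, design.run_noise_sd))
            rt_c += float(rng.normal(0.0, design.rt_jitter_sd))
        comp_mz.append(c.mz)
        comp_rt.append(rt_c)
        comp_sd.append(c.peak_sd)
        comp_apex.append(apex)

    if noise:
        n_np = design.n_noise_peaks
        comp_mz += list(rng.uniform(*design.mz_range, size=n_np))
        comp_rt += list(rng.uniform(t0, t1, size=n_np))
        comp_sd += list(rng.uniform(1.5, 3.0, size=n_np))
        comp_apex += list(rng.lognormal(np.log(device.noise_floor), 0.5, size=n_np))

    scan_idx_parts, mz_parts, int_parts = [], [], []
    for mz, rt_c, sd, apex in zip(comp_mz, comp_rt, comp_sd, comp_apex):
        if apex < design.min_intensity:
            continue
        # scans where the Gaussian exceeds the recording cutoff
        half = sd * np.sqrt(2.0 * np.log(apex / design.min_intensity))
        i0 = max(int(np.ceil((rt_c - half - t0) / design.scan_interval)), 0)
        i1 = min(int(np.floor((rt_c + half - t0) / design.scan_interval)), times.size - 1)
        if i1 < i0:
            continue
        idx = np.arange(i0, i1 + 1)
        inten = apex * np.exp(-((times[idx] - rt_c) ** 2) / (2.0 * sd**2))
        ppm = np.full(idx.size, device.mz_offset_ppm)
        if noise:
            ppm = ppm + rng.normal(0.0, design.mz_jitter_ppm, size=idx.size)
        scan_idx_parts.append(idx)
        mz_parts.append(mz * (1.0 + ppm * 1e-6))
        int_parts.append(inten)

    scans: list[CentroidSpectrum] = []
    if scan_idx_parts:
        scan_idx = np.concatenate(scan_idx_parts)
        mz_all = np.concatenate(mz_parts)
        int_all = np.concatenate(int_parts)
        order = np.lexsort((mz_all, scan_idx))
        scan_idx, mz_all, int_all = scan_idx[order], mz_all[order], int_all[order]
        boundaries = np.flatnonzero(np.diff(scan_idx)) + 1
        starts = np.r_[0, boundaries]
        stops = np.r_[boundaries, scan_idx.size]
        per_scan = {int(scan_idx[a]): (mz_all[a:b], int_all[a:b]) for a, b in zip(starts, stops)}
    else:
        per_scan = {}

    for i, t in enumerate(times):
        if i in per_scan:
            mz_i, int_i = per_scan[i]
            # strictly increasing m/z: merge (sum) exact duplicates
            if mz_i.size > 1 and np.any(np.diff(mz_i) <= 0):
                uniq, inv = np.unique(mz_i, return_inverse=True)
                int_i = np.bincount(inv, weights=int_i)
                mz_i = uniq
        else:
            mz_i, int_i = np.empty(0), np.empty(0)
        scans.append(CentroidSpectrum(rt=float(t), ms_level=1, mz=mz_i, intensity=int_i))
        if design.render_ms2 and mz_i.size:
            for window in CANONICAL_WINDOWS:
                sel = (mz_i >= window.precursor_low) & (mz_i < window.precursor_high)
                if not np.any(sel):
                    continue
                frag_mz, frag_int = [], []
                for m, v in zip(mz_i[sel], int_i[sel]):
                    for fm in _fragment_mzs(m, window):
                        frag_mz.append(fm)
                        frag_int.append(0.5 * v)
                forder = np.argsort(frag_mz)
                fmz = np.asarray(frag_mz)[forder]
                fint = np.asarray(frag_int)[forder]
                if fmz.size > 1 and np.any(np.diff(fmz) <= 0):
                    uniq, inv = np.unique(fmz, return_inverse=True)
                    fint = np.bincount(inv, weights=fint)
                    fmz = uniq
                scans.append(
                    CentroidSpectrum(rt=float(t), ms_level=2, mz=fmz, intensity=fint, window=window)
                )

    return LcmsRun(
        sample_id=sample_id or profile.sample_id,
        mode=mode,
        scans=scans,
        device_id=device.device_id,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _sample_id(syrup: str, honey_id: str, proportion: float) -> str:
    return f"{syrup}_{honey_id}_p{proportion:g}"


def sample_table(design: CohortDesign, syrup: str) -> pd.DataFrame:
    """The sample sheet of one syrup scenario: pure honeys plus all mixtures.

    Device assignment and acquisition order are randomized (seeded); both
    modes of a sample run on the same device.
    """
    if syrup not in design.syrups:
        raise ValueError(f"unknown syrup {syrup!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([design.seed, 404, list(design.syrups).index(syrup)])
    )
    devices = design.device_effects()
    rows = []
    for h in range(design.n_honeys):
        hid = f"H{h + 1:02d}"
        for prop in (0.0, *design.proportions):
            rows.append(
                dict(
                    sample_id=_sample_id(syrup, hid, prop),
                    honey_id=hid,
                    syrup="none" if prop == 0 else syrup,
                    proportion_pct=prop,
                    device_id=devices[int(rng.integers(len(devices)))].device_id,
                )
            )
    df = pd.DataFrame(rows)
    df["acquisition_order"] = rng.permutation(len(df)) + 1
    return df


def iter_runs(
    design: CohortDesign, syrup: str, table: pd.DataFrame | None = None, noise: bool = True
) -> Iterator[tuple[dict, LcmsRun]]:
    """Yield ``(sample row, run)`` for every (sample, mode) of a scenario.

    Each run's randomness is seeded from (cohort seed, syrup, honey,
    proportion, mode), so any run can be regenerated in isolation.
    """
    library = make_library(design)
    if table is None:
        table = sample_table(design, syrup)
    devices = {d.device_id: d for d in design.device_effects()}
    syrup_idx = design.syrups.index(syrup)
    empty_target = None
    if design.plant_empty_rp:
        at50 = table[table["proportion_pct"] == 50.0]
        if len(at50):
            empty_target = at50.iloc[0]["sample_id"]
    for row in table.to_dict("records"):
        honey = library.honey_profiles[row["honey_id"]]
        p = row["proportion_pct"] / 100.0
        profile = mix_profiles(honey, library.syrup_profiles[syrup], p) if p > 0 else honey
        for mi, mode in enumerate(design.modes):
            # stable per-run seed: (cohort seed, syrup, honey, level, mode)
            hidx = int(row["honey_id"].lstrip("H"))
            seed = int(
                np.random.SeedSequence(
                    [design.seed, 505, syrup_idx, hidx, int(row["proportion_pct"] * 10), mi]
                ).generate_state(1)[0]
                % (2**31)
            )
            if mode == "RP_pos" and row["sample_id"] == empty_target:
                rendered_profile = CompoundProfile(sample_id=row["sample_id"], abundances={})
                run = render_run(rendered_profile, mode, devices[row["device_id"]],
                                 design, library, seed=seed, noise=False,
                                 sample_id=row["sample_id"])
            else:
                run = render_run(profile, mode, devices[row["device_id"]], design, library,
                                 seed=seed, noise=noise, sample_id=row["sample_id"])
            yield row, run


def make_cohort(design: CohortDesign, syrup: str, out_dir: str | Path) -> pd.DataFrame:
    """Render a full scenario to disk: mzML files, metadata CSV, manifest.

    Returns the metadata table (also written as ``metadata.csv``); the
    JSON manifest records every generator parameter and the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = sample_table(design, syrup)
    records = []
    for row, run in iter_runs(design, syrup, table):
        fname = f"{run.sample_id}_{run.mode}.mzML"
        write_run(run, out_dir / fname)
        records.append({**row, "mode": run.mode, "path": fname})
    meta = pd.DataFrame(records)
    meta.to_csv(out_dir / "metadata.csv", index=False)
    manifest = {
        "syrup": syrup,
        "design": {
            k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
            for k, v in vars(design).items()
        },
        "n_samples": int(len(table)),
        "n_runs": int(len(records)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return meta
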