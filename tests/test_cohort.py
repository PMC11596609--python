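"""Synthetic-cohort generator: templates, mixing, rendering, determinism."""

import json

import numpy as np
import pytest

from honeyscreen.cohort import (
    IDENTITY_DEVICE,
    CohortDesign,
    CompoundProfile,
    DeviceEffect,
    ci_small_design,
    iter_runs,
    make_cohort,
    make_library,
    mix_profiles,
    paper_design,
    render_run,
    sample_table,
)
from honeyscreen.peaks import detect_all
from honeyscreen.spectra_io import read_run


def test_library_similarity_gradient(small_design, small_library):
    """HFCS shares far more abundance mass with honey than rice/beet do."""
    lib = small_library
    honey = lib.honey_profiles["H01"]
    shared = {
        s: lib.shared_mass(lib.syrup_profiles[s], honey) / small_design.total_abundance
        for s in small_design.syrups
    }
    assert shared["hfcs"] >= 3 * shared["rice"]
    assert shared["hfcs"] >= 3 * shared["beet"]


def test_library_deterministic_and_honey_variation(small_design):
    lib1, lib2 = make_library(small_design), make_library(small_design)
    assert [c.id for c in lib1.compounds] == [c.id for c in lib2.compounds]
    assert lib1.honey_profiles["H03"].abundances == lib2.honey_profiles["H03"].abundances

    frozen = ci_small_design(seed=7, honey_variation_sd=0.0, context_variation_sd=0.0,
                             block_scale_sd=0.0)
    lib = make_library(frozen)
    assert lib.honey_profiles["H01"].abundances == lib.honey_profiles["H02"].abundances


def test_mixing_is_linear():
    h = CompoundProfile("h", {"a": 10.0, "b": 4.0})
    s = CompoundProfile("s", {"a": 20.0, "c": 8.0})
    assert mix_profiles(h, s, 0.0).abundances == {"a": 10.0, "b": 4.0, "c": 0.0}
    assert mix_profiles(h, s, 1.0).abundances == {"a": 20.0, "b": 0.0, "c": 8.0}
    mid = mix_profiles(h, s, 0.5).abundances
    assert mid == {"a": 15.0, "b": 2.0, "c": 4.0}
    with pytest.raises(ValueError):
        mix_profiles(h, s, 1.2)


def test_noiseless_render_recovers_planted_compound(small_design, small_library):
    profile = CompoundProfile("one", {small_library.compounds[0].id: 1e6})
    c = small_library.compounds[0]
    run = render_run(profile, "HILIC_neg", IDENTITY_DEVICE, small_design, small_library,
                     noise=False)
    peaks = detect_all(run)[(1, None)]
    assert len(peaks) == 1
    assert peaks[0].rt_apex == pytest.approx(c.rt_mode["HILIC_neg"], abs=1.0)
    assert peaks[0].mz == pytest.approx(c.mz, rel=5e-6)


def test_device_rt_shift_moves_apexes(small_design, small_library):
    profile = small_library.honey_profiles["H01"]
    base = render_run(profile, "HILIC_neg", IDENTITY_DEVICE, small_design, small_library,
                      noise=False)
    shifted_dev = DeviceEffect("shifted", rt_shift=10.0)
    shifted = render_run(profile, "HILIC_neg", shifted_dev, small_design, small_library,
                         noise=False)
    p0 = sorted(detect_all(base)[(1, None)], key=lambda p: p.mz)
    p1 = sorted(detect_all(shifted)[(1, None)], key=lambda p: p.mz)
    assert len(p0) == len(p1) > 0
    for a, b in zip(p0, p1):
        assert b.rt_apex - a.rt_apex == pytest.approx(10.0, abs=1.0)


def test_doubling_abundance_doubles_apex(small_design, small_library):
    cid = small_library.compounds[0].id
    r1 = render_run(CompoundProfile("x", {cid: 1e6}), "RP_pos", IDENTITY_DEVICE,
                    small_design, small_library, noise=False)
    r2 = render_run(CompoundProfile("x", {cid: 2e6}), "RP_pos", IDENTITY_DEVICE,
                    small_design, small_library, noise=False)
    apex1 = max(s.intensity.max() for s in r1.scans if s.intensity.size)
    apex2 = max(s.intensity.max() for s in r2.scans if s.intensity.size)
    assert apex2 == pytest.approx(2 * apex1, rel=1e-9)


def test_mixing_linearity_through_detection_and_bucketing(small_design, small_library):
    """Noise off: bucket vector of a p-mixture ~ (1-p)*honey + p*syrup per bucket."""
    from honeyscreen.bucketing import bucketize
    from honeyscreen.pipeline import default_grid

    grid = default_grid(small_design, "HILIC_neg")
    honey = small_library.honey_profiles["H01"]
    syrup = small_library.syrup_profiles["rice"]
    p = 0.5

    def vec(profile):
        run = render_run(profile, "HILIC_neg", IDENTITY_DEVICE, small_design, small_library,
                         noise=False)
        return bucketize(detect_all(run)[(1, None)], grid).values

    vh, vs = vec(honey), vec(syrup)
    vm = vec(mix_profiles(honey, syrup, p))
    expected = (1 - p) * vh + p * vs
    occupied = expected > 0.01 * expected.max()
    rel_err = np.abs(vm[occupied] - expected[occupied]) / expected[occupied]
    assert np.quantile(rel_err, 0.95) <= 0.05


def test_sample_table_counts_and_determinism():
    design = paper_design(seed=5)
    table = sample_table(design, "rice")
    assert len(table) == 34 * 6 == 204
    assert (table.groupby("honey_id").size() == 6).all()
    assert set(table["device_id"]) == {"dev1", "dev2", "dev3"}
    assert sorted(table["acquisition_order"]) == list(range(1, 205))
    assert table.equals(sample_table(design, "rice"))
    assert not table.equals(sample_table(design, "beet"))


def test_reduced_design_run_arithmetic():
    design = ci_small_design(seed=1, n_honeys=4, proportions=(10.0, 50.0))
    runs = list(iter_runs(design, "rice"))
    assert len(runs) == 4 * 3 * 2  # honeys x (pure + 2 levels) x modes


def test_runs_regenerate_identically(small_design):
    def first_run():
        for row, run in iter_runs(small_design, "beet"):
            return run

    r1, r2 = first_run(), first_run()
    assert len(r1.scans) == len(r2.scans)
    for a, b in zip(r1.scans, r2.scans):
        np.testing.assert_array_equal(a.mz, b.mz)
        np.testing.assert_array_equal(a.intensity, b.intensity)


def test_make_cohort_writes_readable_files(tmp_path):
    design = ci_small_design(seed=2, n_honeys=2, proportions=(50.0,))
    meta = make_cohort(design, "rice", tmp_path)
    assert len(meta) == 2 * 2 * 2  # 2 honeys x 2 samples x 2 modes
    assert (tmp_path / "metadata.csv").exists()
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["n_runs"] == len(meta)
    assert manifest["design"]["seed"] == 2
    row = meta.iloc[0]
    run = read_run(tmp_path / row["path"], row["mode"])
    assert run.sample_id == row["sample_id"]
    assert run.device_id == row["device_id"]
    assert len(run.scans) > 0


def test_planted_empty_rp_run(small_design):
    design = ci_small_design(seed=7, n_honeys=2, proportions=(50.0,), plant_empty_rp=True)
    empties = [
        (row["sample_id"], run.mode)
        for row, run in iter_runs(design, "rice")
        if not any(s.intensity.size for s in run.scans)
    ]
    assert len(empties) == 1
    assert empties[0][1] == "RP_pos"


def test_design_validation():
    with pytest.raises(ValueError):
        CohortDesign(proportions=(0.0, 10.0)).validate()
    with pytest.raises(ValueError):
        CohortDesign(similarity={"rice": 0.5, "beet": 0.05, "hfcs": 0.35}).validate()


def test_ms2_rendering_produces_window_layers(small_design, small_library):
    import dataclasses

    design = dataclasses.replace(small_design, render_ms2=True)
    profile = small_library.honey_profiles["H01"]
    run = render_run(profile, "HILIC_neg", IDENTITY_DEVICE, design, small_library, noise=False)
    levels = {(s.ms_level, s.window) for s in run.scans}
    assert (1, None) in levels
    assert any(lv == 2 for lv, _ in levels)
    by_layer = detect_all(run)
    ms2_layers = [k for k in by_layer if k[0] == 2]
    assert ms2_layers and any(by_layer[k] for k in ms2_layers)
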