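"""ROI assembly and elution-peak finding on constructed traces."""

import numpy as np
import pytest

from honeyscreen.peaks import PeakParams, detect_all, detect_peaks, find_rois
from honeyscreen.spectra_io import CentroidSpectrum, LcmsRun

from conftest import gaussian_roi


def _run_from_points(points, mode="HILIC_neg", t0=0.0, t1=40.0, interval=1.0):
    """Build a run from (rt, mz, intensity) triples; empty scans elsewhere."""
    times = np.arange(t0, t1, interval)
    by_t = {}
    for rt, mz, inten in points:
        by_t.setdefault(rt, []).append((mz, inten))
    scans = []
    for t in times:
        pts = sorted(by_t.get(t, []))
        scans.append(
            CentroidSpectrum(
                rt=float(t),
                ms_level=1,
                mz=np.array([p[0] for p in pts]),
                intensity=np.array([p[1] for p in pts]),
            )
        )
    return LcmsRun("t", mode, scans=scans)


def test_single_compound_forms_one_roi_with_all_points():
    """A 10-scan trace with ~1.7 ppm jitter stays in one ROI at 5 ppm tolerance."""
    rng = np.random.default_rng(0)
    pts = [
        (float(t), 300.0 + float(rng.uniform(-5e-4, 5e-4)), 1e5)
        for t in range(10, 20)
    ]
    rois = find_rois(_run_from_points(pts), ppm_tol=5.0, min_scans=5)
    assert len(rois) == 1
    assert rois[0].rt.size == 10
    # brute-force check: every pairwise gap within the ROI is < 5 ppm of center
    assert np.all(np.abs(rois[0].mz - rois[0].mz_center) < 5e-6 * 300.0 * 2)


def test_two_compounds_33ppm_apart_form_two_rois():
    pts = [(float(t), 300.000, 1e5) for t in range(10, 20)]
    pts += [(float(t), 300.010, 2e5) for t in range(10, 20)]
    rois = find_rois(_run_from_points(pts), ppm_tol=5.0, min_scans=5)
    assert len(rois) == 2
    assert sorted(round(r.mz_center, 3) for r in rois) == [300.000, 300.010]


def test_same_mz_distant_elutions_split_into_two_rois():
    pts = [(float(t), 250.0, 1e5) for t in range(5, 13)]
    pts += [(float(t), 250.0, 1e5) for t in range(30, 38)]
    rois = find_rois(_run_from_points(pts), ppm_tol=5.0, min_scans=5)
    assert len(rois) == 2


def test_short_traces_discarded():
    pts = [(float(t), 300.0, 1e5) for t in range(10, 13)]  # 3 scans < min_scans
    assert find_rois(_run_from_points(pts), min_scans=5) == []


def test_empty_run_yields_no_rois():
    run = LcmsRun("e", "HILIC_neg", scans=[])
    assert find_rois(run) == []
    assert detect_all(run) == {(1, None): []}


def test_gaussian_peak_apex_and_bounds():
    """Noiseless Gaussian (sd 3 s, apex 1e6) at RT 100: one peak, apex within 1 s."""
    roi = gaussian_roi(apex_rt=100.0, sd=3.0, apex=1e6)
    peaks = detect_peaks(roi, peakwidth=(5.0, 15.0), snr_min=3.0)
    assert len(peaks) == 1
    (p,) = peaks
    assert abs(p.rt_apex - 100.0) <= 1.0
    assert p.rt_lo <= p.rt_apex <= p.rt_hi
    assert 5.0 <= p.rt_hi - p.rt_lo <= 15.0
    # area proxy: total intensity between bounds
    mask = (roi.rt >= p.rt_lo) & (roi.rt <= p.rt_hi)
    assert p.intensity == pytest.approx(roi.intensity[mask].sum())


def test_flat_trace_has_no_peaks():
    from honeyscreen.peaks import Roi

    rt = np.arange(0.0, 30.0)
    roi = Roi(300.0, rt, np.full(rt.size, 300.0), np.full(rt.size, 5000.0))
    assert detect_peaks(roi) == []


def test_two_gaussians_in_one_roi_resolve_in_order():
    a = gaussian_roi(apex_rt=100.0, sd=3.0, apex=1e6, span=30)
    b = gaussian_roi(apex_rt=160.0, sd=3.0, apex=5e5, span=30)
    from honeyscreen.peaks import Roi

    rt = np.concatenate([a.rt, b.rt])
    inten = np.concatenate([a.intensity, b.intensity])
    roi = Roi(300.0, rt, np.full(rt.size, 300.0), inten)
    peaks = detect_peaks(roi)
    assert len(peaks) == 2
    assert peaks[0].rt_apex == pytest.approx(100.0, abs=1.0)
    assert peaks[1].rt_apex == pytest.approx(160.0, abs=1.0)
    assert peaks[0].intensity > peaks[1].intensity


def test_low_snr_peak_rejected():
    """A bump barely above a noisy baseline fails the apex/noise gate."""
    from honeyscreen.peaks import Roi

    rng = np.random.default_rng(1)
    rt = np.arange(0.0, 60.0)
    base = rng.uniform(900.0, 1100.0, rt.size)
    bump = 1500.0 * np.exp(-((rt - 30.0) ** 2) / (2 * 3.0**2))
    roi = Roi(300.0, rt, np.full(rt.size, 300.0), base + bump)
    assert detect_peaks(roi, snr_min=3.0) == []


def test_detection_is_deterministic_and_linear(noiseless_run):
    """Identical input -> identical peaks; scaling intensities by c scales areas by c."""
    p1 = detect_all(noiseless_run)
    p2 = detect_all(noiseless_run)
    assert p1 == p2

    scaled = LcmsRun(
        noiseless_run.sample_id,
        noiseless_run.mode,
        scans=[
            CentroidSpectrum(s.rt, s.ms_level, s.mz.copy(), s.intensity * 3.0, s.window)
            for s in noiseless_run.scans
        ],
    )
    p3 = detect_all(scaled)
    peaks1, peaks3 = p1[(1, None)], p3[(1, None)]
    assert len(peaks1) == len(peaks3) > 0
    for a, b in zip(peaks1, peaks3):
        assert b.rt_apex == a.rt_apex
        assert b.intensity == pytest.approx(3.0 * a.intensity, rel=1e-9)


def test_planted_compounds_recovered(small_design, small_library):
    """Planted compounds >= 10x noise are found within 1 s / 5 ppm (recall >= 0.95)."""
    from honeyscreen.cohort import IDENTITY_DEVICE, render_run

    profile = small_library.honey_profiles["H02"]
    run = render_run(profile, "HILIC_neg", IDENTITY_DEVICE, small_design, small_library,
                     seed=11, noise=True)
    peaks = detect_all(run)[(1, None)]
    by_id = {c.id: c for c in small_library.compounds}
    planted = [
        (by_id[cid].mz, by_id[cid].rt_mode["HILIC_neg"])
        for cid, ab in profile.abundances.items()
        if ab >= 10 * small_design.min_intensity and cid in by_id
    ]
    assert planted
    found = 0
    for mz, rt in planted:
        for p in peaks:
            if abs(p.mz - mz) <= 5e-6 * mz * 2 and abs(p.rt_apex - rt) <= 3.5:
                found += 1
                break
    assert found / len(planted) >= 0.95
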