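"""Chromatographic peak detection on centroided LC-MS runs.

A simplified centWave-style two-stage procedure, as used throughout
untargeted metabolomics: first, centroids are grouped into regions of
interest (ROIs) — m/z traces whose members stay within a ppm tolerance
of the trace centre across consecutive scans; second, each ROI's
intensity trace is scanned for local-maximum elution peaks whose base
width falls inside the expected chromatographic peak-width range and
whose apex rises sufficiently above the trace noise.

The continuous-wavelet stage of full centWave is deliberately omitted:
downstream analysis summarizes peaks onto a coarse fixed grid (20 s x
2 Da buckets), so sub-second apex refinement buys nothing. Peak
intensity is the summed trace intensity between the peak bounds (an
area proxy, matching the integrated intensities used downstream) rather
than apex height.

Detection is fully deterministic, and per-run: no step sees more than
one run, which is what keeps downstream feature vectors independent of
the processing batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import LcmsRun, VdiaWindow

__all__ = ["Roi", "ChromPeak", "PeakParams", "find_rois", "detect_peaks", "detect_all", "peaks_to_frame"]


@dataclass
class Roi:
    """A region of interest: one m/z trace through consecutive scans."""

    mz_center: float
    rt: np.ndarray  # strictly increasing, seconds
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def scan_span(self) -> tuple[float, float]:
        return float(self.rt[0]), float(self.rt[-1])


@dataclass(frozen=True)
class ChromPeak:
    """A detected chromatographic peak.

    ``mz`` is the intensity-weighted mean over the peak's trace points;
    ``intensity`` the summed trace intensity between the bounds.
    """

    mz: float
    rt_apex: float
    rt_lo: float
    rt_hi: float
    intensity: float
    snr: float


@dataclass(frozen=True)
class PeakParams:
    """Detection parameters.

    ppm_tol
        m/z tolerance for ROI assembly, ppm.
    peakwidth
        (min, max) allowed base width of an elution peak, seconds.
    snr_min
        minimum apex / trace-noise ratio.
    min_scans
        minimum number of consecutive scans an ROI must cover.
    bound_frac
        fraction of apex intensity at which peak bounds are placed when
        no local minimum intervenes.
    """

    ppm_tol: float = 5.0
    peakwidth: tuple[float, float] = (5.0, 15.0)
    snr_min: float = 3.0
    min_scans: int = 5
    bound_frac: float = 0.1


def find_rois(
    run: LcmsRun,
    ms_level: int = 1,
    window: VdiaWindow | None = None,
    ppm_tol: float = 5.0,
    min_scans: int = 5,
) -> list[Roi]:
    """Group the centroids of one MS level (and vDIA window) into ROIs.

    Centroids are pooled across scans, sorted by m/z, and split wherever
    the gap to the next centroid exceeds ``ppm_tol``; each m/z cluster is
    then split at retention-time gaps larger than 1.5 scan intervals, so
    that isobaric compounds eluting at different times form separate
    ROIs. Clusters shorter than ``min_scans`` consecutive scans are
    discarded. Every centroid ends up in at most one ROI.
    """
    scans = run.scans_at(ms_level, window)
    if not scans:
        return []
    rts = np.array([s.rt for s in scans])
    interval = float(np.median(np.diff(rts))) if len(rts) > 1 else 1.0

    all_rt = np.concatenate([np.full(s.mz.size, s.rt) for s in scans]) if scans else np.empty(0)
    all_mz = np.concatenate([s.mz for s in scans])
    all_int = np.concatenate([s.intensity for s in scans])
    if all_mz.size == 0:
        return []

    order = np.argsort(all_mz, kind="stable")
    mz_s, rt_s, int_s = all_mz[order], all_rt[order], all_int[order]

    # split the sorted m/z axis where the relative gap exceeds the tolerance
    gaps = np.diff(mz_s) > ppm_tol * 1e-6 * mz_s[:-1]
    cluster_bounds = np.flatnonzero(gaps) + 1
    rois: list[Roi] = []
    max_rt_gap = 1.5 * interval
    for lo, hi in zip(np.r_[0, cluster_bounds], np.r_[cluster_bounds, mz_s.size]):
        c_mz, c_rt, c_int = mz_s[lo:hi], rt_s[lo:hi], int_s[lo:hi]
        t_order = np.argsort(c_rt, kind="stable")
        c_mz, c_rt, c_int = c_mz[t_order], c_rt[t_order], c_int[t_order]
        # one point per scan: on duplicates keep the most intense centroid
        if c_rt.size > 1:
            keep = np.ones(c_rt.size, dtype=bool)
            dup = np.flatnonzero(np.diff(c_rt) == 0)
            for i in dup:
                drop = i if c_int[i] <= c_int[i + 1] else i + 1
                keep[drop] = False
            c_mz, c_rt, c_int = c_mz[keep], c_rt[keep], c_int[keep]
        # split at retention-time gaps
        seg_bounds = np.flatnonzero(np.diff(c_rt) > max_rt_gap) + 1
        for a, b in zip(np.r_[0, seg_bounds], np.r_[seg_bounds, c_rt.size]):
            if b - a < min_scans:
                continue
            seg_int = c_int[a:b]
            total = seg_int.sum()
            center = float((c_mz[a:b] * seg_int).sum() / total) if total > 0 else float(c_mz[a:b].mean())
            rois.append(Roi(mz_center=center, rt=c_rt[a:b], mz=c_mz[a:b], intensity=seg_int))
    rois.sort(key=lambda r: (r.mz_center, r.rt[0]))
    return rois


def _smooth3(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return x.astype(float)
    s = np.convolve(x, np.ones(3) / 3.0, mode="same")
    # edges: average of the two available points
    s[0] = (x[0] + x[1]) / 2.0
    s[-1] = (x[-2] + x[-1]) / 2.0
    return s


def detect_peaks(
    roi: Roi,
    peakwidth: tuple[float, float] = (5.0, 15.0),
    snr_min: float = 3.0,
    bound_frac: float = 0.1,
) -> list[ChromPeak]:
    """Find elution peaks in one ROI.

    The trace is lightly smoothed (3-point moving average) and scanned
    for local maxima; each candidate is expanded outward until the
    intensity rises again (a local minimum separating co-eluting peaks)
    or drops below ``bound_frac`` of the apex. Candidates whose base
    width falls outside ``peakwidth`` are rejected. Noise is the median
    raw intensity outside all candidate bounds (floor 1); candidates
    with apex/noise below ``snr_min`` are rejected.
    """
    n = roi.rt.size
    if n < 3:
        return []
    raw = roi.intensity
    sm = _smooth3(raw)
    min_w, max_w = peakwidth

    # local maxima of the smoothed trace (strict rise on the left)
    apexes = [
        i
        for i in range(1, n - 1)
        if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1]
    ]
    candidates: list[tuple[int, int, int]] = []
    for i in sorted(apexes, key=lambda j: -sm[j]):
        apex_raw = raw[max(0, i - 1) : i + 2].argmax() + max(0, i - 1)
        floor = bound_frac * raw[apex_raw]
        lo = apex_raw
        while lo > 0 and raw[lo - 1] <= raw[lo] and raw[lo - 1] >= floor:
            lo -= 1
        hi = apex_raw
        while hi < n - 1 and raw[hi + 1] <= raw[hi] and raw[hi + 1] >= floor:
            hi += 1
        width = roi.rt[hi] - roi.rt[lo]
        if min_w <= width <= max_w:
            candidates.append((lo, apex_raw, hi))

    if not candidates:
        return []
    outside = np.ones(n, dtype=bool)
    for lo, _, hi in candidates:
        outside[lo : hi + 1] = False
    noise = max(float(np.median(raw[outside])) if outside.any() else 1.0, 1.0)

    peaks = []
    for lo, apex, hi in sorted(candidates):
        snr = raw[apex] / noise
        if snr < snr_min:
            continue
        seg_int = raw[lo : hi + 1]
        total = float(seg_int.sum())
        mz = float((roi.mz[lo : hi + 1] * seg_int).sum() / total) if total > 0 else roi.mz_center
        peaks.append(
            ChromPeak(
                mz=mz,
                rt_apex=float(roi.rt[apex]),
                rt_lo=float(roi.rt[lo]),
                rt_hi=float(roi.rt[hi]),
                intensity=total,
                snr=float(snr),
            )
        )
    return peaks


def detect_all(
    run: LcmsRun, params: PeakParams = PeakParams()
) -> dict[tuple[int, VdiaWindow | None], list[ChromPeak]]:
    """Detect peaks in every (MS level, vDIA window) layer of a run.

    Returns a mapping ``(ms_level, window) -> peaks``; the MS1 layer is
    always present (possibly empty), MS2 layers only for windows that
    have scans. Deterministic: identical input yields identical output.
    """
    layers: list[tuple[int, VdiaWindow | None]] = [(1, None)]
    seen = []
    for s in run.scans:
        if s.ms_level == 2 and s.window not in seen:
            seen.append(s.window)
    layers += [(2, w) for w in seen]

    out: dict[tuple[int, VdiaWindow | None], list[ChromPeak]] = {}
    for level, window in layers:
        rois = find_rois(run, level, window, params.ppm_tol, params.min_scans)
        peaks: list[ChromPeak] = []
        for roi in rois:
            peaks.extend(detect_peaks(roi, params.peakwidth, params.snr_min, params.bound_frac))
        out[(level, window)] = peaks
    return out


def peaks_to_frame(peaks_by_layer, sample_id: str = ""):
    """Flatten a ``detect_all`` result into a tidy table (CSV-ready)."""
    import pandas as pd

    rows = []
    for (level, window), peaks in peaks_by_layer.items():
        wname = "" if window is None else f"{window.precursor_low:g}-{window.precursor_high:g}"
        for p in peaks:
            rows.append(
                dict(
                    sample_id=sample_id,
                    ms_level=level,
                    window=wname,
                    mz=p.mz,
                    rt_apex=p.rt_apex,
                    rt_lo=p.rt_lo,
                    rt_hi=p.rt_hi,
                    intensity=p.intensity,
                    snr=p.snr,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "ms_level", "window", "mz", "rt_apex", "rt_lo", "rt_hi", "intensity", "snr"],
    )
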