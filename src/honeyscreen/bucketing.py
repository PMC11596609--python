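"""Fixed-grid bucketing of detected peaks (the BOULS scheme).

Instead of matching peaks across samples (correspondence), every run is
summarized independently onto a fixed retention-time x m/z grid — by
default 20 s x 2 Da cells — one grid layer per MS level / vDIA window.
The grid is defined purely by configuration, never by the data, so the
feature vector of a run is identical whether the run is processed alone
or inside any batch. That sample independence is the property that lets
a routine laboratory compare runs processed months apart, on different
devices, without ever reprocessing old data.

Each detected peak contributes its whole integrated intensity to the
single bucket containing its (weighted-mean m/z, apex RT); buckets are
half-open ``[lo, hi)`` intervals, and peaks outside the grid are dropped
(counted, never an error). Vectors are made comparable across runs by
total-ion-current normalization: every bucket is divided by the summed
intensity of all buckets, so a normalized vector sums to one.

An optional global retention-time shift correction against a reference
vector is provided (off by default): the whole point of coarse buckets
is to tolerate modest RT drift, but a single rigid shift can be applied
without coupling samples to a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .peaks import ChromPeak
from .spectra_io import VdiaWindow

__all__ = [
    "GridLayer",
    "BucketGrid",
    "FeatureVector",
    "build_grid",
    "assign_bucket",
    "bucketize",
    "normalize_tic",
    "align_global_shift",
    "GridConfigError",
    "EmptyRunError",
]


class GridConfigError(ValueError):
    """Grid ranges are not divisible by the bucket widths."""


class EmptyRunError(ValueError):
    """A run produced no signal at all (cannot be TIC-normalized)."""


def _check_divisible(lo: float, hi: float, width: float, what: str) -> int:
    n = (hi - lo) / width
    if hi <= lo or abs(n - round(n)) > 1e-9 or round(n) < 1:
        raise GridConfigError(f"{what} range ({lo:g}, {hi:g}) is not divisible by width {width:g}")
    return int(round(n))


@dataclass(frozen=True)
class GridLayer:
    """One grid layer: an MS level (with vDIA window for MS2) and its m/z span."""

    ms_level: int
    window: VdiaWindow | None
    mz_lo: float
    mz_hi: float

    def n_mz(self, mz_width: float) -> int:
        return _check_divisible(self.mz_lo, self.mz_hi, mz_width, "m/z")


@dataclass(frozen=True)
class BucketGrid:
    """The fixed RT x m/z bucket grid; configuration-defined, data-independent."""

    rt_lo: float
    rt_hi: float
    rt_width: float
    mz_width: float
    layers: tuple[GridLayer, ...]

    @property
    def n_rt(self) -> int:
        return _check_divisible(self.rt_lo, self.rt_hi, self.rt_width, "RT")

    def layer_sizes(self) -> list[int]:
        n_rt = self.n_rt
        return [n_rt * layer.n_mz(self.mz_width) for layer in self.layers]

    def layer_offsets(self) -> list[int]:
        return np.concatenate([[0], np.cumsum(self.layer_sizes())[:-1]]).astype(int).tolist()

    @property
    def n_buckets(self) -> int:
        return sum(self.layer_sizes())

    def bucket_ids(self) -> list[str]:
        """Canonical bucket names, layer-major then RT index then m/z index."""
        ids = []
        for li, layer in enumerate(self.layers):
            n_mz = layer.n_mz(self.mz_width)
            for ri in range(self.n_rt):
                rt_a = self.rt_lo + ri * self.rt_width
                for mi in range(n_mz):
                    mz_a = layer.mz_lo + mi * self.mz_width
                    ids.append(
                        f"L{li}_RT{rt_a:g}-{rt_a + self.rt_width:g}"
                        f"_MZ{mz_a:g}-{mz_a + self.mz_width:g}"
                    )
        return ids

    def to_dict(self) -> dict:
        return {
            "rt_lo": self.rt_lo,
            "rt_hi": self.rt_hi,
            "rt_width": self.rt_width,
            "mz_width": self.mz_width,
            "layers": [
                {
                    "ms_level": l.ms_level,
                    "window": None
                    if l.window is None
                    else [l.window.precursor_low, l.window.precursor_high,
                          l.window.fragment_low, l.window.fragment_high],
                    "mz_lo": l.mz_lo,
                    "mz_hi": l.mz_hi,
                }
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BucketGrid":
        layers = tuple(
            GridLayer(
                ms_level=l["ms_level"],
                window=None if l["window"] is None else VdiaWindow(*l["window"]),
                mz_lo=l["mz_lo"],
                mz_hi=l["mz_hi"],
            )
            for l in d["layers"]
        )
        return cls(d["rt_lo"], d["rt_hi"], d["rt_width"], d["mz_width"], layers)


def build_grid(
    mz_range: tuple[float, float],
    mz_width: float,
    rt_range: tuple[float, float],
    rt_width: float,
    layers: Sequence[tuple[int, VdiaWindow | None]] = ((1, None),),
) -> BucketGrid:
    """Construct a bucket grid.

    MS1 layers span ``mz_range``; MS2 layers span their window's fragment
    detection range, rounded outward to ``mz_width`` multiples. All
    ranges must be divisible by the respective widths.
    """
    grid_layers = []
    for level, window in layers:
        if level == 1:
            lo, hi = mz_range
        else:
            if window is None:
                raise GridConfigError("MS2 layers require a vDIA window")
            lo = np.floor(window.fragment_low / mz_width) * mz_width
            hi = np.ceil(window.fragment_high / mz_width) * mz_width
        grid_layers.append(GridLayer(level, window, float(lo), float(hi)))
    grid = BucketGrid(
        rt_lo=float(rt_range[0]),
        rt_hi=float(rt_range[1]),
        rt_width=float(rt_width),
        mz_width=float(mz_width),
        layers=tuple(grid_layers),
    )
    grid.n_buckets  # validate divisibility eagerly
    return grid


@dataclass
class FeatureVector:
    """A run's summarized intensities on a grid, in canonical bucket order."""

    grid: BucketGrid
    values: np.ndarray
    normalized: bool = False
    n_dropped: int = 0  # out-of-range peaks, for the processing log

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.n_buckets,):
            raise ValueError(
                f"feature vector length {self.values.size} != grid bucket count {self.grid.n_buckets}"
            )
        if np.any(self.values < 0):
            raise ValueError("bucket values must be nonnegative")


def assign_bucket(peak: ChromPeak, grid: BucketGrid, layer: int = 0) -> int | None:
    """Flat bucket index of a peak on ``grid`` (within ``layer``), or None.

    Buckets are half-open ``[lo, hi)``: the lower edge belongs to the
    bucket, the grid's upper limits do not. Peaks whose m/z or apex RT
    falls outside the grid are out-of-range (None).
    """
    lg = grid.layers[layer]
    if not (lg.mz_lo <= peak.mz < lg.mz_hi) or not (grid.rt_lo <= peak.rt_apex < grid.rt_hi):
        return None
    mi = int((peak.mz - lg.mz_lo) // grid.mz_width)
    ri = int((peak.rt_apex - grid.rt_lo) // grid.rt_width)
    return grid.layer_offsets()[layer] + ri * lg.n_mz(grid.mz_width) + mi


def _as_layer_map(peaks, grid: BucketGrid):
    if isinstance(peaks, Mapping):
        key_of = {(l.ms_level, l.window): i for i, l in enumerate(grid.layers)}
        out = {}
        for key, plist in peaks.items():
            if key in key_of:
                out[key_of[key]] = plist
        return out
    if len(grid.layers) != 1:
        raise ValueError("a plain peak list needs a single-layer grid; pass a (level, window) mapping")
    return {0: list(peaks)}


def bucketize(
    peaks: Sequence[ChromPeak] | Mapping[tuple[int, VdiaWindow | None], Sequence[ChromPeak]],
    grid: BucketGrid,
) -> FeatureVector:
    """Sum peak intensities into grid buckets (unnormalized).

    ``peaks`` is either a flat list (single-layer grid) or the mapping
    produced by :func:`honeyscreen.peaks.detect_all`; layers of the
    mapping that the grid does not define are ignored. Conservation
    holds exactly: ``sum(values)`` equals the summed intensity of all
    in-range peaks. Out-of-range peaks are counted in ``n_dropped``.
    """
    values = np.zeros(grid.n_buckets)
    dropped = 0
    for layer_idx, plist in _as_layer_map(peaks, grid).items():
        for p in plist:
            idx = assign_bucket(p, grid, layer_idx)
            if idx is None:
                dropped += 1
            else:
                values[idx] += p.intensity
    return FeatureVector(grid=grid, values=values, normalized=False, n_dropped=dropped)


def normalize_tic(v: FeatureVector) -> FeatureVector:
    """Divide every bucket by the vector's total intensity (all layers).

    Raises
    ------
    EmptyRunError
        If the vector is all-zero — a signal-free run cannot be
        normalized and should be dropped from the analysis.
    """
    total = v.values.sum()
    if total <= 0:
        raise EmptyRunError("run contains no signals; cannot TIC-normalize")
    return replace(v, values=v.values / total, normalized=True)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _shift_peaks(peaks, offset: float):
    def shift_list(plist):
        return [
            replace_peak(p, offset) for p in plist
        ]

    def replace_peak(p: ChromPeak, off: float) -> ChromPeak:
        return ChromPeak(
            mz=p.mz,
            rt_apex=p.rt_apex + off,
            rt_lo=p.rt_lo + off,
            rt_hi=p.rt_hi + off,
            intensity=p.intensity,
            snr=p.snr,
        )

    if isinstance(peaks, Mapping):
        return {k: shift_list(v) for k, v in peaks.items()}
    return shift_list(peaks)


def align_global_shift(
    peaks,
    reference: FeatureVector,
    max_shift: float = 30.0,
):
    """Rigid retention-time alignment of a peak list against a reference.

    Tries every integer-second offset in ``[-max_shift, +max_shift]``,
    bucketizes the shifted peaks on the reference's grid, and keeps the
    offset with the highest cosine similarity to the reference; ties
    break toward the smallest ``|offset|`` (then the negative one).
    Returns ``(shifted_peaks, offset)``. With an empty or flat query the
    tie-break yields offset 0.
    """
    grid = reference.grid
    best_offset, best_cos = 0.0, -np.inf
    offsets = sorted(range(-int(max_shift), int(max_shift) + 1), key=lambda o: (abs(o), o))
    for off in offsets:
        fv = bucketize(_shift_peaks(peaks, float(off)), grid)
        c = _cosine(fv.values, reference.values)
        if c > best_cos + 1e-12:
            best_cos, best_offset = c, float(off)
    return _shift_peaks(peaks, best_offset), best_offset
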