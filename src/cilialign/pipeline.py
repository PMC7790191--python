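"""From microscopy movies to per-cell beat frequency and beating direction.

The pipeline mirrors a standard work-flow for multiciliated cultures imaged
in bright field (fast acquisition, cilia beating modulates pixel intensity)
plus a fluorescent tracer movie of the same field of view (slow acquisition,
cilia-driven flow advects particles):

1. ``activity_std_map`` — temporal standard deviation of the bright-field
   stack highlights beating cilia;
2. ``otsu_mask`` — Otsu threshold on that map selects active pixels;
3. ``pixel_cbf`` — per-pixel FFT of the intensity time series; the highest
   in-band spectral peak is the ciliary beat frequency (CBF);
4. ``segment_ciliated_cells`` — connected groups of active pixels with a
   coherent frequency (component std below a threshold) are single cells;
5. ``piv`` — windowed cross-correlation of consecutive tracer frames gives
   the cilia-driven flow on a regular grid of interrogation boxes;
6. ``cells_to_boxes`` — boxes containing ciliated cells are kept and merged
   into per-cell records (position, CBF, flow vector, unit beating
   direction), the quantities the culture-level statistics consume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

__all__ = [
    "Movie",
    "CBFMap",
    "CellLabelMap",
    "FlowField",
    "CellRecord",
    "activity_std_map",
    "otsu_mask",
    "pixel_cbf",
    "segment_ciliated_cells",
    "piv",
    "cells_to_boxes",
    "registration_offset",
    "analyze_fov",
    "records_to_frame",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: µm per pixel at the reference magnification (32 px = 7.6 µm).
DEFAULT_PIXEL_SIZE_UM = 7.6 / 32


@dataclass(frozen=True)
class Movie:
    """Intensity stack (frames x rows x cols) with acquisition metadata."""

    stack: np.ndarray
    frame_rate: float  # Hz
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM  # µm / px

    def __post_init__(self) -> None:
        stack = np.asarray(self.stack)
        if stack.ndim != 3 or stack.shape[0] < 2:
            raise ValueError("stack must be (frames, rows, cols) with >= 2 frames")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be positive")
        object.__setattr__(self, "stack", stack)

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def mean_frame(self) -> np.ndarray:
        return self.stack.mean(axis=0)

    def to_tiff(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        import tifffile

        tifffile.imwrite(path, self.stack)
        if meta_path is not None:
            Path(meta_path).write_text(
                json.dumps(
                    {"frame_rate": self.frame_rate, "pixel_size": self.pixel_size}
                )
            )

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        meta_path: str | Path | None = None,
        frame_rate: float | None = None,
        pixel_size: float | None = None,
    ) -> "Movie":
        import tifffile

        stack = tifffile.imread(path)
        if meta_path is not None:
            meta = json.loads(Path(meta_path).read_text())
            frame_rate = frame_rate or meta.get("frame_rate")
            pixel_size = pixel_size or meta.get("pixel_size")
        if frame_rate is None:
            raise ValueError("frame_rate metadata is required")
        return cls(stack, frame_rate, pixel_size or DEFAULT_PIXEL_SIZE_UM)


@dataclass(frozen=True)
class CBFMap:
    """Per-pixel dominant beat frequency (Hz); NaN outside the mask."""

    frequency: np.ndarray
    mask: np.ndarray
    confidence: np.ndarray  # peak power / median in-band power
    band: tuple[float, float]
    resolution: float  # Hz per FFT bin


@dataclass(frozen=True)
class CellLabelMap:
    """Integer cell labels over pixels; 0 is background."""

    labels: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class FlowField:
    """Time-averaged PIV velocity (µm/s) on a grid of interrogation boxes."""

    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    box_size: int  # px
    pixel_size: float  # µm / px

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.vx.shape

    def box_area_um2(self) -> float:
        return (self.box_size * self.pixel_size) ** 2


@dataclass(frozen=True)
class CellRecord:
    """One ciliated-cell box: position, beat frequency, flow, direction."""

    box_i: int
    box_j: int
    x_um: float
    y_um: float
    cbf_hz: float
    vx_um_s: float
    vy_um_s: float
    direction: tuple[float, float] = field(default=(np.nan, np.nan))


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = [
        {
            "box_i": r.box_i,
            "box_j": r.box_j,
            "x_um": r.x_um,
            "y_um": r.y_um,
            "cbf_hz": r.cbf_hz,
            "vx_um_s": r.vx_um_s,
            "vy_um_s": r.vy_um_s,
            "px": r.direction[0],
            "py": r.direction[1],
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "box_i", "box_j", "x_um", "y_um", "cbf_hz", "vx_um_s", "vy_um_s",
            "px", "py",
        ],
    )


# ---------------------------------------------------------------------------
# bright-field branch: activity, CBF, segmentation
# ---------------------------------------------------------------------------

def activity_std_map(movie: Movie) -> np.ndarray:
    """Min-max normalized per-pixel temporal standard deviation.

    Beating cilia modulate the local intensity, so active pixels carry a
    large temporal std.  A perfectly constant movie returns all zeros.
    """
    std = movie.stack.std(axis=0, dtype=np.float64)
    lo, hi = std.min(), std.max()
    if hi == lo:
        warnings.warn("movie has spatially uniform activity; std map is all zeros")
        return np.zeros_like(std)
    return (std - lo) / (hi - lo)


def otsu_mask(std_map: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Binary mask of active pixels from an Otsu threshold on the std map."""
    std_map = np.asarray(std_map, dtype=float)
    if std_map.min() < -1e-9 or std_map.max() > 1 + 1e-9:
        raise ValueError("std map must be normalized to [0, 1]")
    if np.ptp(std_map) == 0:
        warnings.warn("degenerate single-valued map; returning empty mask")
        return np.zeros(std_map.shape, dtype=bool)
    thr = threshold_otsu(std_map, nbins=nbins)
    return std_map > thr


def pixel_cbf(
    movie: Movie,
    mask: np.ndarray,
    f_min: float = 1.0,
    f_max: float = 50.0,
    *,
    min_prominence: float = 30.0,
) -> CBFMap:
    """Dominant in-band frequency of every masked pixel's intensity trace.

    The magnitude spectrum of each pixel time series is searched in
    ``[f_min, f_max]`` (DC excluded) and the bin with the highest peak is
    the CBF; the frequency resolution is ``frame_rate / n_frames``.  A
    confidence score (peak power over median in-band power) lets callers
    flag noise pixels whose argmax is arbitrary.
    """
    if f_max <= f_min or f_min <= 0:
        raise ValueError("need 0 < f_min < f_max")
    if f_max >= movie.frame_rate / 2:
        raise ValueError(
            f"band maximum {f_max} Hz is not below Nyquist "
            f"({movie.frame_rate / 2} Hz)"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != movie.shape:
        raise ValueError("mask shape does not match movie frames")
    if not mask.any():
        raise ValueError("mask selects no pixels")

    n = movie.n_frames
    freqs = np.fft.rfftfreq(n, d=1.0 / movie.frame_rate)
    band = (freqs >= f_min) & (freqs <= f_max) & (freqs > 0)
    if not band.any():
        raise ValueError("frequency band contains no FFT bins")

    traces = movie.stack[:, mask].astype(np.float64)
    spec = np.abs(np.fft.rfft(traces - traces.mean(axis=0), axis=0)) ** 2
    in_band = spec[band]
    peak_idx = np.argmax(in_band, axis=0)
    peak_power = in_band[peak_idx, np.arange(in_band.shape[1])]
    med = np.median(in_band, axis=0)
    conf = peak_power / np.where(med > 0, med, np.inf)

    frequency = np.full(movie.shape, np.nan)
    confidence = np.full(movie.shape, np.nan)
    frequency[mask] = freqs[band][peak_idx]
    confidence[mask] = conf
    low_conf = confidence < min_prominence
    return CBFMap(
        frequency=frequency,
        mask=mask & ~low_conf,
        confidence=confidence,
        band=(f_min, f_max),
        resolution=movie.frame_rate / n,
    )


def segment_ciliated_cells(
    cbf: CBFMap,
    sigma_f: float = 1.0,
    min_area: int = 20,
) -> CellLabelMap:
    """Group frequency-coherent connected pixels into cells.

    Region growing over the validated mask with 8-connectivity: a component
    absorbs a neighbouring pixel only while its CBF standard deviation stays
    at or below ``sigma_f``; components below ``min_area`` pixels are
    dropped.  Two touching patches beating at clearly different frequencies
    therefore receive distinct labels.
    """
    mask = cbf.mask & np.isfinite(cbf.frequency)
    freq = cbf.frequency
    labels = np.zeros(mask.shape, dtype=np.int32)
    visited = ~mask  # treat background as visited
    nrow, ncol = mask.shape
    nbr = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    next_label = 0
    seeds = np.argwhere(mask)
    for r0, c0 in seeds:
        if visited[r0, c0]:
            continue
        next_label += 1
        # Welford accumulators for the component's frequency spread
        count, mean, m2 = 0, 0.0, 0.0
        queue = [(int(r0), int(c0))]
        visited[r0, c0] = True
        members = []
        while queue:
            r, c = queue.pop()
            f = freq[r, c]
            new_count = count + 1
            delta = f - mean
            new_mean = mean + delta / new_count
            new_m2 = m2 + delta * (f - new_mean)
            if count > 0 and np.sqrt(new_m2 / new_count) > sigma_f:
                visited[r, c] = False  # leave it for another component
                continue
            count, mean, m2 = new_count, new_mean, new_m2
            members.append((r, c))
            labels[r, c] = next_label
            for dr, dc in nbr:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol and not visited[rr, cc]:
                    visited[rr, cc] = True
                    queue.append((rr, cc))
        if len(members) < min_area:
            for r, c in members:
                labels[r, c] = 0
            next_label -= 1

    # compact label ids (dropped components left gaps)
    out = np.zeros_like(labels)
    for new_id, old_id in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old_id] = new_id
    return CellLabelMap(labels=out)


# ---------------------------------------------------------------------------
# tracer branch: PIV
# ---------------------------------------------------------------------------

def piv(
    fl_movie: Movie,
    box_size: int = 32,
    *,
    min_texture_std: float = 1e-6,
    max_displacement: float | None = None,
) -> FlowField:
    """Particle image velocimetry on a regular grid of interrogation boxes.

    Consecutive frames are cross-correlated per box (FFT correlation of
    mean-subtracted windows) and the correlation peak located with a
    three-point Gaussian sub-pixel fit; displacements are averaged over all
    frame pairs and converted to µm/s.  Boxes without image texture are
    marked invalid.
    """
    stack = fl_movie.stack.astype(np.float64)
    nt, nr, nc = stack.shape
    nby, nbx = nr // box_size, nc // box_size
    if nby == 0 or nbx == 0:
        raise ValueError("frame smaller than one interrogation box")
    if max_displacement is None:
        max_displacement = box_size / 3

    # (frames, nby, nbx, box, box) view via reshape
    crop = stack[:, : nby * box_size, : nbx * box_size]
    blocks = crop.reshape(nt, nby, box_size, nbx, box_size).transpose(0, 1, 3, 2, 4)

    # zero-padded linear cross-correlation, normalized by the per-lag overlap
    # area so the peak position is unbiased (circular correlation biases
    # displacements toward zero through its wrapped-edge contributions)
    pad = 2 * box_size
    mx = int(np.ceil(max_displacement))
    mx = min(mx, box_size - 2)
    lags = np.arange(-mx, mx + 1)
    overlap = np.outer(box_size - np.abs(lags), box_size - np.abs(lags))
    ctr = pad // 2

    disp_sum = np.zeros((nby, nbx, 2))
    disp_cnt = np.zeros((nby, nbx), dtype=int)
    for t in range(nt - 1):
        a = blocks[t]
        b = blocks[t + 1]
        a = a - a.mean(axis=(-2, -1), keepdims=True)
        b = b - b.mean(axis=(-2, -1), keepdims=True)
        ok = (a.std(axis=(-2, -1)) > min_texture_std) & (
            b.std(axis=(-2, -1)) > min_texture_std
        )
        fa = np.fft.rfft2(a, s=(pad, pad))
        fb = np.fft.rfft2(b, s=(pad, pad))
        corr = np.fft.irfft2(np.conj(fa) * fb, s=(pad, pad))
        corr = np.fft.fftshift(corr, axes=(-2, -1))
        corr = corr[..., ctr - mx : ctr + mx + 1, ctr - mx : ctr + mx + 1]
        corr = corr / overlap
        flat = corr.reshape(nby, nbx, -1)
        pk = flat.argmax(axis=-1)
        pr, pc = np.unravel_index(pk, corr.shape[-2:])

        sub_y = _gaussian_subpixel(corr, pr, pc, axis=0)
        sub_x = _gaussian_subpixel(corr, pr, pc, axis=1)
        dyf = pr - mx + sub_y
        dxf = pc - mx + sub_x
        ok &= (np.abs(dyf) <= max_displacement) & (np.abs(dxf) <= max_displacement)
        disp_sum[..., 0] += np.where(ok, dxf, 0.0)
        disp_sum[..., 1] += np.where(ok, dyf, 0.0)
        disp_cnt += ok

    valid = disp_cnt > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_disp = disp_sum / disp_cnt[..., None]
    scale = fl_movie.frame_rate * fl_movie.pixel_size  # px/frame -> µm/s
    vx = np.where(valid, mean_disp[..., 0] * scale, np.nan)
    vy = np.where(valid, mean_disp[..., 1] * scale, np.nan)
    return FlowField(
        vx=vx, vy=vy, valid=valid, box_size=box_size, pixel_size=fl_movie.pixel_size
    )


def _gaussian_subpixel(corr, pr, pc, axis):
    """Three-point Gaussian peak interpolation along one axis, batched."""
    n = corr.shape[-1]
    iy, ix = np.meshgrid(
        np.arange(corr.shape[0]), np.arange(corr.shape[1]), indexing="ij"
    )
    if axis == 0:
        prc = np.clip(pr, 1, n - 2)
        pm = corr[iy, ix, prc - 1, pc]
        p0 = corr[iy, ix, prc, pc]
        pp = corr[iy, ix, prc + 1, pc]
    else:
        pcc = np.clip(pc, 1, n - 2)
        pm = corr[iy, ix, pr, pcc - 1]
        p0 = corr[iy, ix, pr, pcc]
        pp = corr[iy, ix, pr, pcc + 1]
    eps = 1e-12
    lm = np.log(np.maximum(pm, eps))
    l0 = np.log(np.maximum(p0, eps))
    lp = np.log(np.maximum(pp, eps))
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (lm - lp) / (lm - 2 * l0 + lp)
    shift = np.where((pm > 0) & (p0 > 0) & (pp > 0), shift, 0.0)
    return np.clip(np.nan_to_num(shift), -1.0, 1.0)


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def registration_offset(movie_a: Movie, movie_b: Movie) -> tuple[float, float]:
    """(row, col) shift between the mean frames of two movies, px."""
    shift, _, _ = phase_cross_correlation(
        movie_a.mean_frame(), movie_b.mean_frame(), upsample_factor=4
    )
    return float(shift[0]), float(shift[1])


def cells_to_boxes(
    labels: CellLabelMap,
    flow: FlowField,
    cbf: CBFMap,
    *,
    min_frac: float = 0.1,
    drift_px: tuple[float, float] | None = None,
    max_drift: float = 2.0,
) -> list[CellRecord]:
    """Merge cell labels, CBF and PIV into per-box cell records.

    A box is kept when at least ``min_frac`` of its pixels belong to
    identified ciliated cells and its PIV vector is valid and non-zero; the
    record carries the mean CBF of the cell pixels inside the box, the flow
    vector and its unit direction.  If a drift estimate between the two
    movies is supplied and exceeds ``max_drift`` pixels the field of view is
    considered misregistered and the merge refuses to run.
    """
    if drift_px is not None:
        drift = float(np.hypot(*drift_px))
        if drift > max_drift:
            raise RuntimeError(
                f"bright-field and tracer movies are misregistered "
                f"(drift {drift:.1f} px > {max_drift} px)"
            )
    b = flow.box_size
    lab = labels.labels
    nby, nbx = flow.grid_shape
    records: list[CellRecord] = []
    for i in range(nby):
        for j in range(nbx):
            tile = lab[i * b : (i + 1) * b, j * b : (j + 1) * b]
            frac = np.count_nonzero(tile) / tile.size
            if frac < min_frac or not flow.valid[i, j]:
                continue
            vx, vy = flow.vx[i, j], flow.vy[i, j]
            speed = np.hypot(vx, vy)
            if not np.isfinite(speed) or speed == 0.0:
                continue
            ftile = cbf.frequency[i * b : (i + 1) * b, j * b : (j + 1) * b]
            cell_px = (tile > 0) & np.isfinite(ftile)
            mean_cbf = float(ftile[cell_px].mean()) if cell_px.any() else np.nan
            records.append(
                CellRecord(
                    box_i=i,
                    box_j=j,
                    x_um=(j + 0.5) * b * flow.pixel_size,
                    y_um=(i + 0.5) * b * flow.pixel_size,
                    cbf_hz=mean_cbf,
                    vx_um_s=float(vx),
                    vy_um_s=float(vy),
                    direction=(float(vx / speed), float(vy / speed)),
                )
            )
    return records


def analyze_fov(
    bf_movie: Movie,
    fl_movie: Movie,
    *,
    f_min: float = 1.0,
    f_max: float = 50.0,
    sigma_f: float = 1.0,
    min_area: int = 20,
    box_size: int = 32,
    min_frac: float = 0.1,
    check_drift: bool = False,
    max_drift: float = 2.0,
):
    """Full single-field-of-view analysis.

    Returns ``(records, cbf_map, label_map, flow_field)``.  ``check_drift``
    enables the registration check between the two movies (meaningful when
    both show the same structures).
    """
    std = activity_std_map(bf_movie)
    mask = otsu_mask(std)
    cbf = pixel_cbf(bf_movie, mask, f_min, f_max)
    cells = segment_ciliated_cells(cbf, sigma_f=sigma_f, min_area=min_area)
    flow = piv(fl_movie, box_size=box_size)
    drift = registration_offset(bf_movie, fl_movie) if check_drift else None
    records = cells_to_boxes(
        cells, flow, cbf, min_frac=min_frac, drift_px=drift, max_drift=max_drift
    )
    return records, cbf, cells, flow


def count_boxes(shape: tuple[int, int], box_size: int = 32) -> int:
    """Total number of interrogation boxes tiling a frame."""
    return (shape[0] // box_size) * (shape[1] // box_size)
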