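"""Single-molecule localization (dSTORM) post-processing and spatial statistics.

The processing chain mirrors a standard SMLM pipeline for receptor-cluster
analysis on fixed cells:

1. :func:`filter_localizations` — keep localizations with photon count
   strictly above a threshold (default 400 photons).
2. :func:`merge_blinks` — localizations appearing within one camera pixel in
   up to five consecutive frames are merged into one localization at their
   photon-weighted centroid (re-blinking overcounting control).
3. :func:`drift_correct` — stage drift is estimated by reconstructing
   localization images from 500-frame segments and cross-correlating each
   against the first segment, then interpolated across frames and subtracted.
4. :func:`pair_autocorrelation` — edge-corrected pair auto-correlation g(r)
   of the localization density inside a region-of-interest mask; g = 1 for
   complete spatial randomness, g > 1 at short r indicates clustering.
5. :func:`dbscan_clusters` — DBSCAN cluster detection (default: at least 7
   neighbors within r = 25 nm for a core point) and per-cell cluster-size
   summaries.

The g(r) estimator computes the autocorrelation of the binned localization
image by FFT and normalises it by the autocorrelation of the mask, which
corrects for edge effects of arbitrarily shaped regions; the zero-lag
self-pair contribution is removed so a Poisson pattern yields g = 1 at all
radii including the first bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.fft import fft2, ifft2
from sklearn.cluster import DBSCAN

__all__ = [
    "RegionMask",
    "LocalizationTable",
    "CorrelationCurve",
    "ClusterResult",
    "filter_localizations",
    "merge_blinks",
    "drift_correct",
    "pair_autocorrelation",
    "dbscan_clusters",
]


# ---------------------------------------------------------------------------
# Region-of-interest mask
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMask:
    """Boolean region-of-interest in the localization coordinate frame.

    ``array[i, j]`` covers the square ``[j*pixel_nm, (j+1)*pixel_nm) x
    [i*pixel_nm, (i+1)*pixel_nm)`` offset by ``origin_nm`` — i.e. rows are y,
    columns are x, matching image conventions.
    """

    array: np.ndarray
    pixel_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=bool)
        object.__setattr__(self, "array", arr)
        if self.pixel_nm <= 0:
            raise ValueError("mask pixel size must be positive")
        if arr.ndim != 2 or not arr.any():
            raise ValueError("mask must be a non-empty 2D boolean region")

    @classmethod
    def from_rect(cls, width_nm: float, height_nm: float, pixel_nm: float = 20.0) -> "RegionMask":
        nx = max(int(round(width_nm / pixel_nm)), 1)
        ny = max(int(round(height_nm / pixel_nm)), 1)
        return cls(np.ones((ny, nx), dtype=bool), pixel_nm)

    @property
    def area_nm2(self) -> float:
        return float(self.array.sum()) * self.pixel_nm**2

    @property
    def extent_nm(self) -> tuple[float, float]:
        ny, nx = self.array.shape
        return nx * self.pixel_nm, ny * self.pixel_nm

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float) - self.origin_nm[0]
        y = np.asarray(y, dtype=float) - self.origin_nm[1]
        j = np.floor(x / self.pixel_nm).astype(int)
        i = np.floor(y / self.pixel_nm).astype(int)
        ny, nx = self.array.shape
        ok = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
        out = np.zeros(x.shape, dtype=bool)
        out[ok] = self.array[i[ok], j[ok]]
        return out

    def save(self, path: str | Path) -> None:
        """Write as an 8-bit image (PNG or TIFF by extension)."""
        path = Path(path)
        img = (self.array.astype(np.uint8)) * 255
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, img)
        else:
            import imageio.v3 as iio

            iio.imwrite(path, img)

    @classmethod
    def load(cls, path: str | Path, pixel_nm: float) -> "RegionMask":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            img = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            img = iio.imread(path)
        if img.ndim == 3:
            img = img[..., 0]
        return cls(img > 0, pixel_nm)


# ---------------------------------------------------------------------------
# Localization table
# ---------------------------------------------------------------------------

@dataclass
class LocalizationTable:
    """List of single-molecule localizations (x, y in nm, frame, photons)."""

    records: pd.DataFrame
    pixel_size_nm: float | None = None
    mask: RegionMask | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"x_nm", "y_nm", "frame", "photons"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        xy = self.records[["x_nm", "y_nm"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("coordinates must be finite")
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, pixel_size_nm: float | None = None, mask: RegionMask | None = None
    ) -> "LocalizationTable":
        return cls(pd.read_csv(path), pixel_size_nm=pixel_size_nm, mask=mask)


@dataclass(frozen=True)
class CorrelationCurve:
    """Radially averaged pair auto-correlation g(r)."""

    radii_nm: np.ndarray
    g: np.ndarray
    n_localizations: int
    mask_area_nm2: float
    bin_width_nm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_nm": self.radii_nm, "g": self.g})


@dataclass(frozen=True)
class ClusterResult:
    """DBSCAN cluster assignment and per-cell size summary.

    ``labels`` follows the input record order; noise is labelled -1.
    Cluster sizes count localizations per cluster; the per-cell summary is
    the mean and SD of cluster size taken over clusters, not localizations.
    """

    labels: np.ndarray
    cluster_sizes: np.ndarray
    mean_size: float
    sd_size: float

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_sizes.size)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_localizations(raw: LocalizationTable, photon_min: int = 400) -> LocalizationTable:
    """Keep localizations with photon count strictly above ``photon_min``."""
    if photon_min < 0:
        raise ValueError("photon_min must be >= 0")
    kept = raw.records[raw.records["photons"] > photon_min].reset_index(drop=True)
    return replace(raw, records=kept)


def merge_blinks(
    locs: LocalizationTable,
    max_consecutive_frames: int = 5,
    merge_radius_nm: float | None = None,
) -> LocalizationTable:
    """Merge re-blinking events into single localizations.

    Chains of localizations appearing in consecutive frames, each within
    ``merge_radius_nm`` (default: one camera pixel) of the chain's previous
    member, are collapsed to one localization at their photon-weighted
    centroid with summed photons; a chain is capped at
    ``max_consecutive_frames`` frames, so longer on-events split into
    successive merged records. Output rows carry the chain's first frame and
    an ``n_frames`` column with the number of frames merged, which makes the
    operation idempotent: an already-merged record at the frame cap cannot
    absorb more frames.
    """
    if merge_radius_nm is None:
        if locs.pixel_size_nm is None:
            raise ValueError("merge radius defaults to one pixel: set pixel_size_nm or pass merge_radius_nm")
        merge_radius_nm = locs.pixel_size_nm
    rec = locs.records.copy()
    if "n_frames" not in rec.columns:
        rec["n_frames"] = 1
    rec = rec.sort_values(["frame", "x_nm", "y_nm"], kind="mergesort").reset_index(drop=True)

    x = rec["x_nm"].to_numpy(float)
    y = rec["y_nm"].to_numpy(float)
    fr = rec["frame"].to_numpy(int)
    ph = rec["photons"].to_numpy(float)
    nf = rec["n_frames"].to_numpy(int)

    chains: list[dict] = []  # active chains
    done: list[dict] = []
    r2 = merge_radius_nm**2
    for i in range(len(rec)):
        start, end = fr[i], fr[i] + nf[i] - 1
        # retire chains that can no longer be extended
        still = []
        for c in chains:
            if c["end"] >= start - 1:
                still.append(c)
            else:
                done.append(c)
        chains = still
        best = None
        best_d2 = r2
        for c in chains:
            if c["end"] != start - 1 or c["frames"] + nf[i] > max_consecutive_frames:
                continue
            d2 = (c["lx"] - x[i]) ** 2 + (c["ly"] - y[i]) ** 2
            if d2 <= best_d2:
                best_d2 = d2
                best = c
        if best is None:
            chains.append(
                {"first": start, "end": end, "frames": nf[i], "lx": x[i], "ly": y[i],
                 "wx": ph[i] * x[i], "wy": ph[i] * y[i], "w": ph[i]}
            )
        else:
            best["end"] = end
            best["frames"] += nf[i]
            best["lx"], best["ly"] = x[i], y[i]
            best["wx"] += ph[i] * x[i]
            best["wy"] += ph[i] * y[i]
            best["w"] += ph[i]
    done.extend(chains)
    done.sort(key=lambda c: (c["first"], c["wx"] / c["w"], c["wy"] / c["w"]))
    merged = pd.DataFrame(
        {
            "x_nm": [c["wx"] / c["w"] for c in done],
            "y_nm": [c["wy"] / c["w"] for c in done],
            "frame": [c["first"] for c in done],
            "photons": [c["w"] for c in done],
            "n_frames": [c["frames"] for c in done],
        }
    )
    return replace(locs, records=merged)


def _bin_image(x: np.ndarray, y: np.ndarray, bin_nm: float, x0: float, y0: float, shape: tuple[int, int]) -> np.ndarray:
    j = np.floor((x - x0) / bin_nm).astype(int)
    i = np.floor((y - y0) / bin_nm).astype(int)
    ny, nx = shape
    ok = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
    img = np.zeros(shape, dtype=float)
    np.add.at(img, (i[ok], j[ok]), 1.0)
    return img


def drift_correct(
    locs: LocalizationTable,
    segment_frames: int = 500,
    bin_nm: float = 20.0,
    upsample_factor: int = 50,
    min_localizations_per_segment: int = 10,
) -> LocalizationTable:
    """Estimate and subtract stage drift by segment image correlation.

    Localization images are reconstructed from ``segment_frames``-frame
    subsets and registered against the first segment by phase
    cross-correlation (sub-pixel, ``1/upsample_factor`` of ``bin_nm``).
    Per-segment shifts are interpolated linearly across frames (anchored at
    segment centers) and subtracted from the coordinates.
    """
    from skimage.registration import phase_cross_correlation

    rec = locs.records
    frames = rec["frame"].to_numpy(int)
    seg = frames // segment_frames
    n_seg = int(seg.max()) + 1 if len(rec) else 0
    if n_seg < 2:
        warnings.warn("fewer than 2 frame segments: drift correction is the identity", stacklevel=2)
        return replace(locs, records=rec.copy())

    x = rec["x_nm"].to_numpy(float)
    y = rec["y_nm"].to_numpy(float)
    pad = 2 * bin_nm
    x0, y0 = x.min() - pad, y.min() - pad
    nx = int(np.ceil((x.max() + pad - x0) / bin_nm)) + 1
    ny = int(np.ceil((y.max() + pad - y0) / bin_nm)) + 1

    ref = None
    shifts = np.full((n_seg, 2), np.nan)  # (dx, dy) in nm: drift of segment relative to first
    counts = np.zeros(n_seg, dtype=int)
    for s in range(n_seg):
        sel = seg == s
        counts[s] = int(sel.sum())
        if counts[s] < min_localizations_per_segment:
            continue
        img = _bin_image(x[sel], y[sel], bin_nm, x0, y0, (ny, nx))
        if ref is None:
            ref = img
            shifts[s] = 0.0
            continue
        shift, _, _ = phase_cross_correlation(ref, img, upsample_factor=upsample_factor, normalization=None)
        # shift registers the segment image onto the reference: segment drifted by -shift
        shifts[s] = (-shift[1] * bin_nm, -shift[0] * bin_nm)

    bad = np.isnan(shifts[:, 0])
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} segment(s) with < {min_localizations_per_segment} localizations: "
            "shift interpolated from neighbors",
            stacklevel=2,
        )
        good = ~bad
        idx = np.arange(n_seg)
        for k in (0, 1):
            shifts[bad, k] = np.interp(idx[bad], idx[good], shifts[good, k])

    centers = (np.arange(n_seg) + 0.5) * segment_frames
    dx = np.interp(frames, centers, shifts[:, 0])
    dy = np.interp(frames, centers, shifts[:, 1])
    out = rec.copy()
    out["x_nm"] = x - dx
    out["y_nm"] = y - dy
    meta = dict(locs.metadata)
    meta["drift_shifts_nm"] = shifts.tolist()
    return replace(locs, records=out, metadata=meta)


def pair_autocorrelation(
    locs: LocalizationTable,
    r_max: float = 500.0,
    bin_width: float = 5.0,
    mask: RegionMask | None = None,
    grid_nm: float | None = None,
) -> CorrelationCurve:
    """Edge-corrected pair auto-correlation g(r) within a mask.

    The localization density is binned into an image at ``grid_nm`` pixels
    (default 5 nm, never coarser than ``bin_width``) covering the mask; the
    image autocorrelation (computed with zero-padded FFTs) is normalised by
    the mask autocorrelation, which counts the pixel pairs available at each
    lag and thereby corrects for edges. The zero-lag self-pair term is
    subtracted, so a completely spatially random pattern gives g(r) = 1 at
    every radius. Lags are radially averaged into bins of ``bin_width`` up
    to ``r_max``.
    """
    mask = mask or locs.mask
    if mask is None:
        raise ValueError("pair_autocorrelation requires a region mask")
    x, y = locs.xy[:, 0], locs.xy[:, 1]
    inside = mask.contains(x, y)
    x, y = x[inside], y[inside]
    n = x.size
    if n < 50:
        raise ValueError(f"need >= 50 localizations inside the mask, got {n}")

    w_nm, h_nm = mask.extent_nm
    max_extent = float(np.hypot(w_nm, h_nm))
    if r_max > max_extent:
        warnings.warn("r_max beyond mask extent: truncating", stacklevel=2)
        r_max = max_extent

    if grid_nm is None:
        grid_nm = min(5.0, bin_width)
    if grid_nm > bin_width:
        raise ValueError("grid_nm must not exceed the radial bin_width")
    ox, oy = mask.origin_nm
    nx = int(np.ceil(w_nm / grid_nm))
    ny = int(np.ceil(h_nm / grid_nm))
    img = _bin_image(x, y, grid_nm, ox, oy, (ny, nx))

    # resample the mask onto the analysis grid (pixel-center lookup)
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    mx = ox + (jj + 0.5) * grid_nm
    my = oy + (ii + 0.5) * grid_nm
    m = mask.contains(mx.ravel(), my.ravel()).reshape(ny, nx).astype(float)
    img *= m
    n_in = img.sum()
    if n_in < 50:
        raise ValueError("fewer than 50 localizations on the masked analysis grid")

    py, px = 2 * ny, 2 * nx
    fi = fft2(img, s=(py, px))
    fm = fft2(m, s=(py, px))
    corr = np.real(ifft2(fi * np.conj(fi)))
    wcorr = np.real(ifft2(fm * np.conj(fm)))
    corr[0, 0] -= n_in  # remove self pairs

    rho = n_in / m.sum()  # mean localizations per mask pixel
    lag_y = np.fft.fftfreq(py, d=1.0 / py)  # signed lags in pixels
    lag_x = np.fft.fftfreq(px, d=1.0 / px)
    lr = np.hypot(*np.meshgrid(lag_x, lag_y)) * grid_nm

    edges = np.arange(0.0, r_max + 1e-9, bin_width)
    if len(edges) < 2:
        raise ValueError("r_max must be at least one bin_width")
    which = np.digitize(lr.ravel(), edges) - 1
    nbins = len(edges) - 1
    valid = (which >= 0) & (which < nbins) & (wcorr.ravel() > 0.5)
    num = np.bincount(which[valid], weights=corr.ravel()[valid], minlength=nbins)
    den = np.bincount(which[valid], weights=wcorr.ravel()[valid], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = num / (rho**2 * den)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = den > 0
    return CorrelationCurve(
        radii_nm=centers[keep],
        g=g[keep],
        n_localizations=int(n_in),
        mask_area_nm2=mask.area_nm2,
        bin_width_nm=bin_width,
    )


def dbscan_clusters(
    locs: LocalizationTable,
    radius: float = 25.0,
    min_neighbors: int = 7,
) -> ClusterResult:
    """DBSCAN clustering of localizations with per-cell size summary.

    A core point has at least ``min_neighbors`` *other* localizations within
    ``radius`` nm; clusters are maximal density-connected sets and all
    remaining points are noise (label -1). Records are scanned in
    (x, y, frame) sort order so border-point assignment is deterministic.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    rec = locs.records
    order = np.lexsort((rec["frame"].to_numpy(), rec["y_nm"].to_numpy(float), rec["x_nm"].to_numpy(float)))
    xy = locs.xy[order]
    if len(xy) == 0:
        return ClusterResult(np.array([], dtype=int), np.array([], dtype=int), float("nan"), float("nan"))
    # scikit-learn's min_samples counts the point itself
    model = DBSCAN(eps=radius, min_samples=min_neighbors + 1)
    sorted_labels = model.fit_predict(xy)
    labels = np.empty(len(xy), dtype=int)
    labels[order] = sorted_labels
    uniq, sizes = np.unique(sorted_labels[sorted_labels >= 0], return_counts=True)
    if sizes.size:
        mean = float(np.mean(sizes))
        sd = float(np.std(sizes, ddof=1)) if sizes.size > 1 else 0.0
    else:
        mean = sd = float("nan")
    return ClusterResult(labels=labels, cluster_sizes=sizes, mean_size=mean, sd_size=sd)
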