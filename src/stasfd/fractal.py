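"""Box-counting fractal dimension for binary tumor masks.

The fractal dimension (FD) of a binary occupancy lattice is estimated by the
classical box-counting method: the lattice is covered by a regular grid of
cubic (or square, in 2D) boxes of edge length ``s``, the number ``N(s)`` of
boxes containing at least one occupied voxel is counted at each scale, and
the FD is the slope of the ordinary least-squares line through the points
``(log 1/s, log N(s))``.  For an object that fills its embedding space the
slope approaches the embedding dimension (3 for volumes, 2 for slices); a
fragmented or sparse object fills large boxes more readily than its voxel
count alone would suggest, flattening the curve and lowering the slope.

Counting operates on the voxel lattice: box edges are integer numbers of
voxels and the grid is anchored at the array origin.  Physical voxel spacing
is carried as metadata only; strongly anisotropic spacing triggers a warning
because lattice-unit counting then mixes physical scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "VoxelMask",
    "BoxCountCurve",
    "FractalEstimate",
    "FdConfig",
    "binarize_volume",
    "default_box_sizes",
    "box_count",
    "fit_fractal_dimension",
    "fd_pipeline",
    "fd2d_pipeline",
    "max_area_slice",
    "qc_linearity_report",
]

#: QC flag names
POOR_LINEARITY = "POOR_LINEARITY"
FD_EXCEEDS_EMBEDDING = "FD_EXCEEDS_EMBEDDING"
TOO_FEW_SCALES = "TOO_FEW_SCALES"
EMPTY_FIT_RANGE = "EMPTY_FIT_RANGE"

#: spacing anisotropy (max/min ratio) above which a warning is raised
ANISOTROPY_WARN_RATIO = 1.2


@dataclass
class VoxelMask:
    """Binary 3D occupancy lattice with physical voxel spacing.

    Parameters
    ----------
    occupancy
        3D boolean array indexed ``(z, y, x)``.
    spacing
        Voxel edge lengths in mm per axis, strictly positive.
    source_id
        Free-text provenance label (file name, phantom spec, ...).
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.dtype != bool:
            if not np.isin(occ, (0, 1)).all():
                raise ValueError("occupancy must be boolean or contain only {0, 1}")
            occ = occ.astype(bool)
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3D, got {occ.ndim}D")
        if min(occ.shape) < 1:
            raise ValueError("all lattice dimensions must be >= 1")
        self.occupancy = occ
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.spacing = sp
        if max(sp) / min(sp) > ANISOTROPY_WARN_RATIO:
            warnings.warn(
                f"anisotropic voxel spacing {sp} (ratio "
                f"{max(sp) / min(sp):.2f} > {ANISOTROPY_WARN_RATIO}); box counting "
                "operates in voxel units and mixes physical scales",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def bounding_extent(self) -> tuple[int, ...]:
        """Per-axis extent (in voxels) of the occupied bounding box."""
        if self.n_occupied == 0:
            return (0, 0, 0)
        idx = np.nonzero(self.occupancy)
        return tuple(int(ax.max() - ax.min() + 1) for ax in idx)


@dataclass
class BoxCountCurve:
    """Occupied-box counts ``N(s)`` over a ladder of box sizes ``s``.

    Sizes are strictly increasing positive integers in voxel units; counts
    must be positive and non-increasing (guaranteed for nested grids such as
    the default power-of-two ladder, where every size divides the next).
    """

    sizes: np.ndarray
    counts: np.ndarray
    embedding_dim: int = 3

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=int)
        counts = np.asarray(self.counts, dtype=int)
        if sizes.ndim != 1 or counts.shape != sizes.shape:
            raise ValueError("sizes and counts must be 1D arrays of equal length")
        if len(sizes) < 1 or (sizes < 1).any():
            raise ValueError("box sizes must be positive integers")
        if (np.diff(sizes) <= 0).any():
            raise ValueError("box sizes must be strictly increasing")
        if (counts < 1).any():
            raise ValueError("box counts must be >= 1 for a non-empty mask")
        if (np.diff(counts) > 0).any():
            raise ValueError("box counts must be non-increasing with box size")
        if self.embedding_dim not in (2, 3):
            raise ValueError("embedding_dim must be 2 or 3")
        self.sizes = sizes
        self.counts = counts

    def select(self, fit_sizes) -> "BoxCountCurve":
        """Sub-curve restricted to ``fit_sizes`` (must be a subset)."""
        fit = np.asarray(sorted(set(int(s) for s in fit_sizes)))
        missing = set(fit) - set(self.sizes.tolist())
        if missing:
            raise ValueError(f"fit sizes {sorted(missing)} not present in curve")
        keep = np.isin(self.sizes, fit)
        return BoxCountCurve(self.sizes[keep], self.counts[keep], self.embedding_dim)


@dataclass
class FractalEstimate:
    """Result of the log-log fit: slope (FD), intercept, linearity, QC flags."""

    fd: float
    intercept: float
    r_squared: float
    fit_sizes: np.ndarray
    qc_flags: frozenset = field(default_factory=frozenset)
    embedding_dim: int = 3
    curve: BoxCountCurve | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.fd):
            raise ValueError("fd must be finite")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))
        self.fit_sizes = np.asarray(self.fit_sizes, dtype=int)
        self.qc_flags = frozenset(self.qc_flags)


@dataclass
class FdConfig:
    """Configuration of the FD pipeline.

    max_box_size
        Upper bound of the power-of-two size ladder.  Fixing this across a
        cohort guarantees identical box-size ranges for every case; ``None``
        uses the largest lattice dimension of the mask at hand.
    fit_max_fraction
        The fit range keeps sizes up to this fraction of the largest extent
        of the occupied bounding box (default one half), suppressing the
        flat large-box tail of the curve.
    linearity_threshold
        ``r_squared`` below this raises the POOR_LINEARITY flag.
    min_scales
        Fewer fit points than this raises the TOO_FEW_SCALES flag.
    minimize_over_offsets
        If true, each count is minimized over all grid phases (s^3 shifts
        per size) instead of using the origin-anchored grid.  Exponential in
        box size; intended for sensitivity analysis on small masks only.
    """

    max_box_size: int | None = None
    fit_max_fraction: float = 0.5
    linearity_threshold: float = 0.98
    min_scales: int = 3
    minimize_over_offsets: bool = False


def binarize_volume(volume, threshold: float, spacing=(1.0, 1.0, 1.0), source_id: str = "") -> VoxelMask:
    """Threshold a real-valued 3D lattice into a :class:`VoxelMask`.

    Voxels strictly greater than ``threshold`` become occupied.  Spacing is
    copied unchanged: no resampling, smoothing or interpolation is applied,
    so the intrinsic geometry of the mask is preserved.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3 or vol.size == 0:
        raise ValueError("volume must be a non-empty 3D lattice")
    if not np.isfinite(vol).all():
        raise ValueError("volume contains non-finite voxel values")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    occ = vol > threshold
    if not occ.any():
        warnings.warn("binarization produced an empty mask", stacklevel=2)
    return VoxelMask(occ, spacing=spacing, source_id=source_id)


def default_box_sizes(shape, max_size: int | None = None) -> list[int]:
    """Power-of-two box-size ladder ``[1, 2, 4, ...]``.

    The ladder runs up to the largest power of two not exceeding
    ``max_size`` (default: ``max(shape)``).  Keeping ``max_size`` fixed
    across a cohort makes the schedule a pure function of configuration, so
    every case is measured over the identical range of scales.
    """
    shape = tuple(int(d) for d in np.atleast_1d(shape))
    if len(shape) < 1 or any(d < 1 for d in shape):
        raise ValueError(f"invalid lattice shape {shape}")
    top = int(max_size) if max_size is not None else max(shape)
    sizes = []
    s = 1
    while s <= top:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        raise ValueError(
            f"shape {shape} with max size {top} admits fewer than two box scales"
        )
    return sizes


def _count_at_size(occ: np.ndarray, s: int) -> int:
    """Number of origin-anchored grid cells of edge s containing occupancy."""
    if s == 1:
        return int(occ.sum())
    pad = [(0, (-d) % s) for d in occ.shape]
    p = np.pad(occ, pad) if any(b for _, b in pad) else occ
    if occ.ndim == 3:
        nz, ny, nx = (d // s for d in p.shape)
        blocks = p.reshape(nz, s, ny, s, nx, s).any(axis=(1, 3, 5))
    else:
        ny, nx = (d // s for d in p.shape)
        blocks = p.reshape(ny, s, nx, s).any(axis=(1, 3))
    return int(blocks.sum())


def _min_count_over_offsets(occ: np.ndarray, s: int) -> int:
    from itertools import product

    best = None
    for off in product(range(s), repeat=occ.ndim):
        pad = [(o, (-(d + o)) % s) for o, d in zip(off, occ.shape)]
        p = np.pad(occ, pad)
        c = _count_at_size(p, s)
        best = c if best is None else min(best, c)
    return best


def box_count(mask, sizes, minimize_over_offsets: bool = False) -> BoxCountCurve:
    """Count occupied boxes of each size over a grid anchored at the origin.

    ``mask`` may be a :class:`VoxelMask` or a bare 2D/3D boolean array.  A
    box of edge ``s`` covers the half-open index range ``[i*s, (i+1)*s)``
    along each axis.  Counting is in voxel units; spacing metadata is not
    used.
    """
    occ = mask.occupancy if isinstance(mask, VoxelMask) else np.asarray(mask, dtype=bool)
    if occ.ndim not in (2, 3):
        raise ValueError("mask must be 2D or 3D")
    if not occ.any():
        raise ValueError("cannot box-count empty mask")
    sizes = [int(s) for s in sizes]
    if len(sizes) < 1 or any(s < 1 for s in sizes) or (np.diff(sizes) <= 0).any():
        raise ValueError("sizes must be strictly increasing positive integers")
    oversized = [s for s in sizes if s >= max(occ.shape)]
    if len(oversized) > 1:
        warnings.warn(
            f"{len(oversized)} box sizes meet or exceed every lattice dimension; "
            "their counts are all 1 and carry no scaling information",
            stacklevel=2,
        )
    counter = _min_count_over_offsets if minimize_over_offsets else _count_at_size
    counts = [counter(occ, s) for s in sizes]
    return BoxCountCurve(np.asarray(sizes), np.asarray(counts), embedding_dim=occ.ndim)


def fit_fractal_dimension(
    curve: BoxCountCurve,
    fit_sizes=None,
    linearity_threshold: float = 0.98,
    min_scales: int = 3,
) -> FractalEstimate:
    """OLS fit of ``log N(s)`` against ``log(1/s)``; the slope is the FD.

    The sign convention (regressing on ``log(1/s)`` rather than ``log s``)
    makes the slope non-negative for any non-empty mask.  QC flags record
    poor linearity, too few scales, and slopes exceeding the embedding
    dimension (impossible for exact box counts on collinear ladders, hence
    diagnostic of a misconfigured fit range).
    """
    sub = curve if fit_sizes is None else curve.select(fit_sizes)
    if len(sub.sizes) < 2:
        raise ValueError("need at least two distinct box sizes to fit a slope")
    if (sub.counts < 1).any():
        raise ValueError("zero count in curve")
    x = np.log(1.0 / sub.sizes.astype(float))
    y = np.log(sub.counts.astype(float))
    if np.allclose(y, y[0]):
        # constant counts: slope 0, perfect fit (e.g. single occupied voxel)
        slope, intercept, r2 = 0.0, float(y[0]), 1.0
    else:
        res = _stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    flags = set()
    if r2 < linearity_threshold:
        flags.add(POOR_LINEARITY)
    if slope > sub.embedding_dim + 1e-9:
        flags.add(FD_EXCEEDS_EMBEDDING)
    if len(sub.sizes) < min_scales:
        flags.add(TOO_FEW_SCALES)
    return FractalEstimate(
        fd=slope,
        intercept=intercept,
        r_squared=r2,
        fit_sizes=sub.sizes,
        qc_flags=frozenset(flags),
        embedding_dim=sub.embedding_dim,
        curve=curve,
    )


def _auto_fit_sizes(sizes, extent: int, fraction: float) -> list[int]:
    limit = extent * fraction
    return [s for s in sizes if s <= limit]


def fd_pipeline(mask: VoxelMask, config: FdConfig | None = None) -> FractalEstimate:
    """Full FD workflow: size ladder, box counting, log-log fit, QC.

    The fit range keeps sizes up to ``fit_max_fraction`` of the largest
    occupied-bounding-box extent (the flat tail where a handful of large
    boxes covers everything contributes no scaling information).  If that
    rule leaves fewer than two scales, the fit falls back to the whole
    ladder and the EMPTY_FIT_RANGE flag is raised.  The counted curve is
    kept on the returned estimate so the log-log points can be archived.
    """
    config = config or FdConfig()
    sizes = default_box_sizes(mask.shape, config.max_box_size)
    curve = box_count(mask, sizes, minimize_over_offsets=config.minimize_over_offsets)
    extent = max(mask.bounding_extent())
    fit = _auto_fit_sizes(sizes, extent, config.fit_max_fraction)
    extra = set()
    if len(fit) < 2:
        fit = sizes
        extra.add(EMPTY_FIT_RANGE)
    est = fit_fractal_dimension(
        curve,
        fit_sizes=fit,
        linearity_threshold=config.linearity_threshold,
        min_scales=config.min_scales,
    )
    if extra:
        est.qc_flags = frozenset(est.qc_flags | extra)
    return est


def max_area_slice(mask: VoxelMask, axis: int = 0) -> np.ndarray:
    """The 2D slice (default axial, axis 0) with the largest occupied area."""
    counts = mask.occupancy.sum(axis=tuple(i for i in range(3) if i != axis))
    k = int(np.argmax(counts))
    return np.take(mask.occupancy, k, axis=axis)


def fd2d_pipeline(mask: VoxelMask, config: FdConfig | None = None, slice_index: int | None = None, axis: int = 0) -> FractalEstimate:
    """2D box-counting FD on one slice (maximum-area slice by default)."""
    config = config or FdConfig()
    if slice_index is None:
        sl = max_area_slice(mask, axis=axis)
    else:
        sl = np.take(mask.occupancy, slice_index, axis=axis)
    if not sl.any():
        raise ValueError("selected slice contains no occupied voxels")
    sizes = default_box_sizes(sl.shape, config.max_box_size)
    curve = box_count(sl, sizes, minimize_over_offsets=config.minimize_over_offsets)
    idx = np.nonzero(sl)
    extent = max(int(ax.max() - ax.min() + 1) for ax in idx)
    fit = _auto_fit_sizes(sizes, extent, config.fit_max_fraction)
    extra = set()
    if len(fit) < 2:
        fit = sizes
        extra.add(EMPTY_FIT_RANGE)
    est = fit_fractal_dimension(
        curve, fit_sizes=fit,
        linearity_threshold=config.linearity_threshold, min_scales=config.min_scales,
    )
    if extra:
        est.qc_flags = frozenset(est.qc_flags | extra)
    return est


def qc_linearity_report(curve: BoxCountCurve, estimate: FractalEstimate, plot_path=None) -> dict:
    """Numeric summary (plus optional log-log plot) of the scaling fit.

    Deterministic given its inputs; returns a JSON-serializable dict with
    the log-log points, fitted line, r^2 and QC flags.  When ``plot_path``
    is given a scatter-plus-fit figure is written there.
    """
    log_inv_s = np.log(1.0 / curve.sizes.astype(float))
    log_n = np.log(curve.counts.astype(float))
    report = {
        "sizes": curve.sizes.tolist(),
        "counts": curve.counts.tolist(),
        "log_inv_size": log_inv_s.tolist(),
        "log_count": log_n.tolist(),
        "fd": estimate.fd,
        "intercept": estimate.intercept,
        "r_squared": estimate.r_squared,
        "fit_sizes": estimate.fit_sizes.tolist(),
        "embedding_dim": estimate.embedding_dim,
        "qc_flags": sorted(estimate.qc_flags),
    }
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(log_inv_s, log_n, label="box counts", zorder=3)
        in_fit = np.isin(curve.sizes, estimate.fit_sizes)
        xs = log_inv_s[in_fit]
        ax.plot(xs, estimate.intercept + estimate.fd * xs, "r-",
                label=f"fit: FD={estimate.fd:.3f}, $r^2$={estimate.r_squared:.4f}")
        ax.set_xlabel("log(1/s)")
        ax.set_ylabel("log N(s)")
        flags = ", ".join(sorted(estimate.qc_flags)) or "none"
        ax.set_title(f"Box-count scaling (flags: {flags})")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        report["plot_path"] = str(plot_path)
    return report
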