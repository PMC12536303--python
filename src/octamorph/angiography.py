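"""Inter-frame intensity-based Doppler variance (IBDV) angiography.

OCT angiography derives flow contrast from the temporal decorrelation of the
backscattered signal: at each slow-scan position the B-scan is repeated J times
(here J = 6, inter-frame interval ΔT = 5 ms) and consecutive repeats are
compared.  Static tissue produces nearly identical speckle realisations, while
moving scatterers (blood) decorrelate the signal between repeats.  The IBDV
statistic quantifies this per voxel from the amplitude |A| alone:

    σ² = 1 − Σ_{j=1}^{J−1} |A_j||A_{j+1}| / Σ_{j=1}^{J−1} (|A_j|² + |A_{j+1}|²)/2

σ² ∈ [0, 1]: 0 for perfectly repeating frames, approaching 1 − π/4 ≈ 0.215 in
expectation for fully decorrelated Rayleigh speckle.  The numerator and
denominator are each averaged over a small lateral window before the ratio is
taken, which suppresses single-voxel speckle noise without biasing the ratio.

The module assembles per-position σ² B-scans into a volume, masks voxels whose
mean amplitude sits in the noise floor (where decorrelation would otherwise
masquerade as flow), and reslices the volume into en-face angiograms by
maximum-intensity projection over a depth range.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
from scipy.ndimage import uniform_filter1d

__all__ = [
    "ScanMeta",
    "OctFrameSeries",
    "DopplerVarianceVolume",
    "EnFaceAngiogram",
    "compute_ibdv",
    "intensity_mask",
    "assemble_volume",
    "enface_mip",
    "read_frames_hdf5",
    "read_frames_tiff_dir",
    "write_sigma2_hdf5",
    "read_sigma2_hdf5",
    "write_angiogram_tiff",
]


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition metadata attached to a repeated-B-scan series.

    Attributes
    ----------
    n_repeats : int
        Number of repeated B-scans per slow-scan position (J).
    dt : float
        Inter-frame interval ΔT in seconds.
    lateral_spacing_um : float
        Pixel pitch along the fast (x) and slow (y) axes, µm.
    axial_spacing_um : float
        Pixel pitch along depth (z), µm.
    """

    n_repeats: int
    dt: float
    lateral_spacing_um: float
    axial_spacing_um: float


@dataclass
class OctFrameSeries:
    """Repeated-B-scan amplitude data.

    ``amplitude`` has shape (n_positions y, J, n_lateral x, n_depth z) and
    holds linear (non-log) amplitudes.  Complex input is accepted and the
    magnitude taken, since the IBDV statistic uses |A| only.
    """

    amplitude: np.ndarray
    meta: ScanMeta

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitude)
        if np.iscomplexobj(a):
            a = np.abs(a)
        if a.ndim != 4:
            raise ValueError(
                f"amplitude must be 4-D (y, repeat, x, z); got shape {a.shape}"
            )
        if a.shape[1] != self.meta.n_repeats:
            raise ValueError(
                f"axis 1 has {a.shape[1]} frames but meta.n_repeats={self.meta.n_repeats}"
            )
        if self.meta.n_repeats < 2:
            raise ValueError("need at least two repeated frames")
        if a.size and float(a.min()) < 0:
            raise ValueError("amplitudes must be nonnegative")
        self.amplitude = a

    @property
    def n_positions(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.amplitude.shape[2]

    @property
    def n_depth(self) -> int:
        return self.amplitude.shape[3]

    def mean_bscan(self, position: int) -> np.ndarray:
        """Mean amplitude over the J repeats at one position, shape (x, z)."""
        return self.amplitude[position].mean(axis=0)


@dataclass
class DopplerVarianceVolume:
    """Per-voxel IBDV σ², shape (y, x, z); NaN where the intensity mask removed
    low-amplitude voxels.  ``mask`` is True for kept voxels."""

    sigma2: np.ndarray
    mask: np.ndarray
    meta: ScanMeta

    @property
    def n_depth(self) -> int:
        return self.sigma2.shape[2]


@dataclass
class EnFaceAngiogram:
    """2-D en-face projection of σ² over ``depth_range`` = [z_lo, z_hi)."""

    image: np.ndarray
    depth_range: tuple[int, int]
    lateral_spacing_um: float
    projection: str = "max"


def compute_ibdv(
    frames: np.ndarray,
    window: int = 2,
    depth_window: bool = False,
) -> np.ndarray:
    """IBDV σ² B-scan from J repeated frames at one slow-scan position.

    Parameters
    ----------
    frames : array, shape (J, x, z)
        Repeated B-scan amplitudes (complex accepted; magnitude is taken).
    window : int
        Lateral averaging half-width: numerator and denominator are each
        averaged over ``2*window + 1`` neighbouring A-lines before the ratio.
        ``window=0`` gives the pure per-voxel statistic.
    depth_window : bool
        If True, additionally average numerator and denominator over a
        1-voxel depth window (3 samples).

    Returns
    -------
    sigma2 : float64 array, shape (x, z), clipped to [0, 1].  Voxels with zero
        denominator (no signal in the whole averaging window) are set to 0:
        no signal carries no measurable flow.  σ² is invariant under global
        amplitude scaling.
    """
    a = np.asarray(frames)
    if np.iscomplexobj(a):
        a = np.abs(a)
    a = a.astype(np.float64, copy=False)
    if a.ndim != 3:
        raise ValueError(f"frames must be 3-D (J, x, z); got shape {a.shape}")
    if a.shape[0] < 2:
        raise ValueError("need at least two repeated frames")
    if window < 0:
        raise ValueError("window must be >= 0")

    # consecutive-pair sums over j = 1..J-1
    num = np.einsum("jxz,jxz->xz", a[:-1], a[1:])
    den = 0.5 * (np.einsum("jxz,jxz->xz", a[:-1], a[:-1])
                 + np.einsum("jxz,jxz->xz", a[1:], a[1:]))
    if window > 0:
        size = 2 * window + 1
        num = uniform_filter1d(num, size=size, axis=0, mode="nearest")
        den = uniform_filter1d(den, size=size, axis=0, mode="nearest")
    if depth_window:
        num = uniform_filter1d(num, size=3, axis=1, mode="nearest")
        den = uniform_filter1d(den, size=3, axis=1, mode="nearest")

    sigma2 = np.zeros_like(den)
    nz = den > 0
    sigma2[nz] = 1.0 - num[nz] / den[nz]
    return np.clip(sigma2, 0.0, 1.0)


def intensity_mask(series: OctFrameSeries, threshold_quantile: float = 0.25) -> np.ndarray:
    """Boolean (y, x, z) mask of voxels with signal above the noise floor.

    A voxel is kept iff its mean amplitude over the J repeats is strictly
    above the given quantile of the volume-wide mean-amplitude distribution.
    ``threshold_quantile = 0`` keeps every voxel.
    """
    if not 0 <= threshold_quantile < 1:
        raise ValueError("threshold_quantile must be in [0, 1)")
    mean_amp = series.amplitude.mean(axis=1)
    if threshold_quantile == 0:
        return np.ones(mean_amp.shape, dtype=bool)
    thr = float(np.quantile(mean_amp, threshold_quantile))
    return mean_amp > thr


def assemble_volume(
    series: OctFrameSeries,
    window: int = 2,
    threshold_quantile: float = 0.25,
    depth_window: bool = False,
) -> DopplerVarianceVolume:
    """Apply :func:`compute_ibdv` at every slow-scan position and mask the
    noise floor; masked voxels become NaN in ``sigma2``."""
    ny = series.n_positions
    sigma2 = np.empty((ny, series.n_lateral, series.n_depth), dtype=np.float32)
    for y in range(ny):
        sigma2[y] = compute_ibdv(series.amplitude[y], window=window,
                                 depth_window=depth_window)
    mask = intensity_mask(series, threshold_quantile)
    sigma2[~mask] = np.nan
    return DopplerVarianceVolume(sigma2=sigma2, mask=mask, meta=series.meta)


def enface_mip(
    volume: DopplerVarianceVolume,
    depth_range: tuple[int, int] | None = None,
) -> EnFaceAngiogram:
    """En-face angiogram: per (y, x), maximum σ² over [z_lo, z_hi), ignoring
    NaN; columns that are all-NaN in the range project to 0."""
    nz = volume.n_depth
    if depth_range is None:
        depth_range = (0, nz)
    z_lo, z_hi = int(depth_range[0]), int(depth_range[1])
    if not (0 <= z_lo < z_hi <= nz):
        raise ValueError(
            f"empty or out-of-bounds depth range [{z_lo}, {z_hi}) for n_depth={nz}"
        )
    sub = volume.sigma2[:, :, z_lo:z_hi]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        img = np.nanmax(sub, axis=2)
    img = np.where(np.isfinite(img), img, 0.0).astype(np.float32)
    return EnFaceAngiogram(
        image=img,
        depth_range=(z_lo, z_hi),
        lateral_spacing_um=volume.meta.lateral_spacing_um,
    )


# ---------------------------------------------------------------------------
# I/O: HDF5 volumes, multi-page TIFF stacks, 32-bit TIFF angiograms
# ---------------------------------------------------------------------------

def read_frames_hdf5(path: str | Path) -> OctFrameSeries:
    """Read a repeated-B-scan series from the phantom HDF5 layout
    (dataset ``/frames`` of shape (y, j, x, z); metadata as root attributes)."""
    with h5py.File(path, "r") as f:
        frames = f["frames"][()]
        attrs = f.attrs
        meta = ScanMeta(
            n_repeats=int(attrs["J"]),
            dt=float(attrs["dt"]),
            lateral_spacing_um=float(attrs["lateral_spacing_um"]),
            axial_spacing_um=float(attrs["axial_spacing_um"]),
        )
    return OctFrameSeries(amplitude=frames, meta=meta)


def read_frames_tiff_dir(
    directory: str | Path,
    dt: float,
    lateral_spacing_um: float,
    axial_spacing_um: float,
    pattern: str = "*.tif*",
) -> OctFrameSeries:
    """Read per-position multi-page TIFF stacks (page order = repeat index).

    Files are sorted by name; each must contain the same number of pages J,
    each page an (x, z) amplitude image.
    """
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no TIFF stacks matching {pattern!r} in {directory}")
    stacks = [tifffile.imread(f) for f in files]
    for f, s in zip(files, stacks):
        if s.ndim != 3 or s.shape != stacks[0].shape:
            raise ValueError(f"stack {f.name} has shape {s.shape}; expected "
                             f"uniform (J, x, z) stacks")
    frames = np.stack(stacks, axis=0)
    meta = ScanMeta(
        n_repeats=frames.shape[1],
        dt=dt,
        lateral_spacing_um=lateral_spacing_um,
        axial_spacing_um=axial_spacing_um,
    )
    return OctFrameSeries(amplitude=frames, meta=meta)


def write_sigma2_hdf5(path: str | Path, volume: DopplerVarianceVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sigma2", data=volume.sigma2.astype(np.float32),
                         compression="gzip")
        f.create_dataset("mask", data=volume.mask, compression="gzip")
        f.attrs["J"] = volume.meta.n_repeats
        f.attrs["dt"] = volume.meta.dt
        f.attrs["lateral_spacing_um"] = volume.meta.lateral_spacing_um
        f.attrs["axial_spacing_um"] = volume.meta.axial_spacing_um


def read_sigma2_hdf5(path: str | Path) -> DopplerVarianceVolume:
    with h5py.File(path, "r") as f:
        sigma2 = f["sigma2"][()]
        mask = f["mask"][()].astype(bool)
        meta = ScanMeta(
            n_repeats=int(f.attrs["J"]),
            dt=float(f.attrs["dt"]),
            lateral_spacing_um=float(f.attrs["lateral_spacing_um"]),
            axial_spacing_um=float(f.attrs["axial_spacing_um"]),
        )
    return DopplerVarianceVolume(sigma2=sigma2, mask=mask, meta=meta)


def write_angiogram_tiff(path: str | Path, angiogram: EnFaceAngiogram) -> None:
    """Write the en-face angiogram as a 32-bit float TIFF."""
    tifffile.imwrite(path, angiogram.image.astype(np.float32))
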