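"""Synthetic OCT speckle phantom with known vascular and layer ground truth.

The phantom emulates the statistical structure that inter-frame OCT
angiography assumes, with every quantity of interest known exactly:

* fully developed speckle — each voxel's complex field is circular Gaussian,
  so its amplitude is Rayleigh distributed;
* temporal correlation — the J repeated frames at a position are generated by
  a per-voxel AR(1) mixing of the complex field, E_j = ρ·E_{j−1} + √(1−ρ²)·G_j
  with fresh circular-Gaussian G_j; static tissue uses ρ = static_correlation
  (default 0.99), vessel voxels use their own flow_correlation (0 = complete
  inter-frame decorrelation, as for fast flow over ΔT = 5 ms);
* a two-layer tissue (epithelium over dermis) below an undulating surface,
  with the dermal reflectivity step scaled by ``dej_contrast`` — 0 mimics the
  loss of layer contrast seen in sclerotic tissue, where the dermal–epidermal
  junction becomes optically indistinguishable;
* exponential depth attenuation measured from the local surface (optical depth
  in tissue, not absolute z), so surface undulation is physically consistent;
* an additive Rayleigh noise floor, independent between frames, which
  decorrelates signal-free voxels — the failure mode the intensity mask in the
  angiography stage exists to suppress.

Geometry convention: z index increases with depth; x is the fast axis within
a B-scan; y the slow axis; all indices 0-based; ranges half-open.  The slow
axis uses the same pixel pitch as the fast axis, so en-face images are
isotropic.  A voxel belongs to a vessel iff its centre lies within the tube
radius of the centreline (no anti-aliasing — ground-truth counting stays
exact).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy.spatial import cKDTree

from .angiography import OctFrameSeries, ScanMeta

__all__ = [
    "PhantomSpecError",
    "SurfaceProfile",
    "VesselSpec",
    "PhantomSpec",
    "GroundTruth",
    "straight_vessel",
    "generate_speckle_frames",
    "ground_truth",
    "write_phantom_hdf5",
    "read_ground_truth_hdf5",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates an invariant; the message
    names the offending field."""


@dataclass(frozen=True)
class SurfaceProfile:
    """Sinusoidal surface topography: depth(x, y) = base + amplitude ·
    sin(2π·x_um/period) · cos(2π·y_um/period).  Units µm."""

    base_depth_um: float = 160.0
    amplitude_um: float = 40.0
    period_um: float = 2000.0


@dataclass(frozen=True)
class VesselSpec:
    """A tubular vessel along a parametric 3-D path.

    ``centerline`` is an (N, 3) array of (x, y, z) voxel coordinates (floats;
    linearly interpolated between points).  ``flow_correlation`` is the
    inter-frame complex-field correlation inside the vessel; 0 means complete
    decorrelation between repeats.
    """

    centerline: np.ndarray
    radius_um: float
    flow_correlation: float = 0.0


def straight_vessel(start, end, radius_um: float,
                    flow_correlation: float = 0.0) -> VesselSpec:
    """Convenience constructor for a straight tube between two (x, y, z)
    voxel-coordinate endpoints."""
    return VesselSpec(
        centerline=np.array([start, end], dtype=float),
        radius_um=radius_um,
        flow_correlation=flow_correlation,
    )


@dataclass
class PhantomSpec:
    """Complete description of a synthetic OCT acquisition.

    Defaults reflect the emulated protocol: a 5 mm fast-axis field of view at
    128 A-lines (39.06 µm pitch, matching a 40 µm lateral resolution), J = 6
    repeated B-scans per position at ΔT = 5 ms, and a grid small enough that
    a full phantom builds in seconds.
    """

    n_lateral: int = 128
    n_depth: int = 256
    n_positions: int = 64
    frames_per_position: int = 6
    dt: float = 0.005
    lateral_spacing_um: float = 5000.0 / 128.0
    axial_spacing_um: float = 4.0
    surface_profile: SurfaceProfile = field(default_factory=SurfaceProfile)
    epithelium_thickness_um: float = 250.0
    epithelium_reflectivity: float = 0.5
    dermis_reflectivity: float = 1.0
    attenuation_per_um: float = 0.002
    dej_contrast: float = 1.0
    vessels: list[VesselSpec] = field(default_factory=list)
    noise_floor: float = 0.02
    static_correlation: float = 0.99
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.frames_per_position < 2:
            raise PhantomSpecError("frames_per_position must be >= 2")
        for name in ("n_lateral", "n_depth", "n_positions"):
            if getattr(self, name) < 1:
                raise PhantomSpecError(f"{name} must be >= 1")
        for name in ("lateral_spacing_um", "axial_spacing_um", "dt"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be > 0")
        if not 0.0 <= self.dej_contrast <= 1.0:
            raise PhantomSpecError("dej_contrast must be in [0, 1]")
        if not 0.0 <= self.static_correlation <= 1.0:
            raise PhantomSpecError("static_correlation must be in [0, 1]")
        if self.epithelium_thickness_um <= 0:
            raise PhantomSpecError("epithelium_thickness_um must be > 0")
        if self.noise_floor < 0:
            raise PhantomSpecError("noise_floor must be >= 0")
        if self.attenuation_per_um < 0:
            raise PhantomSpecError("attenuation_per_um must be >= 0")
        for i, v in enumerate(self.vessels):
            if v.radius_um <= 0:
                raise PhantomSpecError(f"vessels[{i}].radius_um must be > 0")
            if not 0.0 <= v.flow_correlation <= 1.0:
                raise PhantomSpecError(
                    f"vessels[{i}].flow_correlation must be in [0, 1]")
            if v.flow_correlation > self.static_correlation:
                raise PhantomSpecError(
                    f"vessels[{i}].flow_correlation must not exceed "
                    "static_correlation")
            cl = np.asarray(v.centerline, dtype=float)
            if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
                raise PhantomSpecError(
                    f"vessels[{i}].centerline must be an (N>=2, 3) array")

    # -- YAML schema --------------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["surface_profile"] = dataclasses.asdict(self.surface_profile)
        d["vessels"] = [
            {
                "centerline": np.asarray(v.centerline, float).tolist(),
                "radius_um": float(v.radius_um),
                "flow_correlation": float(v.flow_correlation),
            }
            for v in self.vessels
        ]
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "surface_profile" in d and isinstance(d["surface_profile"], dict):
            d["surface_profile"] = SurfaceProfile(**d["surface_profile"])
        vessels = []
        for i, v in enumerate(d.get("vessels") or []):
            v = dict(v)
            if "line" in v:  # shorthand: {line: {start: [...], end: [...]}, ...}
                line = v.pop("line")
                v["centerline"] = [line["start"], line["end"]]
            if "centerline" not in v:
                raise PhantomSpecError(
                    f"vessels[{i}] needs a 'centerline' or 'line' entry")
            vessels.append(VesselSpec(
                centerline=np.asarray(v["centerline"], dtype=float),
                radius_um=float(v["radius_um"]),
                flow_correlation=float(v.get("flow_correlation", 0.0)),
            ))
        d["vessels"] = vessels
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PhantomSpecError(f"unknown PhantomSpec fields: {sorted(unknown)}")
        spec = cls(**d)
        spec.validate()
        return spec

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


@dataclass
class GroundTruth:
    """Exact geometry the generator used, for validating the analysis chain.

    ``surface_z`` / ``dej_z`` are float pixel-depth maps of shape (y, x);
    ``vessel_mask`` is a boolean (y, x, z) volume; ``true_density_pct`` is the
    exact en-face footprint fraction of ``vessel_mask`` in percent;
    ``true_diameters_um`` lists 2 × radius per vessel; ``true_thickness_um``
    is the per-(y, x) epithelial thickness map.
    """

    vessel_mask: np.ndarray
    surface_z: np.ndarray
    dej_z: np.ndarray
    true_density_pct: float
    true_diameters_um: np.ndarray
    true_thickness_um: np.ndarray


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _surface_z_map(spec: PhantomSpec) -> np.ndarray:
    """Float surface depth map in pixels, shape (y, x)."""
    p = spec.surface_profile
    x_um = np.arange(spec.n_lateral) * spec.lateral_spacing_um
    y_um = np.arange(spec.n_positions) * spec.lateral_spacing_um
    und = (p.amplitude_um
           * np.sin(2 * np.pi * x_um[None, :] / p.period_um)
           * np.cos(2 * np.pi * y_um[:, None] / p.period_um))
    return (p.base_depth_um + und) / spec.axial_spacing_um


def _densify_centerline(cl: np.ndarray, step_um: float, scale: np.ndarray) -> np.ndarray:
    """Resample a polyline (voxel coords, scaled to µm by ``scale``) at
    ~``step_um`` spacing; returns points in µm."""
    pts_um = np.asarray(cl, float) * scale[None, :]
    out = [pts_um[0]]
    for a, b in zip(pts_um[:-1], pts_um[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step_um)), 1)
        t = np.linspace(0, 1, n + 1)[1:]
        out.append(a[None, :] + t[:, None] * (b - a)[None, :])
    return np.vstack([np.atleast_2d(p) for p in out])


def _vessel_mask_and_rho(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean vessel mask (y, x, z) and per-voxel AR(1) correlation map."""
    ny, nx, nz = spec.n_positions, spec.n_lateral, spec.n_depth
    mask = np.zeros((ny, nx, nz), dtype=bool)
    rho = np.full((ny, nx, nz), spec.static_correlation, dtype=np.float32)
    scale = np.array([spec.lateral_spacing_um, spec.lateral_spacing_um,
                      spec.axial_spacing_um])
    for v in spec.vessels:
        step = 0.4 * min(spec.lateral_spacing_um, spec.axial_spacing_um)
        pts = _densify_centerline(v.centerline, step, scale)
        tree = cKDTree(pts)
        # bounding box in voxel indices, padded by the radius
        lo_um = pts.min(axis=0) - v.radius_um
        hi_um = pts.max(axis=0) + v.radius_um
        lo = np.maximum(np.floor(lo_um / scale).astype(int), 0)
        hi = np.minimum(np.ceil(hi_um / scale).astype(int) + 1, [nx, ny, nz])
        if np.any(lo >= hi):
            continue
        xs = np.arange(lo[0], hi[0])
        ys = np.arange(lo[1], hi[1])
        zs = np.arange(lo[2], hi[2])
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        centers = np.column_stack([gx.ravel() * scale[0],
                                   gy.ravel() * scale[1],
                                   gz.ravel() * scale[2]])
        dist, _ = tree.query(centers, k=1)
        inside = (dist <= v.radius_um).reshape(gx.shape)
        ix, iy, iz = np.nonzero(inside)
        mask[ys[iy], xs[ix], zs[iz]] = True
        rho[ys[iy], xs[ix], zs[iz]] = v.flow_correlation
    return mask, rho


def _reflectivity_and_attenuation(spec: PhantomSpec,
                                  surface_z: np.ndarray) -> np.ndarray:
    """Static envelope (reflectivity × attenuation), shape (y, x, z)."""
    z_px = np.arange(spec.n_depth, dtype=np.float64)
    depth_px = z_px[None, None, :] - surface_z[:, :, None]
    depth_um = depth_px * spec.axial_spacing_um
    in_tissue = depth_px >= 0
    dermis_eff = (spec.epithelium_reflectivity
                  + spec.dej_contrast * (spec.dermis_reflectivity
                                         - spec.epithelium_reflectivity))
    refl = np.where(depth_um < spec.epithelium_thickness_um,
                    spec.epithelium_reflectivity, dermis_eff)
    refl = np.where(in_tissue, refl, 0.0)
    att = np.exp(-spec.attenuation_per_um * np.clip(depth_um, 0.0, None))
    return (refl * att).astype(np.float32)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _complex_speckle(rng: np.random.Generator, shape) -> np.ndarray:
    """Unit-power circular-Gaussian complex field (|E| is Rayleigh(1/√2))."""
    re = rng.standard_normal(shape, dtype=np.float32)
    im = rng.standard_normal(shape, dtype=np.float32)
    return ((re + 1j * im) / np.sqrt(2.0)).astype(np.complex64)


def generate_speckle_frames(spec: PhantomSpec) -> OctFrameSeries:
    """Generate the repeated-B-scan series the spec describes.

    Per voxel: amplitude = |AR(1)-correlated circular-Gaussian speckle|
    × local reflectivity × exp(−attenuation × optical depth below surface)
    + noise_floor × |fresh speckle|.  Fully reproducible for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ny, nx, nz, J = (spec.n_positions, spec.n_lateral, spec.n_depth,
                     spec.frames_per_position)
    surface_z = _surface_z_map(spec)
    envelope = _reflectivity_and_attenuation(spec, surface_z)
    _, rho = _vessel_mask_and_rho(spec)
    mix = np.sqrt(1.0 - rho.astype(np.float64) ** 2).astype(np.float32)

    frames = np.empty((ny, J, nx, nz), dtype=np.float32)
    E = _complex_speckle(rng, (ny, nx, nz))
    for j in range(J):
        if j > 0:
            E = rho * E + mix * _complex_speckle(rng, (ny, nx, nz))
        amp = np.abs(E) * envelope
        if spec.noise_floor > 0:
            amp = amp + spec.noise_floor * np.abs(_complex_speckle(rng, (ny, nx, nz)))
        frames[:, j] = amp

    meta = ScanMeta(n_repeats=J, dt=spec.dt,
                    lateral_spacing_um=spec.lateral_spacing_um,
                    axial_spacing_um=spec.axial_spacing_um)
    return OctFrameSeries(amplitude=frames, meta=meta)


def ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Exact masks, boundaries and summary values for the spec's geometry.

    ``true_density_pct`` is obtained by exact voxel counting of the en-face
    footprint of the vessel mask over the full field of view.
    """
    spec.validate()
    surface_z = _surface_z_map(spec)
    dej_z = surface_z + spec.epithelium_thickness_um / spec.axial_spacing_um
    vessel_mask, _ = _vessel_mask_and_rho(spec)
    footprint = vessel_mask.any(axis=2)
    density = 100.0 * footprint.mean() if footprint.size else 0.0
    thickness = (dej_z - surface_z) * spec.axial_spacing_um
    return GroundTruth(
        vessel_mask=vessel_mask,
        surface_z=surface_z,
        dej_z=dej_z,
        true_density_pct=float(density),
        true_diameters_um=np.array([2.0 * v.radius_um for v in spec.vessels]),
        true_thickness_um=thickness,
    )


# ---------------------------------------------------------------------------
# HDF5 interchange
# ---------------------------------------------------------------------------

def write_phantom_hdf5(path: str | Path, series: OctFrameSeries,
                       truth: GroundTruth | None = None,
                       seed: int | None = None) -> None:
    """Single-file phantom layout: ``/frames`` (y, j, x, z float32), optional
    ``/ground_truth/*`` datasets, scan metadata as root attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=series.amplitude.astype(np.float32),
                         compression="gzip")
        f.attrs["J"] = series.meta.n_repeats
        f.attrs["dt"] = series.meta.dt
        f.attrs["lateral_spacing_um"] = series.meta.lateral_spacing_um
        f.attrs["axial_spacing_um"] = series.meta.axial_spacing_um
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("vessel_mask", data=truth.vessel_mask,
                             compression="gzip")
            g.create_dataset("surface_z", data=truth.surface_z)
            g.create_dataset("dej_z", data=truth.dej_z)
            g.attrs["true_density_pct"] = truth.true_density_pct
            g.create_dataset("true_diameters_um", data=truth.true_diameters_um)
            g.create_dataset("true_thickness_um", data=truth.true_thickness_um)


def read_ground_truth_hdf5(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        g = f["ground_truth"]
        return GroundTruth(
            vessel_mask=g["vessel_mask"][()].astype(bool),
            surface_z=g["surface_z"][()],
            dej_z=g["dej_z"][()],
            true_density_pct=float(g.attrs["true_density_pct"]),
            true_diameters_um=g["true_diameters_um"][()],
            true_thickness_um=g["true_thickness_um"][()],
        )
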