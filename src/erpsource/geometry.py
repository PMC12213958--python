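"""Head geometry, electrode montages, source grids and ROI masks.

Coordinate convention throughout the package: right-handed RAS head frame
(x to the right, y anterior, z superior), units in meters, origin at the
center of the concentric shells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeadGeometry",
    "Montage",
    "SourceSpace",
    "RoiMaskSet",
    "make_head",
    "make_montage",
    "make_source_space",
    "make_roi_masks",
    "DEFAULT_RADII",
    "DEFAULT_CONDUCTIVITIES",
]

# 4-shell surrogate for a layered head: brain, CSF, skull, scalp.
# Conductivities are standard literature values in S/m.
DEFAULT_RADII = (0.08, 0.085, 0.09, 0.1)
DEFAULT_CONDUCTIVITIES = (0.33, 1.79, 0.01, 0.43)

# Unit directions of anatomical landmarks on the scalp surface.  The nine
# classical landmarks used for electrode/MRI co-registration; AC/PC are deep
# midline structures but are placed on the outer shell here because only
# their role as registration targets matters.
_FIDUCIAL_DIRECTIONS = {
    "nasion": (0.0, 1.0, 0.0),
    "inion": (0.0, -1.0, 0.0),
    "lpa": (-1.0, 0.0, 0.0),
    "rpa": (1.0, 0.0, 0.0),
    "vertex": (0.0, 0.0, 1.0),
    "left_mastoid": (-0.9396926, -0.2620026, -0.2198463),
    "right_mastoid": (0.9396926, -0.2620026, -0.2198463),
    "ac": (0.0, 0.2588190, 0.9659258),
    "pc": (0.0, -0.2588190, 0.9659258),
}

# BioSemi-style 64-channel 10-10 label set, used for the default montage.
_LABELS_64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]


@dataclass(frozen=True)
class HeadGeometry:
    """Concentric-shell conductor model plus scalp landmarks.

    Parameters
    ----------
    shell_radii : ndarray
        Shell outer radii in meters, strictly increasing, innermost first.
    shell_conductivities : ndarray
        Conductivity of each shell in S/m (same order as ``shell_radii``).
    fiducials : dict
        Landmark name -> 3-vector position in head coordinates (meters).
    """

    shell_radii: np.ndarray
    shell_conductivities: np.ndarray
    fiducials: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def inner_radius(self) -> float:
        return float(self.shell_radii[0])

    @property
    def outer_radius(self) -> float:
        return float(self.shell_radii[-1])

    @property
    def n_shells(self) -> int:
        return len(self.shell_radii)


@dataclass(frozen=True)
class Montage:
    """Electrode labels, positions and the 3x3 scalp-cluster assignment.

    ``coronal`` holds one of {"frontal", "central", "posterior"} and
    ``sagittal`` one of {"left", "middle", "right"} per electrode.
    """

    labels: list[str]
    positions: np.ndarray  # (n_electrodes, 3) meters
    coronal: list[str]
    sagittal: list[str]

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def cluster_channels(self) -> dict[tuple[str, str], np.ndarray]:
        """Channel indices for each (coronal, sagittal) cell."""
        out: dict[tuple[str, str], list[int]] = {}
        for i, (c, s) in enumerate(zip(self.coronal, self.sagittal)):
            out.setdefault((c, s), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}


@dataclass(frozen=True)
class SourceSpace:
    """Regular dipole grid restricted to a spherical grey-matter band."""

    positions: np.ndarray  # (M, 3) meters
    spacing: float
    hemisphere: np.ndarray  # (M,) of {"left", "right", "midline"}

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class RoiMask:
    name: str
    indices: np.ndarray
    hemisphere: str  # "left" | "right" | "bilateral"
    family: str  # "MTL_atlas" | "fMRI_constrained"


@dataclass(frozen=True)
class RoiMaskSet:
    masks: dict[str, RoiMask]

    def family(self, family: str) -> list[RoiMask]:
        return [m for m in self.masks.values() if m.family == family]

    def __getitem__(self, name: str) -> RoiMask:
        return self.masks[name]

    def __iter__(self):
        return iter(self.masks.values())

    def __len__(self) -> int:
        return len(self.masks)


def make_head(
    radii=DEFAULT_RADII,
    conductivities=DEFAULT_CONDUCTIVITIES,
    fiducial_spec: dict[str, tuple[float, float, float]] | None = None,
) -> HeadGeometry:
    """Build a validated concentric-shell head model.

    ``fiducial_spec`` maps landmark names to unit directions; landmarks are
    placed deterministically on the outer shell.  Defaults to the nine
    classical co-registration landmarks.
    """
    radii = np.asarray(radii, dtype=float)
    cond = np.asarray(conductivities, dtype=float)
    if radii.ndim != 1 or radii.size < 1:
        raise ValueError("at least one shell is required")
    if radii.size != cond.size:
        raise ValueError("radii and conductivities must have the same length")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("shell radii must be strictly increasing")
    for k, c in enumerate(cond):
        if c <= 0:
            raise ValueError(f"shell {k} has non-positive conductivity {c}")
    spec = _FIDUCIAL_DIRECTIONS if fiducial_spec is None else fiducial_spec
    if len(set(spec)) != len(spec):
        raise ValueError("fiducial names must be unique")
    r_out = radii[-1]
    fiducials = {}
    for name, d in spec.items():
        d = np.asarray(d, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError(f"fiducial {name!r} has zero direction")
        fiducials[name] = d / n * r_out
    return HeadGeometry(radii, cond, fiducials)


def _fibonacci_cap(n: int, max_polar_deg: float) -> np.ndarray:
    """n quasi-uniform unit vectors on the spherical cap from the vertex
    (+z) down to the given polar angle (deterministic spiral)."""
    z_min = np.cos(np.deg2rad(max_polar_deg))
    i = np.arange(n)
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_montage(
    head: HeadGeometry, n_electrodes: int = 64, max_polar_deg: float = 115.0
) -> Montage:
    """Place electrodes quasi-uniformly on the upper outer shell.

    Uses a deterministic spherical (Fibonacci) spiral over the cap covering
    polar angles up to ``max_polar_deg``.  The default 64 channels carry a
    10-10-style label set; other counts are labelled ``E001``...  Every
    electrode is assigned to one cell of the 3 (coronal) x 3 (sagittal)
    scalp-cluster scheme by position terciles.
    """
    if n_electrodes < 4:
        raise ValueError("at least 4 electrodes are required")
    unit = _fibonacci_cap(n_electrodes, max_polar_deg)
    pos = unit * head.outer_radius
    if n_electrodes == 64:
        labels = list(_LABELS_64)
    else:
        labels = [f"E{i + 1:03d}" for i in range(n_electrodes)]
    # Tercile cuts on anterior (y) and lateral (x) coordinates give the
    # frontal/central/posterior x left/middle/right partition.
    y_lo, y_hi = np.quantile(pos[:, 1], [1 / 3, 2 / 3])
    x_lo, x_hi = np.quantile(pos[:, 0], [1 / 3, 2 / 3])
    coronal = [
        "frontal" if y > y_hi else ("posterior" if y <= y_lo else "central")
        for y in pos[:, 1]
    ]
    sagittal = [
        "right" if x > x_hi else ("left" if x <= x_lo else "middle")
        for x in pos[:, 0]
    ]
    return Montage(labels, pos, coronal, sagittal)


def make_source_space(
    head: HeadGeometry,
    spacing: float = 0.01,
    band: tuple[float, float] = (0.6, 0.95),
) -> SourceSpace:
    """Cubic dipole lattice clipped to a grey-matter shell band.

    The band is expressed as fractions of the innermost shell radius; the
    default [0.6, 0.95] keeps a cortex-like shell and excludes deep
    (subcortical) positions.  Hemisphere labels use the lateral (x)
    coordinate with a midline band of half a grid step.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo, hi = band
    if not (0 < lo < hi <= 1):
        raise ValueError("band fractions must satisfy 0 < lo < hi <= 1")
    r = head.inner_radius
    n_steps = int(np.floor(hi * r / spacing))
    axis = np.arange(-n_steps, n_steps + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    norm = np.linalg.norm(pts, axis=1)
    keep = (norm >= lo * r) & (norm <= hi * r)
    pts = pts[keep]
    if pts.shape[0] == 0:
        raise ValueError("empty source space (spacing too large for head)")
    hemi = np.where(
        pts[:, 0] < -spacing / 2,
        "left",
        np.where(pts[:, 0] > spacing / 2, "right", "midline"),
    )
    return SourceSpace(pts, float(spacing), hemi)


# Seed directions (unit-ish vectors in RAS) for synthetic ROI patches.  The
# medial-temporal family sits in the inferior-medial band of the grid; the
# fMRI-constrained family mimics the cortical regions carrying a BOLD
# subsequent-memory effect (parietal, occipital, temporal, frontal).
_MTL_SEEDS = {
    "rostral PhG": (0.45, 0.35, -0.82),
    "caudal PhG": (0.45, -0.05, -0.89),
    "lateral PPHC": (0.62, -0.25, -0.74),
    "EC": (0.50, 0.50, -0.70),
    "TI": (0.65, 0.30, -0.70),
    "medial PPHC": (0.30, -0.30, -0.90),
}
_FMRI_SEEDS = {
    "left IPL/SPL": ((-0.55, -0.45, 0.70), "left"),
    "IOG": ((-0.15, -0.95, -0.25), "bilateral"),
    "left ITG": ((-0.80, 0.10, -0.55), "left"),
    "left IFG": ((-0.75, 0.60, 0.15), "left"),
    "FuG": ((-0.45, -0.55, -0.70), "bilateral"),
    "OFG": ((0.0, 0.85, -0.50), "bilateral"),
}

MTL_ROI_NAMES = tuple(_MTL_SEEDS)
FMRI_ROI_NAMES = tuple(_FMRI_SEEDS)


def _grow_patch(
    positions: np.ndarray, seed_point: np.ndarray, size: int, claimed: np.ndarray
) -> np.ndarray:
    """Greedy nearest-neighbor accretion of unclaimed grid points around a
    seed location; deterministic (distance then index tie-break)."""
    free = np.flatnonzero(~claimed)
    if free.size < size:
        raise ValueError(
            f"requested patch size {size} exceeds {free.size} available grid points"
        )
    d = np.linalg.norm(positions[free] - seed_point, axis=1)
    order = np.lexsort((free, d))
    chosen = free[order[:size]]
    claimed[chosen] = True
    return np.sort(chosen)


def make_roi_masks(
    source_space: SourceSpace,
    patch_size: int = 8,
    seed: int = 0,
    jitter: float = 0.0,
) -> RoiMaskSet:
    """Build the two synthetic ROI mask families on a source grid.

    The medial-temporal family contains six bilateral region names (12
    patches); the fMRI-constrained family contains six group-mask regions.
    Patches are grown by nearest-neighbor accretion around anatomical seed
    directions; ``jitter`` (meters, default 0) perturbs seed locations
    reproducibly from ``seed``.
    """
    if source_space.n_sources == 0:
        raise ValueError("source space is empty")
    rng = np.random.default_rng(seed)
    pos = source_space.positions
    r_mean = float(np.mean(np.linalg.norm(pos, axis=1)))
    masks: dict[str, RoiMask] = {}

    claimed = np.zeros(source_space.n_sources, dtype=bool)
    for name, d in _MTL_SEEDS.items():
        d = np.asarray(d, dtype=float)
        d /= np.linalg.norm(d)
        for hemi, sign in (("left", -1.0), ("right", 1.0)):
            target = d * np.array([sign, 1.0, 1.0]) * r_mean
            target = target + rng.normal(0.0, jitter, 3)
            # keep the seed clearly inside the requested hemisphere
            lat_floor = source_space.spacing
            if hemi == "left":
                target[0] = min(target[0], -lat_floor)
            else:
                target[0] = max(target[0], lat_floor)
            hemi_ok = source_space.hemisphere == hemi
            blocked = claimed | ~hemi_ok
            idx = _grow_patch(pos, target, patch_size, blocked)
            claimed[idx] = True
            masks[f"{hemi} {name}"] = RoiMask(f"{hemi} {name}", idx, hemi, "MTL_atlas")

    claimed = np.zeros(source_space.n_sources, dtype=bool)
    for name, (d, hemi) in _FMRI_SEEDS.items():
        d = np.asarray(d, dtype=float)
        d /= np.linalg.norm(d)
        target = d * r_mean + rng.normal(0.0, jitter, 3)
        idx = _grow_patch(pos, target, patch_size, claimed)
        masks[name] = RoiMask(name, idx, hemi, "fMRI_constrained")

    return RoiMaskSet(masks)
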