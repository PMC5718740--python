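"""Voxelized balloon-in-tissue phantoms.

Synthetic stand-in for the CT'd breast phantom: a spherical applicator
balloon (4/5/6 cm diameter) filled with saline or contrast mixture, centred
in a tissue block with full-scatter margin, voxelized on the 0.15 cm dose
scoring grid.  Balloon deformation (hemispherical outward displacement,
cosine-tapered at the equator) and source offsets are represented
geometrically; the planning target volume (PTV) is the 1 cm tissue shell
around the (possibly deformed) balloon surface.

Coordinates are continuous cm with the origin at the nominal source
position (the balloon centre); the deformation axis is +z.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .materials import Material, material_from_text, material_to_text

__all__ = [
    "BalloonGeometry",
    "VoxelPhantom",
    "build_phantom",
    "ptv_mask",
    "prescription_point",
    "deform_balloon",
    "write_phantom",
    "read_phantom",
]

DEFAULT_VOXEL_CM = 0.15
PTV_THICKNESS_CM = 1.0
DEFORMATION_MODES = ("none", "hemispherical_outward")


@dataclass(frozen=True)
class BalloonGeometry:
    """Balloon diameter/filling plus deformation and source-offset state."""

    diameter_cm: float
    filling: Material
    center_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    deformation_mm: float = 0.0
    deformation_mode: str = "none"
    source_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.diameter_cm < 0:
            raise ValueError("diameter must be >= 0")
        if self.deformation_mm < 0:
            raise ValueError("deformation must be >= 0")
        if self.deformation_mode not in DEFORMATION_MODES:
            raise ValueError(f"unknown deformation mode {self.deformation_mode!r}")
        if self.deformation_mm > 0 and self.deformation_mode == "none":
            object.__setattr__(self, "deformation_mode", "hemispherical_outward")

    @property
    def radius_cm(self) -> float:
        return self.diameter_cm / 2.0

    def surface_radius_cm(self, cos_polar) -> np.ndarray:
        """Balloon surface radius as a function of the polar angle cosine.

        In ``hemispherical_outward`` mode the +z hemisphere is displaced
        outward by up to ``deformation_mm``, tapering smoothly to zero at
        the equator (displacement = d * max(cos theta, 0)).
        """
        mu = np.asarray(cos_polar, dtype=float)
        r = np.full_like(mu, self.radius_cm)
        if self.deformation_mode == "hemispherical_outward" and self.deformation_mm > 0:
            r = r + (self.deformation_mm / 10.0) * np.maximum(mu, 0.0)
        return r

    @property
    def source_position_cm(self) -> np.ndarray:
        return np.asarray(self.center_cm) + np.asarray(self.source_offset_mm) / 10.0


@dataclass
class VoxelPhantom:
    """3-D material-index grid with its material table.

    ``material_index[i,j,k]`` indexes ``material_table``; voxel (0,0,0) has
    its low corner at ``origin_cm`` and voxel centres at
    ``origin + (index + 0.5) * voxel_size``.
    """

    material_index: np.ndarray
    material_table: list[Material]
    voxel_size_cm: float = DEFAULT_VOXEL_CM
    origin_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.voxel_size_cm <= 0:
            raise ValueError("voxel size must be > 0")
        idx = np.asarray(self.material_index)
        if idx.ndim != 3:
            raise ValueError("material_index must be 3-D")
        if idx.min() < 0 or idx.max() >= len(self.material_table):
            raise ValueError("material index out of range")
        self.material_index = np.ascontiguousarray(idx, dtype=np.int8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_index.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin_cm)
        axes = [
            o[d] + (np.arange(self.shape[d]) + 0.5) * self.voxel_size_cm
            for d in range(3)
        ]
        return tuple(axes)

    def radius_grid(self, center=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Distance of each voxel centre from ``center`` (cm)."""
        x, y, z = self.voxel_centers()
        c = np.asarray(center)
        return np.sqrt(
            (x[:, None, None] - c[0]) ** 2
            + (y[None, :, None] - c[1]) ** 2
            + (z[None, None, :] - c[2]) ** 2
        )

    def cos_polar_grid(self, center=(0.0, 0.0, 0.0)) -> np.ndarray:
        x, y, z = self.voxel_centers()
        c = np.asarray(center)
        r = self.radius_grid(center)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = (z[None, None, :] - c[2]) / r
        return np.where(r == 0, 1.0, mu)


def build_phantom(
    balloon: BalloonGeometry,
    tissue: Material,
    half_extent_cm: float,
    voxel_size_cm: float = DEFAULT_VOXEL_CM,
) -> VoxelPhantom:
    """Voxelize a balloon centred in a cubic tissue block.

    ``half_extent_cm`` should leave >= 5 cm of tissue beyond the balloon for
    full-scatter conditions.  Voxel membership is decided by the voxel
    centre position (no partial-volume weighting).
    """
    max_r = balloon.radius_cm + balloon.deformation_mm / 10.0
    if max_r > half_extent_cm:
        raise ValueError("balloon larger than phantom")
    n = int(round(2.0 * half_extent_cm / voxel_size_cm))
    origin = (-n * voxel_size_cm / 2.0,) * 3
    phantom = VoxelPhantom(
        material_index=np.zeros((n, n, n), dtype=np.int8),
        material_table=[tissue, balloon.filling],
        voxel_size_cm=voxel_size_cm,
        origin_cm=origin,
    )
    if balloon.diameter_cm > 0:
        r = phantom.radius_grid(balloon.center_cm)
        mu = phantom.cos_polar_grid(balloon.center_cm)
        inside = r <= balloon.surface_radius_cm(mu)
        phantom.material_index[inside] = 1
    return phantom


def ptv_mask(phantom: VoxelPhantom, balloon: BalloonGeometry) -> np.ndarray:
    """Boolean mask of the PTV: tissue shell extending 1 cm from the
    (deformed) balloon surface, excluding the balloon itself."""
    r = phantom.radius_grid(balloon.center_cm)
    mu = phantom.cos_polar_grid(balloon.center_cm)
    surf = balloon.surface_radius_cm(mu)
    return (r > surf) & (r <= surf + PTV_THICKNESS_CM)


def prescription_point(balloon: BalloonGeometry) -> np.ndarray:
    """Prescription point: 1 cm from the nominal balloon surface, on the +x
    axis (perpendicular to the deformation axis)."""
    return np.asarray(balloon.center_cm) + np.array(
        [balloon.radius_cm + PTV_THICKNESS_CM, 0.0, 0.0]
    )


def deform_balloon(balloon: BalloonGeometry, d_mm: float) -> BalloonGeometry:
    """Return the balloon with a hemispherical outward deformation of d_mm."""
    if d_mm < 0:
        raise ValueError("deformation must be >= 0")
    mode = "none" if d_mm == 0 else "hemispherical_outward"
    return dataclasses.replace(balloon, deformation_mm=d_mm, deformation_mode=mode)


# -- grid I/O: binary grid + plain-text header --------------------------------

def write_phantom(phantom: VoxelPhantom, path_stem: str) -> None:
    """Write ``<stem>.hdr`` (text) and ``<stem>.bin`` (int8 grid, C order)."""
    nx, ny, nz = phantom.shape
    with open(path_stem + ".hdr", "w") as fh:
        fh.write(f"shape {nx} {ny} {nz}\n")
        fh.write(f"voxel_size_cm {phantom.voxel_size_cm!r}\n")
        fh.write("origin_cm " + " ".join(repr(v) for v in phantom.origin_cm) + "\n")
        fh.write(f"n_materials {len(phantom.material_table)}\n")
        for mat in phantom.material_table:
            fh.write("--\n")
            fh.write(material_to_text(mat))
    phantom.material_index.tofile(path_stem + ".bin")


def read_phantom(path_stem: str) -> VoxelPhantom:
    with open(path_stem + ".hdr") as fh:
        text = fh.read()
    head, *mat_blocks = text.split("--\n")
    meta = {}
    for line in head.splitlines():
        key, *vals = line.split()
        meta[key] = vals
    shape = tuple(int(v) for v in meta["shape"])
    idx = np.fromfile(path_stem + ".bin", dtype=np.int8).reshape(shape)
    return VoxelPhantom(
        material_index=idx,
        material_table=[material_from_text(b) for b in mat_blocks],
        voxel_size_cm=float(meta["voxel_size_cm"][0]),
        origin_cm=tuple(float(v) for v in meta["origin_cm"]),
    )
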