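"""Dual-probe grid detection of internal cavities.

A cavity is a void a small probe (water-sized, 1.4 A) can occupy but a
large probe (4.0 A) rolled from the outside cannot reach.  The grid
algorithm: voxels within (vdW + small probe) of any atom are protein;
the bulk solvent is the set of voxels swept by large-probe spheres whose
centres flood in from the box boundary; everything else is cavity.
Volumes are voxel counts times spacing cubed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .structio import Structure

__all__ = [
    "CavityResult",
    "CavityComponent",
    "detect_cavities",
    "cavity_volume_for_design",
    "VDW_RADII",
    "RESIDUE_COARSE_RADII",
]

# per-element van der Waals radii, A
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "SE": 1.90, "P": 1.80}
DEFAULT_VDW = 1.70

# Coarse one-sphere-per-residue radii for C-alpha-only design models:
# r = (3 V / 4 pi)^(1/3) from standard amino-acid volumes (A^3).
_RESIDUE_VOLUMES = {
    "G": 60.1, "A": 88.6, "S": 89.0, "C": 108.5, "D": 111.1, "P": 112.7,
    "N": 114.1, "T": 116.1, "E": 138.4, "V": 140.0, "Q": 143.8, "H": 153.2,
    "M": 162.9, "I": 166.7, "L": 166.7, "K": 168.6, "R": 173.4, "F": 189.9,
    "Y": 193.6, "W": 227.8,
}
RESIDUE_COARSE_RADII = {
    aa: float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)) for aa, v in _RESIDUE_VOLUMES.items()
}


@dataclasses.dataclass
class CavityComponent:
    voxel_count: int
    volume: float  # A^3
    centroid: np.ndarray  # A


@dataclasses.dataclass
class CavityResult:
    components: list[CavityComponent]
    spacing: float
    small_probe: float
    large_probe: float
    grid_shape: tuple[int, int, int]

    @property
    def total_volume(self) -> float:
        return sum(c.volume for c in self.components)

    @property
    def n_cavities(self) -> int:
        return len(self.components)

    def largest(self) -> CavityComponent | None:
        if not self.components:
            return None
        return max(self.components, key=lambda c: c.volume)


def _gather_atoms(structure, include_ligands: bool, include_waters: bool):
    coords, radii = [], []
    for atom in structure.atoms():
        resname = atom.resname
        is_water = resname in {"HOH", "WAT", "DOD"}
        if is_water and not include_waters:
            continue
        if atom.het and not is_water and not include_ligands:
            continue
        coords.append(atom.position)
        radii.append(VDW_RADII.get(atom.element.upper(), DEFAULT_VDW))
    return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


def _mark_spheres(mask: np.ndarray, origin: np.ndarray, spacing: float,
                  coords: np.ndarray, radii: np.ndarray) -> None:
    """Set True every voxel whose centre lies within radius of an atom."""
    shape = np.array(mask.shape)
    for xyz, r in zip(coords, radii):
        lo = np.maximum(np.floor((xyz - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((xyz + r - origin) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [origin[d] + spacing * np.arange(lo[d], hi[d]) - xyz[d] for d in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r


def _detect(coords: np.ndarray, radii: np.ndarray, small_probe: float,
            large_probe: float, spacing: float, min_volume: float) -> CavityResult:
    if spacing <= 0 or small_probe <= 0 or large_probe <= 0:
        raise ValueError("spacing and probe radii must be positive")
    if len(coords) == 0:
        raise ValueError("no atoms to analyse")
    margin = 2.0 * large_probe + radii.max() + spacing
    origin = coords.min(axis=0) - margin
    top = coords.max(axis=0) + margin
    shape = tuple(np.ceil((top - origin) / spacing).astype(int) + 1)

    protein = np.zeros(shape, dtype=bool)
    _mark_spheres(protein, origin, spacing, coords, radii + small_probe)
    large_blocked = np.zeros(shape, dtype=bool)
    _mark_spheres(large_blocked, origin, spacing, coords, radii + large_probe)

    # flood the large-probe-accessible region in from the box boundary
    free = ~large_blocked
    labels, _ = ndimage.label(free)  # 6-connectivity by default
    boundary_labels = np.unique(
        np.concatenate([
            labels[0].ravel(), labels[-1].ravel(),
            labels[:, 0].ravel(), labels[:, -1].ravel(),
            labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
        ])
    )
    outside = np.isin(labels, boundary_labels[boundary_labels != 0])
    # bulk = volume swept by large-probe spheres centred in the outside region
    dist_to_outside = ndimage.distance_transform_edt(~outside, sampling=spacing)
    bulk = dist_to_outside <= large_probe

    cavity = ~protein & ~bulk
    comp_labels, n_comp = ndimage.label(cavity)
    components: list[CavityComponent] = []
    voxel_volume = spacing**3
    for lab in range(1, n_comp + 1):
        idx = np.argwhere(comp_labels == lab)
        volume = len(idx) * voxel_volume
        if volume < min_volume:
            continue
        centroid = origin + spacing * idx.mean(axis=0)
        components.append(CavityComponent(voxel_count=len(idx), volume=volume, centroid=centroid))
    components.sort(key=lambda c: -c.volume)
    return CavityResult(components=components, spacing=spacing, small_probe=small_probe,
                        large_probe=large_probe, grid_shape=shape)


def detect_cavities(
    structure: Structure,
    small_probe: float = 1.4,
    large_probe: float = 4.0,
    spacing: float = 0.6,
    min_volume: float = 5.0,
    include_ligands: bool = False,
    include_waters: bool = False,
) -> CavityResult:
    """Internal cavities of an atomic structure (protein atoms by default)."""
    coords, radii = _gather_atoms(structure, include_ligands, include_waters)
    return _detect(coords, radii, small_probe, large_probe, spacing, min_volume)


def cavity_volume_for_design(
    backbone,
    sequence: str | None = None,
    small_probe: float = 1.4,
    large_probe: float = 4.0,
    spacing: float = 0.6,
    min_volume: float = 5.0,
) -> CavityResult:
    """Cavity detection on a coarse one-sphere-per-residue representation.

    ``backbone`` supplies C-alpha coordinates (``ca_coords()`` or array);
    each residue is a sphere at its C-alpha with the residue-type coarse
    radius (sequence defaults to the backbone's own).
    """
    ca = backbone.ca_coords() if hasattr(backbone, "ca_coords") else np.asarray(backbone, dtype=float)
    if sequence is None:
        if hasattr(backbone, "sequence"):
            sequence = backbone.sequence()
        else:
            raise ValueError("sequence required for a bare coordinate array")
    if len(sequence) != len(ca):
        raise ValueError("sequence length must match backbone residues")
    radii = np.array([RESIDUE_COARSE_RADII[aa] for aa in sequence])
    return _detect(ca, radii, small_probe, large_probe, spacing, min_volume)


def cavity_voxels_to_structure(result_components, entry_id: str = "cavities"):
    """Pseudo-atom Structure of cavity centroids, for visual inspection."""
    from .structio import AtomRecord, Residue, Structure

    st = Structure(entry_id=entry_id)
    for i, comp in enumerate(result_components, start=1):
        res = Residue(resname="CAV", resseq=i, het=True)
        res.atoms.append(
            AtomRecord(serial=i, name="X", altloc="", resname="CAV", chain="Z",
                       resseq=i, icode="", position=comp.centroid, het=True, element="X")
        )
        st.add_residue("Z", res)
    return st
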