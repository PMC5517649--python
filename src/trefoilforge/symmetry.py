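"""C3 symmetrisation of beta-trefoil repeats.

A pseudo-threefold trefoil is turned into an exactly symmetric backbone
in four steps: extract the three repeats, fit the pseudo-C3 axis from
the repeat-to-repeat rotations, replicate one repeat at exact 120-degree
rotations about that axis (optionally refining the repeat placement by a
rigid-body grid search scored with the coarse interface objective), and
join the copies with linkers — either synthetic inserts or geometry
grafted from a donor trefoil.  A bonded-term regulariser cleans up the
junction geometry while re-imposing exact symmetry.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import ONE_TO_THREE, AtomRecord, Residue, Structure, ca_trace, extract_sequence
from .superpose import GeometryError, RigidTransform, kabsch, trimmed_superpose

__all__ = [
    "RepeatDefinition",
    "SymmetryAxis",
    "SymmetricBackbone",
    "NotThreefoldError",
    "PackingError",
    "GraftError",
    "extract_repeats",
    "fit_c3_axis",
    "symmetrize",
    "concatenate_with_linkers",
    "graft_linker",
    "regularize_backbone",
]

IDEAL_BONDS = {("N", "CA"): 1.458, ("CA", "C"): 1.525, ("C", "N"): 1.329, ("C", "O"): 1.231}
IDEAL_N_CA_C = np.deg2rad(111.2)


class NotThreefoldError(ValueError):
    pass


class PackingError(ValueError):
    pass


class GraftError(ValueError):
    pass


@dataclasses.dataclass
class RepeatDefinition:
    """Three equal-length residue ranges (chain, start, end), inclusive."""

    ranges: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if len(self.ranges) != 3:
            raise ValueError("exactly three repeat ranges required")
        lengths = {hi - lo + 1 for _, lo, hi in self.ranges}
        if len(lengths) != 1:
            raise ValueError(f"repeat ranges differ in length: {self.ranges}")
        (self.length,) = lengths
        if self.length < 20:
            raise ValueError(f"repeat length {self.length} < 20")
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for chain, lo, hi in self.ranges:
            by_chain.setdefault(chain, []).append((lo, hi))
        for chain, spans in by_chain.items():
            spans.sort()
            for (_lo1, hi1), (lo2, _hi2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError(f"repeat ranges overlap in chain {chain}")


@dataclasses.dataclass
class SymmetryAxis:
    direction: np.ndarray  # unit 3-vector
    point: np.ndarray  # any point on the axis, Angstrom
    angle_deg: float  # pre-projection mean rotation angle

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.point = np.asarray(self.point, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            self.direction = self.direction / norm
        if not 0.0 < self.angle_deg < 360.0:
            raise ValueError(f"rotation angle {self.angle_deg} outside (0, 360)")

    def rotation(self, angle_deg: float) -> RigidTransform:
        """Rigid rotation by angle_deg about this axis (through self.point)."""
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * self.direction).as_matrix()
        t = self.point - R @ self.point
        return RigidTransform(R, t)


@dataclasses.dataclass
class BackboneResidue:
    """One residue of a backbone model: a name, its atoms, and provenance."""

    aa: str  # one-letter
    atoms: dict[str, np.ndarray]
    provenance: str = "template"  # template | donor
    role: str = "repeat"  # repeat | linker

    def copy_transformed(self, transform: RigidTransform) -> "BackboneResidue":
        return BackboneResidue(
            aa=self.aa,
            atoms={k: transform.apply(v[None, :])[0] for k, v in self.atoms.items()},
            provenance=self.provenance,
            role=self.role,
        )

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


class SymmetricBackbone:
    """An exactly C_n-symmetric chain generated from one asymmetric unit.

    The asymmetric unit is one repeat plus (optionally) the linker that
    follows it; the full chain is n rotated copies with the final linker
    omitted (the chain is open, not cyclic)."""

    def __init__(
        self,
        repeat: list[BackboneResidue],
        axis: SymmetryAxis,
        order: int = 3,
        linker: list[BackboneResidue] | None = None,
    ) -> None:
        self.repeat = repeat
        self.axis = axis
        self.order = order
        self.linker = linker or []

    @property
    def unit(self) -> list[BackboneResidue]:
        return self.repeat + self.linker

    def unit_transform(self, k: int) -> RigidTransform:
        return self.axis.rotation(k * 360.0 / self.order)

    def residues(self) -> list[tuple[int, BackboneResidue]]:
        """Full chain as (unit index, residue), final linker omitted."""
        out: list[tuple[int, BackboneResidue]] = []
        for k in range(self.order):
            tr = self.unit_transform(k)
            for res in self.repeat:
                out.append((k, res.copy_transformed(tr)))
            if k < self.order - 1:
                for res in self.linker:
                    out.append((k, res.copy_transformed(tr)))
        return out

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for _, r in self.residues()])

    def sequence(self) -> str:
        return "".join(r.aa for _, r in self.residues())

    def repeat_ca_coords(self, k: int) -> np.ndarray:
        tr = self.unit_transform(k)
        return np.array([tr.apply(r.ca[None, :])[0] for r in self.repeat])

    def max_asymmetry(self) -> float:
        """Max RMSD between unit i and the rotated image of unit j (0 by
        construction; assayed for regression safety)."""
        worst = 0.0
        base = self.repeat_ca_coords(0)
        for k in range(1, self.order):
            rot = self.unit_transform(k).apply(base)
            worst = max(worst, float(np.sqrt(((rot - self.repeat_ca_coords(k)) ** 2).sum(axis=1).mean())))
        return worst

    def to_structure(self, chain: str = "A", entry_id: str = "symmetric_model") -> Structure:
        st = Structure(entry_id=entry_id)
        resseq = 0
        serial = 0
        for _, res in self.residues():
            resseq += 1
            resname = ONE_TO_THREE.get(res.aa, "GLY")
            residue = Residue(resname=resname, resseq=resseq)
            for name in ("N", "CA", "C", "O"):
                if name in res.atoms:
                    serial += 1
                    residue.atoms.append(
                        AtomRecord(
                            serial=serial, name=name, altloc="", resname=resname,
                            chain=chain, resseq=resseq, icode="",
                            position=res.atoms[name], element=name[0],
                        )
                    )
            st.add_residue(chain, residue)
        st.metadata["axis"] = self.axis
        return st


def extract_repeats(
    structure: Structure, repeat_def: RepeatDefinition
) -> list[tuple[np.ndarray, str]]:
    """The three repeats as (C-alpha coordinates, one-letter sequence),
    labelled A, B, C in sequence order."""
    out = []
    for chain, lo, hi in repeat_def.ranges:
        trace, missing = ca_trace(structure, chain, ranges=[(lo, hi)])
        if missing:
            raise GeometryError(f"repeat {chain}:{lo}-{hi} missing CA at {missing}")
        if len(trace) != hi - lo + 1:
            present = {r for r, _ in trace}
            gaps = [r for r in range(lo, hi + 1) if r not in present]
            raise GeometryError(f"repeat {chain}:{lo}-{hi} has residue gaps at {gaps}")
        seq = extract_sequence(structure, chain).residues
        first = structure.chain(chain)[0].resseq
        sub = "".join(
            seq[r - first] for r, _ in trace
        )
        out.append((np.array([p for _, p in trace]), sub))
    return out


def _axis_point(R: np.ndarray, t: np.ndarray) -> np.ndarray:
    # fixed line of x -> Rx + t; min-norm solution of (I - R) p = t
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t, rcond=None)
    return p


def fit_c3_axis(repeats: Sequence[np.ndarray]) -> SymmetryAxis:
    """Fit the pseudo-threefold axis from three superposable repeats.

    The A->B and B->C Kabsch rotations are averaged as quaternions (signs
    aligned); the axis is the mean rotation's axis, the reported angle is
    the pre-projection mean of the two rotation angles, and downstream
    symmetry operations use the exact 120-degree projection.
    """
    if len(repeats) != 3:
        raise ValueError("exactly three repeats required")
    A, B, C = (np.asarray(r, dtype=float) for r in repeats)
    sup_ab = kabsch(A, B)
    sup_bc = kabsch(B, C)
    rots = [sup_ab.transform, sup_bc.transform]
    quats = Rotation.from_matrix([tr.rotation for tr in rots]).as_quat()
    if np.dot(quats[0], quats[1]) < 0:
        quats[1] = -quats[1]
    q_mean = quats.mean(axis=0)
    q_mean /= np.linalg.norm(q_mean)
    r_mean = Rotation.from_quat(q_mean)
    angles = [np.rad2deg(np.linalg.norm(Rotation.from_matrix(tr.rotation).as_rotvec())) for tr in rots]
    mean_angle = float(np.mean(angles))
    if not 80.0 <= mean_angle <= 160.0:
        raise NotThreefoldError(f"mean repeat rotation {mean_angle:.1f} deg is not close to 120")
    rotvec = r_mean.as_rotvec()
    direction = rotvec / np.linalg.norm(rotvec)
    points = [_axis_point(tr.rotation, tr.translation) for tr in rots]
    point = np.mean(points, axis=0)
    return SymmetryAxis(direction=direction, point=point, angle_deg=mean_angle)


def interface_objective(ca_a: np.ndarray, ca_b: np.ndarray,
                        clash_radius: float = 4.0, contact_range: tuple[float, float] = (4.0, 8.0),
                        clash_weight: float = 10.0) -> float:
    """Coarse inter-unit packing objective: soft-sphere clash minus contact
    count.  Lower is better."""
    d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)
    clash = np.clip(clash_radius - d, 0.0, None)
    contacts = ((d >= contact_range[0]) & (d <= contact_range[1])).sum()
    return float(clash_weight * (clash**2).sum() - contacts)


def _residues_from_ca(coords: np.ndarray, sequence: str) -> list[BackboneResidue]:
    return [
        BackboneResidue(aa=aa, atoms={"CA": np.asarray(xyz, dtype=float)})
        for aa, xyz in zip(sequence, coords)
    ]


def symmetrize(
    repeat_template: list[BackboneResidue] | tuple[np.ndarray, str],
    axis: SymmetryAxis,
    n: int = 3,
    rigid_search: bool = False,
    spin_step_deg: float = 1.0,
    offset_range: float = 3.0,
    offset_step: float = 0.25,
    min_contact_distance: float = 2.5,
) -> SymmetricBackbone:
    """Replicate one repeat at exact 360/n-degree rotations about the axis.

    With ``rigid_search`` the template placement is refined on a grid of
    spin about the axis and axial/radial offsets, scored by the coarse
    interface objective between adjacent units; the best placement is kept.
    Raises :class:`PackingError` if adjacent units clash below
    ``min_contact_distance`` at the optimum.
    """
    if isinstance(repeat_template, tuple):
        coords, seq = repeat_template
        repeat = _residues_from_ca(coords, seq)
    else:
        repeat = [dataclasses.replace(r, atoms=dict(r.atoms)) for r in repeat_template]

    ca = np.array([r.ca for r in repeat])
    d = axis.direction
    if rigid_search:
        centroid = ca.mean(axis=0)
        radial = centroid - axis.point
        radial = radial - np.dot(radial, d) * d
        rnorm = np.linalg.norm(radial)
        radial_dir = radial / rnorm if rnorm > 1e-9 else np.zeros(3)
        rot120 = SymmetryAxis(d, axis.point, 120.0).rotation(360.0 / n)
        best = (np.inf, None)
        spins = np.arange(0.0, 360.0 / n, spin_step_deg)
        offsets = np.arange(-offset_range, offset_range + 1e-9, offset_step)
        for spin in spins:
            spin_tr = axis.rotation(spin)
            ca_spun = spin_tr.apply(ca)
            for ax_off in offsets:
                for rad_off in offsets:
                    shift = ax_off * d + rad_off * radial_dir
                    ca_try = ca_spun + shift
                    obj = interface_objective(ca_try, rot120.apply(ca_try))
                    if obj < best[0]:
                        best = (obj, (spin, ax_off, rad_off))
        _, (spin, ax_off, rad_off) = best
        placement = axis.rotation(spin)
        shift = ax_off * d + rad_off * radial_dir
        for r in repeat:
            r.atoms = {k: placement.apply(v[None, :])[0] + shift for k, v in r.atoms.items()}
        ca = np.array([r.ca for r in repeat])

    backbone = SymmetricBackbone(repeat=repeat, axis=SymmetryAxis(d, axis.point, axis.angle_deg), order=n)
    neighbour = backbone.unit_transform(1).apply(ca)
    dmin = np.linalg.norm(ca[:, None, :] - neighbour[None, :, :], axis=2).min()
    if dmin < min_contact_distance:
        raise PackingError(
            f"adjacent units clash: minimum inter-unit CA distance {dmin:.2f} A"
        )
    return backbone


@dataclasses.dataclass
class ConcatenationResult:
    sequence: str
    # global 1-based position -> (segment, copy index, local 1-based position)
    numbering: dict[int, tuple[str, int, int]]

    @property
    def length(self) -> int:
        return len(self.sequence)


def concatenate_with_linkers(repeat_seq: str, linker_seq: str, n: int = 3) -> ConcatenationResult:
    """Concatenate n copies of a repeat with a linker at each of the n-1
    junctions; the numbering map is a bijection onto 1..total length."""
    if len(repeat_seq) < 1:
        raise ValueError("repeat sequence must be non-empty")
    seq_parts: list[str] = []
    numbering: dict[int, tuple[str, int, int]] = {}
    pos = 0
    for k in range(n):
        for i, aa in enumerate(repeat_seq, start=1):
            pos += 1
            numbering[pos] = ("repeat", k, i)
        seq_parts.append(repeat_seq)
        if k < n - 1:
            for i, aa in enumerate(linker_seq, start=1):
                pos += 1
                numbering[pos] = ("linker", k, i)
            seq_parts.append(linker_seq)
    return ConcatenationResult(sequence="".join(seq_parts), numbering=numbering)


def graft_linker(
    backbone: SymmetricBackbone,
    donor_structure: Structure,
    donor_range: tuple[str, int, int],
    k: int,
    anchor_size: int = 3,
    anchor_rmsd_max: float = 1.5,
) -> SymmetricBackbone:
    """Replace the junction linker with k donor residues (k in {6, 9}).

    The donor segment (``donor_range``, length k) is positioned by Kabsch
    superposition of ``anchor_size`` anchor residues on either side of it
    onto the host junction anchors (the last/first residues of adjacent
    repeats).  The same graft is applied in all junctions by symmetry;
    provenance is recorded per residue.
    """
    if k not in (6, 9):
        raise ValueError(f"graft length k must be 6 or 9, got {k}")
    chain, lo, hi = donor_range
    if hi - lo + 1 != k:
        raise ValueError(f"donor range {lo}-{hi} does not span {k} residues")

    trace, missing = ca_trace(donor_structure, chain,
                              ranges=[(lo - anchor_size, hi + anchor_size)])
    if missing or len(trace) != k + 2 * anchor_size:
        raise GraftError(f"donor range {donor_range} incomplete (missing {missing})")
    donor_ca = np.array([p for _, p in trace])
    donor_seq_all = extract_sequence(donor_structure, chain).residues
    first = donor_structure.chain(chain)[0].resseq
    donor_seq = "".join(donor_seq_all[r - first] for r, _ in trace)

    # host anchors: C-terminal residues of unit 0's repeat, N-terminal of unit 1's
    host_pre = [r.ca for r in backbone.repeat[-anchor_size:]]
    tr1 = backbone.unit_transform(1)
    host_post = [tr1.apply(r.ca[None, :])[0] for r in backbone.repeat[:anchor_size]]
    host_anchors = np.array(host_pre + host_post)
    donor_anchors = np.vstack([donor_ca[:anchor_size], donor_ca[-anchor_size:]])
    sup = trimmed_superpose(donor_anchors, host_anchors, distance_cutoff=anchor_rmsd_max * 2)
    if sup.rmsd > anchor_rmsd_max:
        raise GraftError(
            f"anchor superposition RMSD {sup.rmsd:.2f} A exceeds {anchor_rmsd_max} A"
        )
    linker_ca = sup.transform.apply(donor_ca[anchor_size : anchor_size + k])
    linker_seq = donor_seq[anchor_size : anchor_size + k]
    linker = [
        BackboneResidue(aa=aa, atoms={"CA": xyz}, provenance="donor", role="linker")
        for aa, xyz in zip(linker_seq, linker_ca)
    ]
    return SymmetricBackbone(
        repeat=[dataclasses.replace(r, atoms=dict(r.atoms)) for r in backbone.repeat],
        axis=backbone.axis,
        order=backbone.order,
        linker=linker,
    )


def _bond_terms(names: list[str]) -> list[tuple[int, int, float]]:
    bonds = []
    for i in range(len(names) - 1):
        pair = (names[i], names[i + 1])
        if pair in IDEAL_BONDS:
            bonds.append((i, i + 1, IDEAL_BONDS[pair]))
        elif names[i] == "O" and names[i + 1] == "N" and i >= 1 and names[i - 1] == "C":
            # O branches off the carbonyl C; the peptide bond links C to the next N
            bonds.append((i - 1, i + 1, IDEAL_BONDS[("C", "N")]))
    return bonds


def _angle_terms(names: list[str]) -> list[tuple[int, int, int, float]]:
    angles = []
    for i in range(len(names) - 2):
        if names[i] == "N" and names[i + 1] == "CA" and names[i + 2] == "C":
            angles.append((i, i + 1, i + 2, IDEAL_N_CA_C))
    return angles


def regularize_backbone(
    coords: np.ndarray,
    names: list[str],
    restraint_weights: dict | None = None,
    max_steps: int = 200,
    clash_distance: float = 3.0,
) -> tuple[np.ndarray, list[float]]:
    """Gradient descent on bonded terms plus a soft-sphere clash term.

    ``names`` lists the backbone atom names ("N", "CA", "C", "O") in chain
    order.  Steps are accepted only if the objective decreases, so the
    objective trace is non-increasing.  Returns (coords, objective trace).
    """
    w = {"bond": 100.0, "angle": 10.0, "clash": 1.0}
    if restraint_weights:
        w.update(restraint_weights)
    x = np.array(coords, dtype=float)
    bonds = _bond_terms(names)
    angles = _angle_terms(names)
    bonded = {(i, j) for i, j, _ in bonds} | {(j, i) for i, j, _ in bonds}

    def objective_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        E = 0.0
        g = np.zeros_like(x)
        for i, j, l0 in bonds:
            v = x[i] - x[j]
            d = np.linalg.norm(v)
            E += w["bond"] * (d - l0) ** 2
            gi = 2 * w["bond"] * (d - l0) * v / max(d, 1e-9)
            g[i] += gi
            g[j] -= gi
        for i, j, kk, th0 in angles:
            u = x[i] - x[j]
            v = x[kk] - x[j]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            c = np.clip(np.dot(u, v) / (nu * nv), -1 + 1e-9, 1 - 1e-9)
            th = np.arccos(c)
            E += w["angle"] * (th - th0) ** 2
            s = np.sqrt(1 - c * c)
            dth_du = -(v / (nu * nv) - c * u / nu**2) / s
            dth_dv = -(u / (nu * nv) - c * v / nv**2) / s
            coeff = 2 * w["angle"] * (th - th0)
            g[i] += coeff * dth_du
            g[kk] += coeff * dth_dv
            g[j] -= coeff * (dth_du + dth_dv)
        # soft-sphere clash between atoms not bonded and >2 apart in order
        diff = x[:, None, :] - x[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        n = len(x)
        iu, ju = np.triu_indices(n, k=3)
        mask = dist[iu, ju] < clash_distance
        for i, j in zip(iu[mask], ju[mask]):
            if (i, j) in bonded:
                continue
            d = dist[i, j]
            E += w["clash"] * (clash_distance - d) ** 2
            gi = -2 * w["clash"] * (clash_distance - d) * diff[i, j] / max(d, 1e-9)
            g[i] += gi
            g[j] -= gi
        if not np.isfinite(E):
            raise FloatingPointError("non-finite regularisation objective")
        return E, g

    E, g = objective_grad(x)
    trace = [E]
    step = 1e-3
    for _ in range(max_steps):
        if np.linalg.norm(g) < 1e-10:
            break
        x_new = x - step * g
        E_new, g_new = objective_grad(x_new)
        if E_new < E:
            x, E, g = x_new, E_new, g_new
            step *= 1.2
            trace.append(E)
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return x, trace


def regularize_symmetric(backbone: SymmetricBackbone, **kwargs) -> SymmetricBackbone:
    """Regularise the full chain, then re-impose exact symmetry by mapping
    every unit back into the template frame and averaging."""
    placed = backbone.residues()
    names, coords, owners = [], [], []
    for k, res in placed:
        for name in ("N", "CA", "C", "O"):
            if name in res.atoms:
                names.append(name)
                coords.append(res.atoms[name])
                owners.append(k)
    new_coords, _ = regularize_backbone(np.array(coords), names, **kwargs)

    # pull each unit back to the template frame and average over copies
    unit_len = len(backbone.unit)
    atom_idx = 0
    unit_atoms: dict[int, list[np.ndarray]] = {}
    counts: dict[int, int] = {}
    for k, res in placed:
        inv = backbone.unit_transform(k)
        inv = RigidTransform(inv.rotation.T, -inv.rotation.T @ inv.translation)
        n_at = sum(1 for name in ("N", "CA", "C", "O") if name in res.atoms)
        back = inv.apply(new_coords[atom_idx : atom_idx + n_at])
        atom_idx += n_at
        local = counts.get(k, 0)
        counts[k] = local + 1
        unit_atoms.setdefault(local, []).append(back)
    new_unit = []
    for local, res in enumerate(backbone.unit):
        avg = np.mean(unit_atoms[local], axis=0)
        atoms = {}
        for i, name in enumerate(n for n in ("N", "CA", "C", "O") if n in res.atoms):
            atoms[name] = avg[i]
        new_unit.append(dataclasses.replace(res, atoms=atoms))
    nrep = len(backbone.repeat)
    return SymmetricBackbone(
        repeat=new_unit[:nrep], axis=backbone.axis, order=backbone.order,
        linker=new_unit[nrep:],
    )
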