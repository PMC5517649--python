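"""Synthetic fixtures with known ground truth.

Three generators make every pipeline stage testable offline: C3-symmetric
(or controllably noisy) C-alpha backbones shaped like a three-repeat
beta-sandwich about the z-axis, repeat sequences evolved from a known
ancestor along a known star tree under a reversible substitution model,
and hollow spherical shells of atoms whose enclosed cavity volume is
known analytically.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ancestors import AMINO_ACIDS, PhyloTree, SubstitutionModel
from .structio import SequenceRecord, Structure, structure_from_ca
from .symmetry import SymmetryAxis

__all__ = [
    "TrefoilParams",
    "EvolutionScenario",
    "make_c3_backbone",
    "make_repeat_trace",
    "evolve",
    "make_shell",
    "ideal_extended_chain",
]

CA_SPACING = 3.8  # consecutive C-alpha distance, A
STRAND_SEPARATION = 4.8  # inter-strand spacing in a sheet, A


class FixtureError(ValueError):
    pass


@dataclasses.dataclass
class TrefoilParams:
    L: int = 47  # residues per repeat
    strands: int = 4
    radial_offset: float = 7.0  # repeat centroid distance from the C3 axis, A
    noise_sigma: float = 0.0  # isotropic Gaussian displacement per atom, A
    seed: int = 1

    def __post_init__(self) -> None:
        if self.L < 20:
            raise FixtureError(f"repeat length {self.L} < 20")
        if self.noise_sigma < 0:
            raise FixtureError("noise sigma must be >= 0")
        if self.radial_offset < 6.0:
            raise FixtureError("radial offset < 6 A would clash repeats at the axis")


def make_repeat_trace(params: TrefoilParams) -> np.ndarray:
    """One repeat as a serpentine C-alpha trace of ``strands`` strands.

    Residues advance 3.3 A along the strand with a +-0.95 A zig-zag so
    consecutive C-alphas sit 3.8 A apart (up to floating point in the
    turns); strands are 4.8 A apart, alternating direction.
    """
    L, n_strands = params.L, params.strands
    per_strand = int(np.ceil(L / n_strands))
    advance = 3.3
    zig = np.sqrt(CA_SPACING**2 - advance**2) / 2  # +-0.95 A about the strand line
    coords = []
    i = 0
    for s in range(n_strands):
        y = s * STRAND_SEPARATION
        direction = 1 if s % 2 == 0 else -1
        n_here = min(per_strand, L - i)
        x0 = 0.0 if direction == 1 else (per_strand - 1) * advance
        for k in range(n_here):
            x = x0 + direction * k * advance
            z = zig if (i % 2 == 0) else -zig
            coords.append([x, y, z])
            i += 1
        if i >= L:
            break
    coords = np.array(coords[:L])
    coords -= coords.mean(axis=0)
    # stand the sheet up (strands along z) and push it out radially in x
    coords = coords[:, [2, 1, 0]]
    coords[:, 0] += params.radial_offset
    return coords


def c3_axis_z() -> SymmetryAxis:
    return SymmetryAxis(direction=np.array([0.0, 0.0, 1.0]), point=np.zeros(3), angle_deg=120.0)


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )


# default repeat sequence for fixtures; carries the HxDxH and HPxGG
# galactose-binding-style motifs so motif gates are exercised
FIXTURE_REPEAT_SEQUENCE = "ADHTDSHGVKLMNPQRSTVWYFEDHIKLHNGARSTVHPDGG" * 3


def make_c3_backbone(
    params: TrefoilParams,
    sequence: str | None = None,
    sequences: list[str] | None = None,
) -> Structure:
    """Three copies of the repeat trace at exact 120-degree rotations about
    the z-axis, one chain per repeat (A, B, C), with optional Gaussian
    noise applied independently per atom.  ``sequences`` assigns a distinct
    sequence per chain (emulating the diverged repeats of a natural
    pseudo-symmetric trefoil); ``sequence`` uses one for all chains."""
    repeat = make_repeat_trace(params)
    d = np.linalg.norm(np.diff(repeat, axis=0), axis=1)
    pair = repeat[:, None, :] - repeat[None, :, :]
    dist = np.linalg.norm(pair, axis=2)
    np.fill_diagonal(dist, np.inf)
    if dist.min() < 2.5:
        raise FixtureError(f"repeat geometry clashes: min CA-CA {dist.min():.2f} A")
    rng = np.random.default_rng(params.seed)
    st = Structure(entry_id="c3_fixture")
    if sequences is None:
        one = sequence or FIXTURE_REPEAT_SEQUENCE[: params.L]
        sequences = [one, one, one]
    if len(sequences) != 3 or any(len(s) != params.L for s in sequences):
        raise FixtureError("need three chain sequences of length L")
    for k, chain in enumerate("ABC"):
        coords = repeat @ _rot_z(120.0 * k).T
        if params.noise_sigma > 0:
            coords = coords + rng.normal(0.0, params.noise_sigma, coords.shape)
        sub = structure_from_ca(coords, sequence=sequences[k], chain=chain, entry_id="c3_fixture")
        for res in sub.chain(chain):
            st.add_residue(chain, res)
    st.metadata["params"] = params
    return st


@dataclasses.dataclass
class EvolutionScenario:
    root: str
    tree: PhyloTree
    model: SubstitutionModel
    seed: int = 1

    def __post_init__(self) -> None:
        bad = set(self.root) - set(AMINO_ACIDS)
        if bad:
            raise FixtureError(f"root sequence has non-standard symbols {sorted(bad)}")


def random_root(length: int, model: SubstitutionModel, seed: int = 1) -> str:
    # distinct sub-stream from evolve() so sharing one seed between the two
    # cannot correlate the root draw with the branch substitution draws
    rng = np.random.default_rng([seed, 0])
    idx = rng.choice(20, size=length, p=model.pi)
    return "".join(AMINO_ACIDS[i] for i in idx)


def evolve(scenario: EvolutionScenario) -> tuple[list[SequenceRecord], SequenceRecord]:
    """Evolve the root sequence down each branch of the tree by sampling
    per-site from P(t) = exp(Qt); returns (leaves, true ancestor)."""
    rng = np.random.default_rng([scenario.seed, 1])
    root_idx = np.array([AMINO_ACIDS.index(a) for a in scenario.root])
    leaves = []
    for name, bl in zip(scenario.tree.leaf_names, scenario.tree.branch_lengths):
        P = scenario.model.transition_matrix(bl)
        cum = P.cumsum(axis=1)
        cum /= cum[:, -1:]
        u = rng.random(len(root_idx))
        child = (cum[root_idx] < u[:, None]).sum(axis=1)
        leaves.append(
            SequenceRecord(id=name, residues="".join(AMINO_ACIDS[i] for i in child))
        )
    return leaves, SequenceRecord(id="ancestor", residues=scenario.root)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_shell(
    inner_radius: float,
    atom_radius: float = 1.7,
    max_gap: float = 1.0,
    seed: int = 1,
    small_probe: float = 1.4,
) -> Structure:
    """A sealed hollow shell of atoms with an analytically known cavity.

    Atom centres tile a sphere of radius (inner_radius + atom_radius) on a
    Fibonacci lattice dense enough that the largest gap between adjacent
    centres is <= ``max_gap``; the analytic small-probe cavity volume
    (4/3) pi (inner_radius - small_probe)^3 is recorded in the metadata.
    """
    if inner_radius <= atom_radius + small_probe:
        raise FixtureError("inner radius too small to enclose a probe-accessible cavity")
    R = inner_radius + atom_radius
    # Fibonacci lattice point spacing ~ sqrt(4 pi R^2 / n); solve for max_gap
    n = int(np.ceil(4.0 * np.pi * R * R / (max_gap * max_gap) * 1.3))
    pts = fibonacci_sphere(n) * R
    # verify the seal: nearest-neighbour gaps
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    if dists[:, 1].max() > 2.0 * small_probe:
        raise FixtureError("shell tiling too sparse: small probe would leak out")
    st = structure_from_ca(pts, chain="S", entry_id="shell_fixture")
    st.metadata["analytic_cavity_volume"] = (
        4.0 / 3.0 * np.pi * (inner_radius - small_probe) ** 3
    )
    st.metadata["inner_radius"] = inner_radius
    st.metadata["atom_radius"] = atom_radius
    return st


def ideal_extended_chain(n_residues: int, include_o: bool = False) -> tuple[np.ndarray, list[str]]:
    """An N-CA-C(-O) chain with exactly ideal bond lengths and N-CA-C
    angles, laid out as a planar zig-zag; the analytic minimum of the
    bonded regularisation objective."""
    from .symmetry import IDEAL_BONDS, IDEAL_N_CA_C

    names_cycle = ["N", "CA", "C"]
    lengths = [IDEAL_BONDS[("N", "CA")], IDEAL_BONDS[("CA", "C")], IDEAL_BONDS[("C", "N")]]
    theta = IDEAL_N_CA_C  # use the same angle at every junction for simplicity
    coords = [np.zeros(3)]
    names = []
    direction_flip = 1
    heading = np.array([1.0, 0.0, 0.0])
    for i in range(n_residues * 3 - 1):
        bond = lengths[i % 3]
        # alternate heading around the ideal angle in the xy-plane
        ang = (np.pi - theta) / 2 * direction_flip
        rot = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        heading = rot @ np.array([1.0, 0.0, 0.0])
        coords.append(coords[-1] + bond * heading)
        direction_flip *= -1
    for i in range(n_residues * 3):
        names.append(names_cycle[i % 3])
    return np.array(coords), names
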