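"""Rigid-body superposition and structure-guided sequence identity.

The Kabsch least-squares fit is the arithmetic behind every structural
comparison in the symmetrisation workflow: repeat-vs-repeat RMSDs, axis
fitting, graft anchoring, and design-vs-template deviations.  The trimmed
variant iteratively discards badly fitting pairs, which is how overlay
statistics such as "N atoms within X Angstrom" are produced.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from .structio import Structure, ca_trace, extract_sequence

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "GeometryError",
    "kabsch",
    "trimmed_superpose",
    "structure_guided_identity",
]


class GeometryError(ValueError):
    pass


@dataclasses.dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise GeometryError("rotation determinant is not +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclasses.dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    correspondence: list[tuple[int, int]]
    trimmed: bool = False

    def to_dict(self) -> dict:
        return {
            "rmsd": self.rmsd,
            "n_atoms": self.n_atoms,
            "trimmed": self.trimmed,
            "rotation": self.transform.rotation.tolist(),
            "translation": self.transform.translation.tolist(),
            "correspondence": self.correspondence,
        }


def _as_points(x) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"expected (n, 3) points, got {pts.shape}")
    return pts


def kabsch(
    points_a: np.ndarray,
    points_b: np.ndarray,
    correspondence: Sequence[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of paired point sets.

    Returns the transform that maps ``points_a`` onto ``points_b`` and the
    residual RMSD.  SVD with determinant sign correction; degenerate
    (collinear or too-small) inputs raise :class:`GeometryError`.
    """
    A = _as_points(points_a)
    B = _as_points(points_b)
    if A.shape != B.shape:
        raise GeometryError(f"point sets differ in shape: {A.shape} vs {B.shape}")
    n = len(A)
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    # collinearity check: rank of the centred configuration
    if np.linalg.matrix_rank(Ac, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point configuration")
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cb - R @ ca
    transform = RigidTransform(R, t)
    diff = transform.apply(A) - B
    rmsd = float(np.sqrt((diff**2).sum() / n))
    if correspondence is None:
        correspondence = [(i, i) for i in range(n)]
    return SuperpositionResult(transform, rmsd, n, list(correspondence))


def raw_rmsd(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """RMSD of the pairing as given, with no superposition."""
    A, B = _as_points(points_a), _as_points(points_b)
    return float(np.sqrt(((A - B) ** 2).sum() / len(A)))


def trimmed_superpose(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    distance_cutoff: float = 3.5,
    max_iter: int = 20,
    correspondence: Sequence[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Iteratively superpose and discard pairs beyond ``distance_cutoff``.

    The retained pair set never grows; convergence is reached when no pair
    exceeds the cutoff.  To keep gross outliers from skewing the early fits
    (and dragging well-fitting pairs over the cutoff with them), at most the
    worst 10% of retained pairs are discarded per iteration.  Raises if
    fewer than 3 pairs survive.
    """
    A = _as_points(trace_a)
    B = _as_points(trace_b)
    if correspondence is None:
        if len(A) != len(B):
            raise GeometryError("equal-length traces or an explicit correspondence required")
        pairs = [(i, i) for i in range(len(A))]
    else:
        pairs = list(correspondence)
    result = None
    for _ in range(max_iter):
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        if len(pairs) < 3:
            raise GeometryError("trimmed correspondence shrank below 3 pairs")
        result = kabsch(A[ia], B[ib], correspondence=pairs)
        moved = result.transform.apply(A[ia])
        dist = np.linalg.norm(moved - B[ib], axis=1)
        if (dist <= distance_cutoff).all():
            break
        threshold = max(distance_cutoff, float(np.quantile(dist, 0.9)))
        keep = dist <= threshold
        if keep.all():  # ensure progress: drop at least the single worst pair
            keep[np.argmax(dist)] = False
        pairs = [p for p, k in zip(pairs, keep) if k]
    assert result is not None
    result.trimmed = True
    return result


def _pair_by_distance(
    dist: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """One-to-one, sequence-order-preserving pairing of residues whose
    distance is <= cutoff, maximising sum(cutoff - d) by dynamic programming.
    Ties favour the smaller distance, then the lower residue index."""
    n, m = dist.shape
    score = np.where(dist <= cutoff, cutoff - dist, -np.inf)
    dp = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = dp[i - 1, j - 1] + score[i - 1, j - 1] if np.isfinite(score[i - 1, j - 1]) else -np.inf
            dp[i, j] = max(match, dp[i - 1, j], dp[i, j - 1])
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if np.isfinite(score[i - 1, j - 1]) and np.isclose(dp[i, j], dp[i - 1, j - 1] + score[i - 1, j - 1]):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif np.isclose(dp[i, j], dp[i - 1, j]):
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _alignment_correspondence(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Global sequence alignment (BLOSUM62, affine 10/0.5) as a seed pairing."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    aln = aligner.align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def structure_guided_identity(
    struct_a: Structure,
    struct_b: Structure,
    chain_a: str | None = None,
    chain_b: str | None = None,
    pairing_cutoff: float = 3.5,
) -> tuple[float, list[tuple[int, int]]]:
    """Percent sequence identity over structurally equivalent positions.

    Residues are paired one-to-one (sequence order preserved) when their
    C-alpha atoms lie within ``pairing_cutoff`` after a trimmed
    superposition seeded by a global sequence alignment.  The denominator
    is the number of paired positions, reported to 0.1%.
    """
    chain_a = chain_a or struct_a.chain_ids[0]
    chain_b = chain_b or struct_b.chain_ids[0]
    trace_a, _ = ca_trace(struct_a, chain_a)
    trace_b, _ = ca_trace(struct_b, chain_b)
    seq_a = extract_sequence(struct_a, chain_a).residues
    seq_b = extract_sequence(struct_b, chain_b).residues
    A = np.array([p for _, p in trace_a])
    B = np.array([p for _, p in trace_b])
    seed = _alignment_correspondence(seq_a, seq_b)
    sup = trimmed_superpose(A, B, distance_cutoff=pairing_cutoff * 2, correspondence=seed)
    moved = sup.transform.apply(A)
    dist = np.linalg.norm(moved[:, None, :] - B[None, :, :], axis=2)
    pairs = _pair_by_distance(dist, pairing_cutoff)
    if len(pairs) < 10:
        raise GeometryError(f"only {len(pairs)} residues paired; structures not alignable")
    identical = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    identity = round(100.0 * identical / len(pairs), 1)
    return identity, pairs


def superpose_report(result: SuperpositionResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)
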