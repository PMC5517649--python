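"""Maximum-likelihood ancestral sequence reconstruction.

The three repeats of a trefoil are treated as leaves of a 3-leaf star
phylogeny descending from the symmetric ancestor.  Branch lengths are
fitted by maximising the Felsenstein pruning likelihood under a
reversible 20-state substitution model; per-site marginal posteriors at
the root give the maximum-a-posteriori ancestral sequence and a pool of
sampled candidates for threading.

Model note: empirical exchangeabilities are derived from the BLOSUM62
target frequencies (S_ij = 2^(s_ij / 2)); a uniform-exchangeability
(Poisson-type) model is also available, and any PAML-format rate file
can be loaded.  Equilibrium frequencies default to the observed residue
frequencies of the alignment with a pseudocount.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .structio import SequenceRecord

__all__ = [
    "AMINO_ACIDS",
    "Alignment",
    "PhyloTree",
    "SubstitutionModel",
    "AncestralPosterior",
    "CandidateSequenceSet",
    "align_repeats",
    "infer_tree",
    "pruning_loglik",
    "marginal_posterior",
    "sample_candidates",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"


@dataclasses.dataclass
class Alignment:
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned rows differ in length: {lengths}")

    @property
    def n_sites(self) -> int:
        return len(self.records[0].residues)

    @property
    def names(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, i: int) -> list[str]:
        return [r.residues[i] for r in self.records]

    def frequencies(self, pseudocount: float = 1.0) -> np.ndarray:
        counts = np.full(20, pseudocount)
        for r in self.records:
            for aa in r.residues:
                if aa in AA_INDEX:
                    counts[AA_INDEX[aa]] += 1
        return counts / counts.sum()


@dataclasses.dataclass
class PhyloTree:
    """Rooted star tree: every leaf hangs directly off the root.

    Sufficient for the three-repeat problem (an unrooted 3-leaf tree has a
    single internal node); branch lengths are expected substitutions/site.
    """

    leaf_names: list[str]
    branch_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        if len(self.leaf_names) != len(self.branch_lengths):
            raise ValueError("one branch length per leaf required")
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("leaf names must be unique")
        if not np.all(np.isfinite(self.branch_lengths)) or np.any(self.branch_lengths < 0):
            raise ValueError("branch lengths must be finite and non-negative")

    def to_newick(self) -> str:
        parts = ",".join(
            f"{name}:{bl:.6f}" for name, bl in zip(self.leaf_names, self.branch_lengths)
        )
        return f"({parts});"

    @staticmethod
    def from_newick(text: str) -> "PhyloTree":
        inner = text.strip().rstrip(";").strip()
        if not (inner.startswith("(") and inner.endswith(")")):
            raise ValueError(f"not a star-tree newick string: {text!r}")
        names, lengths = [], []
        for part in inner[1:-1].split(","):
            if ":" in part:
                name, bl = part.rsplit(":", 1)
                names.append(name.strip())
                lengths.append(float(bl))
            else:
                names.append(part.strip())
                lengths.append(0.0)
        return PhyloTree(names, np.array(lengths))


class SubstitutionModel:
    """Reversible 20-state rate model from exchangeabilities and
    equilibrium frequencies, normalised to 1 expected substitution/site."""

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray, name: str = "custom"):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (20, 20) or pi.shape != (20,):
            raise ValueError("need a 20x20 exchangeability matrix and 20 frequencies")
        if not np.allclose(S, S.T, atol=1e-9):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-9:
            raise ValueError("frequencies must be positive and sum to 1")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(pi, np.diag(Q))
        Q = Q / rate
        self.Q = Q
        self.pi = pi
        self.name = name
        # spectral decomposition of the symmetrised generator (exact for reversible Q)
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = (B + B.T) / 2
        self._eigval, self._eigvec = np.linalg.eigh(B)
        self._sq = sq

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), rows = ancestral state, columns = descendant."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        U = self._eigvec
        expl = np.exp(self._eigval * t)
        M = (U * expl[None, :]) @ U.T
        P = (M / self._sq[:, None]) * self._sq[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    @staticmethod
    def poisson(frequencies: np.ndarray | None = None) -> "SubstitutionModel":
        pi = np.full(20, 0.05) if frequencies is None else np.asarray(frequencies)
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        return SubstitutionModel(S, pi, name="poisson")

    @staticmethod
    def blosum62(frequencies: np.ndarray | None = None) -> "SubstitutionModel":
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        S = np.zeros((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                if i != j:
                    S[i, j] = 2.0 ** (mat[a, b] / 2.0)
        S = (S + S.T) / 2
        pi = np.full(20, 0.05) if frequencies is None else np.asarray(frequencies)
        return SubstitutionModel(S, pi, name="blosum62")

    @staticmethod
    def from_paml(path, frequencies: np.ndarray | None = None, name: str = "paml") -> "SubstitutionModel":
        """Load a PAML .dat empirical model (lower-triangular rates then
        frequencies, PAML amino-acid order = this module's order)."""
        values: list[float] = []
        for line in open(path):
            line = line.split("#")[0].strip()
            if line:
                values.extend(float(v) for v in line.split())
        if len(values) < 190:
            raise ValueError("PAML file too short: need 190 exchangeabilities")
        S = np.zeros((20, 20))
        idx = 0
        for i in range(1, 20):
            for j in range(i):
                S[i, j] = S[j, i] = values[idx]
                idx += 1
        if frequencies is None:
            if len(values) >= idx + 20:
                frequencies = np.array(values[idx : idx + 20])
                frequencies = frequencies / frequencies.sum()
            else:
                frequencies = np.full(20, 0.05)
        return SubstitutionModel(S, np.asarray(frequencies), name=name)


def make_model(name: str, frequencies: np.ndarray | None = None) -> SubstitutionModel:
    if name == "poisson":
        return SubstitutionModel.poisson(frequencies)
    if name == "blosum62":
        return SubstitutionModel.blosum62(frequencies)
    raise ValueError(f"unknown model {name!r} (use 'blosum62', 'poisson', or from_paml)")


@dataclasses.dataclass
class AncestralPosterior:
    """Per-site root posterior over the 20 amino acids."""

    probabilities: np.ndarray  # (n_sites, 20)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 20:
            raise ValueError("posterior must be (n_sites, 20)")
        if np.any(p < -1e-12) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must be probability vectors")
        self.probabilities = np.clip(p, 0.0, None)

    @property
    def n_sites(self) -> int:
        return len(self.probabilities)

    def map_sequence(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.probabilities.argmax(axis=1))

    def entropy(self) -> np.ndarray:
        p = np.clip(self.probabilities, 1e-300, None)
        return -(p * np.log(p)).sum(axis=1)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.probabilities, columns=list(AMINO_ACIDS))
        df.index = np.arange(1, self.n_sites + 1)
        df.index.name = "site"
        df.to_csv(path, sep="\t", float_format="%.6g")


@dataclasses.dataclass
class Candidate:
    sequence: str
    log_posterior: float
    provenance: str  # "MAP" | "sampled"
    seed: int | None = None


@dataclasses.dataclass
class CandidateSequenceSet:
    candidates: list[Candidate]

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, c in enumerate(self.candidates):
                fh.write(f">cand{i:05d} logP={c.log_posterior:.4f} {c.provenance}\n{c.sequence}\n")


# ---------------------------------------------------------------------------
# alignment


def _pairwise_align(seq_ref: str, seq_other: str) -> list[tuple[int, int]]:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    aln = aligner.align(seq_ref, seq_other)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def align_repeats(
    seqs: Sequence[SequenceRecord],
    guide_pairing: Sequence[tuple[int | None, ...]] | None = None,
) -> Alignment:
    """Align the repeat sequences.

    With ``guide_pairing`` (a list of per-sequence index tuples, one tuple
    per alignment column, None for a gap) the columns follow the guide
    exactly.  Otherwise a star multiple alignment is built around the first
    sequence from global pairwise alignments (Needleman-Wunsch, BLOSUM62,
    affine gap open 10 / extend 0.5).
    """
    if guide_pairing is not None:
        cols = list(guide_pairing)
        last_seen = [-1] * len(seqs)
        rows = [[] for _ in seqs]
        for col in cols:
            if len(col) != len(seqs):
                raise ValueError("guide column arity must match sequence count")
            for s, idx in enumerate(col):
                if idx is None:
                    rows[s].append(GAP)
                else:
                    if idx <= last_seen[s]:
                        raise ValueError("guide pairing violates sequence order")
                    last_seen[s] = idx
                    rows[s].append(seqs[s].residues[idx])
        return Alignment(
            [SequenceRecord(id=s.id, residues="".join(r)) for s, r in zip(seqs, rows)]
        )

    ref = seqs[0].residues
    # star alignment: merge every pairwise alignment on the reference scaffold
    pairings = [_pairwise_align(ref, s.residues) for s in seqs[1:]]
    # positions in the final alignment: reference positions, plus insertions
    # of other sequences placed after the preceding reference position
    insertions: dict[int, int] = {}
    maps = []
    for s, pairs in zip(seqs[1:], pairings):
        paired = dict(pairs)
        maps.append(paired)
        rev = {j: i for i, j in pairs}
        run = 0
        anchor = -1
        for j in range(len(s.residues)):
            if j in rev:
                anchor = rev[j]
                run = 0
            else:
                run += 1
                insertions[anchor] = max(insertions.get(anchor, 0), run)

    columns: list[tuple[str, int]] = []  # ("ref", i) or ("ins", slot)
    for slot in range(insertions.get(-1, 0)):
        columns.append(("ins", -1))
    for i in range(len(ref)):
        columns.append(("ref", i))
        for slot in range(insertions.get(i, 0)):
            columns.append(("ins", i))

    rows = [[] for _ in seqs]
    for kind, i in columns:
        rows[0].append(ref[i] if kind == "ref" else GAP)
    for s_idx, (s, paired) in enumerate(zip(seqs[1:], maps), start=1):
        rev = {j: i for i, j in paired.items()}
        row = []
        j = 0
        seq = s.residues
        # walk columns, emitting residues aligned to ref or into insertion slots
        unplaced: dict[int, list[str]] = {}
        anchor = -1
        for jj in range(len(seq)):
            if jj in rev:
                anchor = rev[jj]
            else:
                unplaced.setdefault(anchor, []).append(seq[jj])
        taken: dict[int, int] = {}
        for kind, i in columns:
            if kind == "ref":
                if i in paired:
                    row.append(seq[paired[i]])
                else:
                    row.append(GAP)
            else:
                pool = unplaced.get(i, [])
                k = taken.get(i, 0)
                if k < len(pool):
                    row.append(pool[k])
                    taken[i] = k + 1
                else:
                    row.append(GAP)
        rows[s_idx] = row
    return Alignment(
        [SequenceRecord(id=s.id, residues="".join(r)) for s, r in zip(seqs, rows)]
    )


# ---------------------------------------------------------------------------
# likelihood


def _leaf_conditionals(alignment: Alignment) -> np.ndarray:
    """(n_leaves, n_sites, 20) conditional likelihood vectors; gaps and X are
    missing data (all ones)."""
    L = np.ones((len(alignment.records), alignment.n_sites, 20))
    for r, rec in enumerate(alignment.records):
        for s, aa in enumerate(rec.residues):
            if aa in AA_INDEX:
                L[r, s, :] = 0.0
                L[r, s, AA_INDEX[aa]] = 1.0
    return L


def _site_root_partials(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> np.ndarray:
    """(n_sites, 20) product over branches of P(t) @ leaf conditionals."""
    order = {name: i for i, name in enumerate(alignment.names)}
    L = _leaf_conditionals(alignment)
    partial = np.ones((alignment.n_sites, 20))
    for name, bl in zip(tree.leaf_names, tree.branch_lengths):
        if name not in order:
            raise ValueError(f"tree leaf {name!r} not found in alignment rows")
        P = model.transition_matrix(bl)
        partial *= L[order[name]] @ P.T
    return partial


def pruning_loglik(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> tuple[float, np.ndarray]:
    """Felsenstein pruning log-likelihood; returns (total, per-site)."""
    partial = _site_root_partials(alignment, tree, model)
    site_lik = partial @ model.pi
    if np.any(site_lik <= 0) or not np.all(np.isfinite(site_lik)):
        raise FloatingPointError("non-positive or non-finite site likelihood")
    per_site = np.log(site_lik)
    return float(per_site.sum()), per_site


def infer_tree(
    alignment: Alignment,
    model: SubstitutionModel | None = None,
    max_branch_length: float = 10.0,
    tol: float = 1e-6,
    max_cycles: int = 50,
) -> PhyloTree:
    """ML branch lengths for the rooted star tree over the alignment rows.

    Each branch is optimised in turn by bounded scalar maximisation of the
    pruning likelihood, cycling until the total log-likelihood changes by
    less than ``tol``.
    """
    if alignment.n_sites == 0:
        raise ValueError("zero-length alignment")
    if model is None:
        model = SubstitutionModel.blosum62(alignment.frequencies())
    names = alignment.names
    lengths = np.full(len(names), 0.1)
    prev = -np.inf
    for _ in range(max_cycles):
        for b in range(len(names)):
            def neg(bl: float, b=b) -> float:
                trial = lengths.copy()
                trial[b] = bl
                ll, _ = pruning_loglik(alignment, PhyloTree(names, trial), model)
                return -ll

            res = minimize_scalar(neg, bounds=(0.0, max_branch_length), method="bounded",
                                  options={"xatol": tol / 10})
            lengths[b] = res.x
        ll, _ = pruning_loglik(alignment, PhyloTree(names, lengths), model)
        if abs(ll - prev) < tol:
            break
        prev = ll
    # snap numerically-zero branches
    lengths[lengths < 1e-7] = 0.0
    return PhyloTree(names, lengths)


def marginal_posterior(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> AncestralPosterior:
    """Per-site marginal posterior of the root state:
    P(root = a | data) proportional to pi_a * prod_branches (P(t) L_leaf)_a."""
    partial = _site_root_partials(alignment, tree, model)
    unnorm = partial * model.pi[None, :]
    total = unnorm.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise FloatingPointError("zero marginal likelihood at some site")
    return AncestralPosterior(unnorm / total)


def sample_candidates(
    posterior: AncestralPosterior,
    n: int,
    seed: int = 1,
    include_map: bool = True,
) -> CandidateSequenceSet:
    """Draw n candidate ancestral sequences, sites independent.

    The MAP sequence is entry 0 when requested (counted in n); each entry
    records its log posterior probability under the per-site posteriors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = posterior.probabilities
    logp = np.log(np.clip(p, 1e-300, None))
    out: list[Candidate] = []
    if include_map:
        idx = p.argmax(axis=1)
        out.append(
            Candidate(
                sequence="".join(AMINO_ACIDS[i] for i in idx),
                log_posterior=float(logp[np.arange(len(idx)), idx].sum()),
                provenance="MAP",
            )
        )
    cum = p.cumsum(axis=1)
    cum /= cum[:, -1:]
    while len(out) < n:
        u = rng.random(posterior.n_sites)
        idx = (cum < u[:, None]).sum(axis=1)
        out.append(
            Candidate(
                sequence="".join(AMINO_ACIDS[i] for i in idx),
                log_posterior=float(logp[np.arange(len(idx)), idx].sum()),
                provenance="sampled",
                seed=seed,
            )
        )
    return CandidateSequenceSet(out)
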