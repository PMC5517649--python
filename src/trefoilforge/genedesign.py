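"""Backtranslation and gene design for bacterial expression.

A designed protein is converted to a coding DNA sequence using an
E. coli codon-usage table, framed by NdeI/XhoI restriction sites for
cloning (the NdeI site CATATG supplies the start codon), stripped of any
internal occurrence of the flanking enzymes' sites, and repaired for
self-annealing segments (exact reverse-complement repeats that could
form hairpins or misprime) — all by silent, translation-preserving
codon swaps recorded in an edit log.
"""

from __future__ import annotations

import dataclasses
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "CodonUsageTable",
    "GeneDesign",
    "RESTRICTION_SITES",
    "backtranslate",
    "scan_sites",
    "remove_internal_sites",
    "fix_self_annealing",
    "design_gene",
    "reverse_complement",
]

RESTRICTION_SITES = {"NdeI": "CATATG", "XhoI": "CTCGAG"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class GeneDesignError(ValueError):
    pass


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    return str(Seq(dna).translate())


class CodonUsageTable:
    """Relative codon frequencies per amino acid (each summing to 1)."""

    def __init__(self, table: dict[str, list[tuple[str, float]]], organism: str = "custom"):
        self.organism = organism
        self._table: dict[str, list[tuple[str, float]]] = {}
        for aa, codons in table.items():
            if not codons:
                raise GeneDesignError(f"amino acid {aa} has no codons")
            total = sum(f for _, f in codons)
            if abs(total - 1.0) > 1e-9:
                raise GeneDesignError(f"{aa}: codon fractions sum to {total}, not 1")
            if any(f < 0 for _, f in codons):
                raise GeneDesignError(f"{aa}: negative codon fraction")
            # stored most-frequent first, alphabetical among ties
            self._table[aa] = sorted(codons, key=lambda cf: (-cf[1], cf[0]))

    def codons(self, aa: str) -> list[tuple[str, float]]:
        if aa not in self._table:
            raise GeneDesignError(f"no codons for residue {aa!r}")
        return self._table[aa]

    def best_codon(self, aa: str) -> str:
        return self.codons(aa)[0][0]

    def amino_acid(self, codon: str) -> str:
        aa = translate(codon)
        return aa

    @staticmethod
    def from_tsv(path) -> "CodonUsageTable":
        table: dict[str, list[tuple[str, float]]] = {}
        organism = "custom"
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                if "coli" in line:
                    organism = "E. coli K-12"
                continue
            if not line.strip() or line.startswith("aa\t"):
                continue
            aa, codon, frac = line.split("\t")
            table.setdefault(aa, []).append((codon, float(frac)))
        return CodonUsageTable(table, organism=organism)

    @staticmethod
    def ecoli_k12() -> "CodonUsageTable":
        with resources.as_file(
            resources.files("trefoilforge.data").joinpath("ecoli_k12_codon_usage.tsv")
        ) as p:
            return CodonUsageTable.from_tsv(p)


@dataclasses.dataclass
class GeneDesign:
    protein: str
    coding: str  # codons only, starts with ATG when protein starts with M
    flank5: str = "CAT"  # completes the NdeI site with the ATG start
    flank3: str = RESTRICTION_SITES["XhoI"]
    enzymes: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(RESTRICTION_SITES)
    )
    edit_log: list[dict] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        if translate(self.coding) != self.protein:
            raise GeneDesignError("coding region does not translate to the input protein")

    @property
    def construct(self) -> str:
        return self.flank5 + self.coding + self.flank3

    def codon(self, i: int) -> str:
        return self.coding[3 * i : 3 * i + 3]

    def set_codon(self, i: int, codon: str, reason: str) -> None:
        old = self.codon(i)
        if translate(codon) != translate(old):
            raise GeneDesignError(f"codon swap {old}->{codon} is not synonymous")
        self.coding = self.coding[: 3 * i] + codon + self.coding[3 * i + 3 :]
        self.edit_log.append({"codon_index": i, "old": old, "new": codon, "reason": reason})
        self.check()

    def internal_sites(self) -> list[tuple[str, int]]:
        """Occurrences of the flanking enzymes' sites in the construct other
        than the two intended flank positions."""
        hits = scan_sites(self.construct, self.enzymes)
        expected = {
            ("NdeI", len(self.flank5) - 3),
            ("XhoI", len(self.flank5) + len(self.coding)),
        }
        return [h for h in hits if h not in expected]

    def write_edit_log(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.edit_log).to_csv(path, sep="\t", index=False)


def backtranslate(
    protein: str,
    table: CodonUsageTable | None = None,
    mode: str = "max",
    seed: int = 1,
) -> GeneDesign:
    """Backtranslate a protein into codons.

    mode "max": the most frequent codon per residue (ties alphabetical);
    mode "sample": codons drawn from the usage fractions under ``seed``.
    Translation round-trips exactly by construction.
    """
    if not protein:
        raise GeneDesignError("empty protein")
    bad = set(protein) - set("ARNDCQEGHILKMFPSTWYV")
    if bad:
        raise GeneDesignError(f"protein contains non-standard symbols {sorted(bad)}")
    table = table or CodonUsageTable.ecoli_k12()
    rng = np.random.default_rng(seed)
    codons = []
    for aa in protein:
        options = table.codons(aa)
        if mode == "max":
            codons.append(options[0][0])
        elif mode == "sample":
            names = [c for c, _ in options]
            freqs = np.array([f for _, f in options])
            codons.append(names[rng.choice(len(names), p=freqs / freqs.sum())])
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return GeneDesign(protein=protein, coding="".join(codons))


def scan_sites(dna: str, enzymes: dict[str, str]) -> list[tuple[str, int]]:
    """All occurrences of each recognition site on the given strand and its
    reverse complement, as 0-based forward-strand positions; palindromic
    sites are reported once per occurrence."""
    bad = set(dna) - set("ACGT")
    if bad:
        raise GeneDesignError(f"non-ACGT symbols in DNA: {sorted(bad)}")
    hits: set[tuple[str, int]] = set()
    for name, site in enzymes.items():
        for probe in {site, reverse_complement(site)}:
            start = 0
            while True:
                pos = dna.find(probe, start)
                if pos < 0:
                    break
                hits.add((name, pos))
                start = pos + 1
    return sorted(hits, key=lambda h: (h[1], h[0]))


def _codons_overlapping(design: GeneDesign, pos: int, length: int) -> list[int]:
    """Indices of coding codons overlapping construct positions
    [pos, pos + length)."""
    lo = pos - len(design.flank5)
    hi = lo + length - 1
    first = max(lo // 3, 0)
    last = min(hi // 3, len(design.protein) - 1)
    return list(range(first, last + 1))


def remove_internal_sites(design: GeneDesign, enzymes: dict[str, str] | None = None,
                          max_rounds: int = 50) -> GeneDesign:
    """Remove internal restriction sites by minimal silent codon swaps
    (highest-frequency alternative codon first).  Raises if a site cannot
    be broken synonymously."""
    if enzymes is not None:
        design.enzymes = dict(enzymes)
    table = CodonUsageTable.ecoli_k12()
    for _ in range(max_rounds):
        internal = design.internal_sites()
        if not internal:
            return design
        name, pos = internal[0]
        site_len = len(design.enzymes[name])
        fixed = False
        for ci in _codons_overlapping(design, pos, site_len):
            current = design.codon(ci)
            for alt, _f in table.codons(design.protein[ci]):
                if alt == current:
                    continue
                trial = dataclasses.replace(
                    design, coding=design.coding[: 3 * ci] + alt + design.coding[3 * ci + 3 :],
                    edit_log=list(design.edit_log),
                )
                if (name, pos) not in trial.internal_sites():
                    design.set_codon(ci, alt, reason=f"remove internal {name} at {pos}")
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            raise GeneDesignError(
                f"internal {name} site at {pos} cannot be removed by silent edits"
            )
    raise GeneDesignError("site removal did not converge")


def find_inverted_repeats(dna: str, stem_min: int = 10) -> list[tuple[int, int]]:
    """All position pairs (i, j), i <= j, where the ``stem_min``-mer at i is
    the exact reverse complement of the one at j (brute-force definition of
    a self-annealing stem; longer stems appear as runs of such pairs)."""
    k = stem_min
    kmers: dict[str, list[int]] = {}
    for i in range(len(dna) - k + 1):
        kmers.setdefault(dna[i : i + k], []).append(i)
    pairs = []
    for i in range(len(dna) - k + 1):
        rc = reverse_complement(dna[i : i + k])
        for j in kmers.get(rc, []):
            if j >= i:
                pairs.append((i, j))
    return pairs


def fix_self_annealing(
    design: GeneDesign,
    stem_min: int = 10,
    window: int = 50,
    max_rounds: int = 200,
) -> GeneDesign:
    """Break self-annealing stems (exact reverse-complement repeats of
    length >= ``stem_min`` anywhere in the construct) by silent codon swaps,
    choosing the next-most-frequent codon, iterating to a fixpoint.

    ``window`` only classifies matches in the edit log (separation <=
    window -> "hairpin", else "inverted_repeat"); detection and repair
    cover every separation.  Residual stems that cannot be broken
    synonymously produce a warning, not a failure.
    """
    table = CodonUsageTable.ecoli_k12()
    tried: set[tuple[int, str]] = set()
    for _ in range(max_rounds):
        pairs = find_inverted_repeats(design.construct, stem_min)
        if not pairs:
            return design
        i, j = pairs[0]
        kind = "hairpin" if (j - i) <= window else "inverted_repeat"
        fixed = False
        for pos in (i, j):
            for ci in _codons_overlapping(design, pos, stem_min):
                current = design.codon(ci)
                for alt, _f in table.codons(design.protein[ci]):
                    if alt == current or (ci, alt) in tried:
                        continue
                    trial_coding = design.coding[: 3 * ci] + alt + design.coding[3 * ci + 3 :]
                    trial = dataclasses.replace(design, coding=trial_coding,
                                                edit_log=list(design.edit_log))
                    if len(find_inverted_repeats(trial.construct, stem_min)) < len(pairs) and not trial.internal_sites():
                        design.set_codon(ci, alt, reason=f"break {kind} {i}/{j}")
                        tried.add((ci, alt))
                        fixed = True
                        break
                if fixed:
                    break
            if fixed:
                break
        if not fixed:
            warnings.warn(
                f"residual self-annealing stems remain (first at {i}/{j}); "
                "no synonymous codon swap breaks them", stacklevel=2,
            )
            return design
    warnings.warn("self-annealing repair hit the round limit", stacklevel=2)
    return design


def design_gene(
    protein: str,
    table: CodonUsageTable | None = None,
    mode: str = "max",
    seed: int = 1,
    stem_min: int = 10,
) -> GeneDesign:
    """Full gene design: backtranslate, frame with NdeI/XhoI, remove
    internal sites, repair self-annealing.  The protein must begin with
    methionine so the NdeI site can supply the start codon."""
    if not protein.startswith("M"):
        raise GeneDesignError("protein must start with the initiator methionine")
    design = backtranslate(protein, table=table, mode=mode, seed=seed)
    design = remove_internal_sites(design)
    design = fix_self_annealing(design, stem_min=stem_min)
    return design
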