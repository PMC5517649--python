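"""End-to-end symmetric-trefoil design runs.

Orchestrates the full procedure: load (or synthesise) a pseudo-threefold
template, extract the three repeats, reconstruct the ancestral repeat
sequence pool, fit the C3 axis, build symmetric backbone variants (plain
linkers, or 6- and 9-residue grafted linkers), thread and score every
candidate on every backbone, select the energy-best / RMSD-best /
cavity-best designs, and backtranslate the winner for expression.
Deterministic under fixed seeds; every stage failure is tagged with its
stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestors, cavity, genedesign, symmetry, synthetic, threading
from .structio import SequenceRecord, Structure, read_pdb, structure_from_ca, write_pdb
from .superpose import kabsch

__all__ = ["RunConfig", "RunReport", "run", "report", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    template: str = "synthetic"  # "synthetic" or a PDB path
    repeat_ranges: list[tuple[str, int, int]] | None = None
    repeat_length: int = 47  # synthetic template repeat length
    noise_sigma: float = 0.0  # synthetic template asymmetry noise, A
    donor: str | None = None  # donor PDB for grafting; None -> synthetic donor
    donor_range: tuple[str, int, int] | None = None
    grafts: tuple[int, ...] = (0, 6, 9)  # 0 = plain single-glycine linkers
    n_candidates: int = 2000
    model: str = "blosum62"
    weights: dict = dataclasses.field(default_factory=dict)
    spacing: float = 0.6
    small_probe: float = 1.4
    large_probe: float = 4.0
    rigid_search: bool = False
    sequence_divergence: float = 0.15  # synthetic template: repeat branch length
    seed: int = 1
    outdir: str | None = None
    motif_gate: str = "flag"  # "flag" or "filter"

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        for k in self.grafts:
            if k not in (0, 6, 9):
                raise ValueError(f"graft length {k} not in {{0, 6, 9}}")
        if self.motif_gate not in ("flag", "filter"):
            raise ValueError("motif_gate must be 'flag' or 'filter'")
        if self.template != "synthetic" and not Path(self.template).exists():
            raise FileNotFoundError(self.template)
        if self.donor is not None and not Path(self.donor).exists():
            raise FileNotFoundError(self.donor)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "repeat_ranges" in data and data["repeat_ranges"] is not None:
            data["repeat_ranges"] = [tuple(r) for r in data["repeat_ranges"]]
        if "donor_range" in data and data["donor_range"] is not None:
            data["donor_range"] = tuple(data["donor_range"])
        if "grafts" in data:
            data["grafts"] = tuple(data["grafts"])
        return RunConfig(**data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunReport:
    table: pd.DataFrame  # one row per (backbone variant, candidate)
    selections: dict[str, dict]  # "-1"/"-2"/"-3" -> row record
    subdomain_objectives: dict[str, float]
    axis_angle_deg: float
    gene: genedesign.GeneDesign | None
    provenance: dict

    def selection_row(self, tag: str) -> dict:
        return self.selections[tag]


def _load_template(config: RunConfig) -> tuple[Structure, list[tuple[str, int, int]]]:
    if config.template == "synthetic":
        params = synthetic.TrefoilParams(
            L=config.repeat_length, noise_sigma=config.noise_sigma, seed=config.seed
        )
        L = config.repeat_length
        # diverged repeat sequences, like a natural pseudo-symmetric trefoil
        model = ancestors.make_model(config.model)
        root = synthetic.FIXTURE_REPEAT_SEQUENCE[:L]
        tree = ancestors.PhyloTree(
            ["A", "B", "C"], np.full(3, config.sequence_divergence)
        )
        leaves, _ = synthetic.evolve(
            synthetic.EvolutionScenario(root, tree, model, seed=config.seed)
        )
        st = synthetic.make_c3_backbone(params, sequences=[l.residues for l in leaves])
        ranges = [("A", 1, L), ("B", 1, L), ("C", 1, L)]
        return st, ranges
    st = read_pdb(config.template)
    if not config.repeat_ranges:
        raise StageError("template", "repeat_ranges are required for a PDB template")
    return st, config.repeat_ranges


def _synthetic_linker(backbone: symmetry.SymmetricBackbone, linker_seq: str) -> list[symmetry.BackboneResidue]:
    """Place plain linker residues by interpolation between the end of one
    repeat and the start of the next (rotated) repeat."""
    start = backbone.repeat[-1].ca
    end = backbone.unit_transform(1).apply(backbone.repeat[0].ca[None, :])[0]
    m = len(linker_seq)
    out = []
    for i, aa in enumerate(linker_seq, start=1):
        f = i / (m + 1)
        out.append(
            symmetry.BackboneResidue(
                aa=aa, atoms={"CA": (1 - f) * start + f * end}, role="linker"
            )
        )
    return out


# synthetic donor linker sequences; the 9-residue version carries the
# core tryptophan like a Threefoil-style donor would
_DONOR_SEQ = {6: "GDGSGT", 9: "GDGWSGTSG"}


def make_synthetic_donor(backbone: symmetry.SymmetricBackbone, k: int) -> tuple[Structure, tuple[str, int, int]]:
    """A synthetic graft donor: host junction anchors with k arc-placed
    linker residues between them (stand-in for a donor trefoil's linker
    region when no donor structure is supplied)."""
    anchors_pre = [r.ca for r in backbone.repeat[-3:]]
    tr1 = backbone.unit_transform(1)
    anchors_post = [tr1.apply(r.ca[None, :])[0] for r in backbone.repeat[:3]]
    start, end = anchors_pre[-1], anchors_post[0]
    axis_point = backbone.axis.point
    coords = list(anchors_pre)
    seq = ["G", "G", "G"]
    for i, aa in enumerate(_DONOR_SEQ[k], start=1):
        f = i / (k + 1)
        p = (1 - f) * start + f * end
        # bow the linker slightly outward from the axis so it is not collinear
        radial = p - axis_point
        radial -= np.dot(radial, backbone.axis.direction) * backbone.axis.direction
        norm = np.linalg.norm(radial)
        if norm > 1e-9:
            p = p + (1.5 * np.sin(np.pi * f)) * radial / norm
        coords.append(p)
        seq.append(aa)
    coords.extend(anchors_post)
    seq.extend(["G", "G", "G"])
    donor = structure_from_ca(np.array(coords), sequence="".join(seq), chain="D",
                              entry_id=f"synthetic_donor_k{k}")
    return donor, ("D", 4, 3 + k)


def _repeat_ranges_of(backbone: symmetry.SymmetricBackbone) -> list[tuple[int, int]]:
    """0-based inclusive spans of the repeats within the full chain."""
    L = len(backbone.repeat)
    m = len(backbone.linker)
    out = []
    pos = 0
    for k in range(backbone.order):
        out.append((pos, pos + L - 1))
        pos += L + (m if k < backbone.order - 1 else 0)
    return out


def run(config: RunConfig) -> RunReport:
    rng_seed = config.seed

    # --- template and repeats ------------------------------------------------
    try:
        template, ranges = _load_template(config)
        repeats = symmetry.extract_repeats(template, symmetry.RepeatDefinition(list(ranges)))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("repeats", str(exc)) from exc
    repeat_coords = [c for c, _ in repeats]
    repeat_seqs = [SequenceRecord(id=lab, residues=s) for lab, (_, s) in zip("ABC", repeats)]
    L = len(repeat_seqs[0].residues)

    # --- ancestral reconstruction -------------------------------------------
    try:
        guide = [(i, i, i) for i in range(L)]  # repeats are equal-length ranges
        alignment = ancestors.align_repeats(repeat_seqs, guide_pairing=guide)
        model = ancestors.make_model(config.model, alignment.frequencies())
        tree = ancestors.infer_tree(alignment, model)
        posterior = ancestors.marginal_posterior(alignment, tree, model)
        candidates = ancestors.sample_candidates(posterior, config.n_candidates, seed=rng_seed)
    except Exception as exc:
        raise StageError("ancestors", str(exc)) from exc

    # --- axis and subdomain choice -------------------------------------------
    try:
        axis = symmetry.fit_c3_axis(repeat_coords)
        sub_objectives: dict[str, float] = {}
        backbones_by_sub: dict[str, symmetry.SymmetricBackbone] = {}
        for label, (coords, seq) in zip("ABC", repeats):
            bb = symmetry.symmetrize((coords, seq), axis, n=3, rigid_search=config.rigid_search)
            ca0 = bb.repeat_ca_coords(0)
            ca1 = bb.repeat_ca_coords(1)
            sub_objectives[label] = symmetry.interface_objective(ca0, ca1)
            backbones_by_sub[label] = bb
        best_sub = min(sub_objectives, key=sub_objectives.get)
        base = backbones_by_sub[best_sub]
    except Exception as exc:
        raise StageError("symmetrize", str(exc)) from exc

    # --- backbone variants ----------------------------------------------------
    variants: dict[str, symmetry.SymmetricBackbone] = {}
    try:
        for k in config.grafts:
            if k == 0:
                bb = symmetry.SymmetricBackbone(
                    repeat=base.repeat, axis=base.axis, order=base.order
                )
                bb.linker = _synthetic_linker(bb, "G")  # single-glycine junctions
                variants["nograft"] = bb
            else:
                if config.donor is not None and config.donor_range is not None:
                    donor = read_pdb(config.donor)
                    donor_range = config.donor_range
                else:
                    donor, donor_range = make_synthetic_donor(base, k)
                variants[f"graft{k}"] = symmetry.graft_linker(base, donor, donor_range, k)
    except Exception as exc:
        raise StageError("graft", str(exc)) from exc

    # --- thread, score, select -----------------------------------------------
    rows: list[dict] = []
    designs: list[threading.ScoredDesign] = []
    template_repeat_ca = np.vstack(repeat_coords)
    try:
        for name, bb in variants.items():
            linker_seq = "".join(r.aa for r in bb.linker)
            bb_repeat_ca = np.vstack([bb.repeat_ca_coords(k) for k in range(bb.order)])
            ca_rmsd = kabsch(bb_repeat_ca, template_repeat_ca).rmsd
            rranges = _repeat_ranges_of(bb)
            ca = bb.ca_coords()
            for ci, cand in enumerate(candidates):
                full = symmetry.concatenate_with_linkers(cand.sequence, linker_seq, n=bb.order)
                feats = threading.thread(ca, full.sequence)
                cav = cavity.cavity_volume_for_design(
                    ca, full.sequence, spacing=config.spacing,
                    small_probe=config.small_probe, large_probe=config.large_probe,
                )
                cav_vol = cav.largest().volume if cav.components else 0.0
                energy = threading.score(feats, config.weights, cavity_volume=cav_vol)
                motifs = threading.motif_check(full.sequence, rranges)
                design = threading.ScoredDesign(
                    candidate_id=f"{name}:cand{ci:05d}",
                    sequence=full.sequence,
                    energy=energy,
                    ca_rmsd=ca_rmsd,
                    cavity_volume=cav_vol,
                    motif_flags=motifs,
                    provenance={"backbone": name, "candidate": ci,
                                "seed": rng_seed, "origin": cand.provenance,
                                "graft": name.replace("graft", "") if "graft" in name else "0"},
                )
                if config.motif_gate == "filter" and not design.motifs_ok:
                    continue
                designs.append(design)
                rows.append(
                    {
                        "id": design.candidate_id,
                        "backbone": name,
                        "candidate": ci,
                        "origin": cand.provenance,
                        "total": energy.total,
                        "contact": energy.contact,
                        "burial": energy.burial,
                        "clash": energy.clash,
                        "cavity_term": energy.cavity,
                        "rmsd": ca_rmsd,
                        "cavity_volume": cav_vol,
                        "motifs_ok": design.motifs_ok,
                        "length": len(full.sequence),
                    }
                )
        if not designs:
            raise ValueError("no designs survived scoring")
        selection = threading.rank_and_select(designs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("threading", str(exc)) from exc

    table = pd.DataFrame(rows).sort_values("total", kind="mergesort").reset_index(drop=True)
    selections = {
        "-1": _row_for(table, selection.by_energy),
        "-2": _row_for(table, selection.by_rmsd),
        "-3": _row_for(table, selection.by_cavity),
    }

    # --- gene design for the winner -------------------------------------------
    gene = None
    try:
        winner = selection.by_energy.sequence
        if winner.startswith("M"):
            gene = genedesign.design_gene(winner, seed=rng_seed)
        else:
            gene = genedesign.design_gene("M" + winner, seed=rng_seed)
    except genedesign.GeneDesignError as exc:
        raise StageError("genedesign", str(exc)) from exc

    report_obj = RunReport(
        table=table,
        selections=selections,
        subdomain_objectives=sub_objectives,
        axis_angle_deg=axis.angle_deg,
        gene=gene,
        provenance={
            "config_hash": config.hash(),
            "seed": rng_seed,
            "best_subdomain": best_sub,
            "n_candidates": config.n_candidates,
            "variants": list(variants),
            "tree_newick": tree.to_newick(),
        },
    )
    if config.outdir:
        _write_outputs(config, report_obj, variants)
    return report_obj


def _row_for(table: pd.DataFrame, design: threading.ScoredDesign) -> dict:
    row = table[table["id"] == design.candidate_id].iloc[0].to_dict()
    row["sequence"] = design.sequence
    return row


def _write_outputs(config: RunConfig, rep: RunReport, variants) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep.table.to_csv(outdir / "candidates.tsv", sep="\t", index=False, float_format="%.6f")
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "selections": {k: _jsonable(v) for k, v in rep.selections.items()},
                "subdomain_objectives": rep.subdomain_objectives,
                "axis_angle_deg": rep.axis_angle_deg,
                "provenance": rep.provenance,
            },
            fh, indent=1,
        )
    for name, bb in variants.items():
        st = bb.to_structure(entry_id=name)
        write_pdb(st, outdir / f"backbone_{name}.pdb",
                  remarks=[f"symmetric backbone variant {name}",
                           f"axis direction {np.round(bb.axis.direction, 4).tolist()}"])
    if rep.gene is not None:
        (outdir / "gene.fasta").write_text(
            f">designed_gene {rep.provenance['config_hash']}\n{rep.gene.construct}\n"
        )
        rep.gene.write_edit_log(outdir / "gene_edits.tsv")


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out


def report(run_dir) -> dict:
    """Summarise a completed run directory: energy-vs-RMSD scatter data,
    motif-gate pass rate, cavity-volume distribution."""
    run_dir = Path(run_dir)
    table_path = run_dir / "candidates.tsv"
    if not table_path.exists():
        raise FileNotFoundError(f"no candidate table in {run_dir}")
    table = pd.read_csv(table_path, sep="\t")
    if table.empty:
        raise ValueError("empty candidate table: nothing to report")
    scatter = table[["id", "total", "rmsd"]]
    scatter.to_csv(run_dir / "scatter.tsv", sep="\t", index=False)
    summary = {
        "n_designs": int(len(table)),
        "motif_pass_rate": float(table["motifs_ok"].mean()),
        "cavity_volume_min": float(table["cavity_volume"].min()),
        "cavity_volume_median": float(table["cavity_volume"].median()),
        "cavity_volume_max": float(table["cavity_volume"].max()),
        "energy_best": float(table["total"].min()),
    }
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
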