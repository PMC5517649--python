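# Methods

This note documents the models, numerical choices and deliberate
simplifications behind each stage of the symmetrisation pipeline, and
what the synthetic fixtures do and do not establish about real data.

## Structure handling

PDB files are parsed with gemmi and held in a small chain → residue →
atom container that preserves file order.  Alternate locations are
resolved by keeping the highest-occupancy copy (ties go to the first
copy in the file).  Waters and HETATM ligands are parsed but excluded
from protein selections by default; the cavity module can include
ligand atoms by flag.  Writing uses a fixed-column formatter so that a
read → write → read cycle preserves coordinates to the 3-decimal PDB
convention.  Insertion codes order after their base residue number.
mmCIF, anisotropic B-factors and crystallographic symmetry mates are
out of scope.

## Superposition

Kabsch superposition is computed by SVD of the cross-covariance with
determinant sign correction; inputs of fewer than 3 points or with a
rank-deficient (collinear) configuration are rejected.  The trimmed
variant iterates fit → drop pairs beyond a cutoff (default 3.5 Å, a
conventional Cα-equivalence threshold; at most 20 iterations).  To stop
gross outliers from skewing early fits and dragging sound pairs over
the cutoff, at most the worst 10% of retained pairs are dropped per
iteration; the retained set never grows, and the final RMSD never
exceeds the untrimmed one.

Structure-guided percent identity pairs residues one-to-one (sequence
order preserving) whenever their Cα atoms lie within a cutoff after a
trimmed superposition seeded by a global sequence alignment (BLOSUM62,
affine gaps 10/0.5).  The pairing maximises summed (cutoff − distance)
by dynamic programming, so ties resolve toward the smaller distance.
The identity denominator is the number of structurally paired
positions, not the full sequence length — the convention used when
identities are quoted from structure-based alignments.

## Axis fitting and symmetrisation

The pseudo-C3 axis is fitted from the A→B and B→C Kabsch rotations:
quaternions are sign-aligned and averaged, the axis is the mean
rotation's axis, and the rotation used downstream is the projection to
an exact 120° turn about that axis (the pre-projection mean angle is
reported; a mean outside 120° ± 40° is rejected as not threefold).  The
axis point is the mean of the minimum-norm fixed points of the two
screw transforms.

Symmetrisation replicates one repeat at exact 2π/3 rotations.  An
optional rigid-body search refines the repeat placement on a grid —
spin about the axis in 1° steps over [0°, 120°), axial and radial
offsets ±3 Å in 0.25 Å steps — scored by a coarse interface objective
(soft-sphere clash weight 10 on Cα pairs closer than 4 Å, minus the
count of 4–8 Å contacts).  This axis-based construction is this
package's own documented replacement for symmetric docking with an
all-atom design suite: it reproduces the intent (a symmetric trefoil
assembly built from one subdomain, ranked by packing) at desk scale and
makes no claim of equivalence to any all-atom protocol.  A minimum
inter-unit Cα distance below 2.5 Å at the optimum is a hard packing
error.  Only one subdomain is symmetrised per run; running all three
and comparing interface objectives reproduces the template-choice step.

Junctions: repeats are concatenated with either single-glycine inserts
(47 × 3 + 2 = 143 residues, glycines at positions 48 and 96) or
Gly-Asp-Gly tripeptides (147 residues).  Both published junction
schemes are implemented; the numbering map is a bijection onto
1..total_length.  Grafting replaces the junction with k ∈ {6, 9} donor
residues positioned by Kabsch superposition of 3-residue anchors on
each side (anchor RMSD above 1.5 Å is a graft error); the graft lives
in the asymmetric unit, so all junctions carry it identically and exact
symmetry is preserved by construction.  Which donor residues constitute
the linker is a required user input; when no donor structure is
supplied, the pipeline builds a synthetic donor (anchor geometry copied
from the host, k arc-placed residues between them — the 9-residue
version carries a core tryptophan as a donor-trefoil linker would).

Backbone regularisation is plain gradient descent (backtracking step
control, so the objective trace is non-increasing) on ideal bond
lengths (N–CA 1.458, CA–C 1.525, C–N 1.329, C–O 1.231 Å), the N–CA–C
angle (111.2°), and a soft-sphere clash term below 3 Å.  After
minimising the full chain, each unit is mapped back to the template
frame and averaged, re-imposing exact symmetry.

## Ancestral reconstruction

The three repeat sequences are leaves of a rooted 3-leaf star tree (the
only internal node of an unrooted 3-leaf tree, which is where the
symmetric ancestor lives).  Likelihoods use Felsenstein pruning;
transition matrices P(t) = exp(Qt) come from the symmetric
eigendecomposition of the similarity-transformed generator, exact for
reversible models.  Gaps and unknown residues are missing data
(all-ones conditionals).  Branch lengths are fitted by cyclic
golden-section/bounded scalar maximisation to a 1e-6 log-likelihood
tolerance.  Per-site marginal root posteriors give the MAP ancestor and
the sampled candidate pool (sites independent; joint reconstruction is
a documented non-goal).  The candidate pool size defaults to 2000.

Model choice: the default reversible model uses exchangeabilities
derived from BLOSUM62 target frequencies, S_ij = 2^(s_ij/2) (the scores
are scaled log-odds of pair frequencies over products of marginals, so
this recovers relative pair propensities), with equilibrium frequencies
estimated from the alignment (+1 pseudocount).  A uniform-
exchangeability (Poisson-type) model is built in and any PAML-format
empirical rate file can be loaded; no empirical .dat tables are shipped
because none are redistributable from the installed toolchain.  No
among-site rate heterogeneity is modelled.  Simulation and inference in
the test suite use the same model family, so recovery results certify
the estimator, not robustness to model misspecification.

## Threading and the coarse energy

Candidates are threaded rigidly: the backbone does not move per
sequence.  Features per residue: neighbour count (other Cα within
10 Å), and contacts between pseudo-Cβ centres within 8 Å at sequence
separation ≥ 2.  The pseudo-Cβ sits 1.5 Å from the Cα along the local
side-chain direction (away from the midpoint of the flanking Cα);
glycine and chain termini use the Cα itself.

Energy terms (lower is better; total = weighted sum, default weights
contact 1.0, burial 1.0, clash 10.0, cavity 0.05/Å³):

- **contact** — a packaged 20×20 matrix constructed from the
  Kyte–Doolittle hydropathy scale via the one-body dominance
  approximation for contact potentials, e(a,b) = −0.1·(KD(a)+KD(b));
  hydrophobic pairs favourable, charged/polar pairs penalised.
- **burial** — −Σ h(aᵢ)·nᵢ with h the Kyte–Doolittle value shifted so
  glycine is exactly 0 (scaled ×0.1), rewarding buried hydrophobics.
- **clash** — Σ (4 − d)² over Cα pairs closer than 4 Å at separation ≥ 2.
- **cavity** — the internal cavity volume of the threaded model.

Because threading is rigid, the Cα RMSD to the natural template varies
across backbone variants but not across candidates within one variant;
the RMSD-best ("-2") selection therefore distinguishes backbones, with
ties broken by energy then cavity then candidate id.  This is a
deliberate simplification — the original procedure relaxed each model,
so its RMSD spread per backbone is not reproduced.  Ranking agreement
with any all-atom score is a non-goal; the tested surface is selection
logic, symmetry behaviour (identical per-repeat energies on symmetric
inputs, up to the chain-terminus closure contact) and the motif gates.

Motif gates search each repeat for HxDxH and HPxGG, the
galactose-binding fingerprints of the MytiLec lectin family.  The
default gate flags rather than filters, because in the original
procedure the motifs were retained by the ancestral reconstruction
itself, not enforced.

## Cavity detection

Dual-probe grid algorithm: voxels within (vdW + 1.4 Å) of any atom are
protein; the bulk is the volume swept by 4.0 Å probe spheres whose
centres flood in from the box boundary through the probe-accessible
region (computed with a Euclidean distance transform); cavities are the
rest, 6-connected, with components under 5 Å³ discarded.  Default
spacing 0.6 Å; per-element vdW radii C 1.70, N 1.55, O 1.52, S 1.80 Å.
For Cα-only design models each residue is one sphere with radius
(3V/4π)^⅓ from standard residue volumes.  On the hollow-shell fixture
the measured volume is within ~1% of the analytic value at 0.6 Å
spacing.  A cavity survives until an aperture wider than the large-probe
diameter (~11.4 Å for carbon shells) opens; small perforations do not
leak, which is the intended dual-probe behaviour.

## Gene design

Backtranslation uses a packaged E. coli K-12 codon-usage table
(rounded fractions of the standard usage compilations; any table in the
same TSV format can substitute).  Mode "max" takes the most frequent
codon (ties alphabetical); mode "sample" draws per the fractions under
an explicit seed.  The construct is CAT + coding + CTCGAG: the NdeI
site CATATG is completed by the initiator-methionine ATG, and the XhoI
site follows the final codon.  Internal occurrences of either site (on
either strand) are removed by minimal silent codon swaps, preferring
the highest-frequency alternative.  "Self-annealing" is operationalised
as an exact reverse-complement match of length ≥ 10 between any two
segments of the construct (configurable); repair swaps one overlapping
codon to its next-most-frequent synonym, iterating to a fixpoint, and
warns (rather than fails) if single-codon amino acids make a stem
unbreakable.  Every edit is logged and every output re-translated and
checked.  mRNA folding energies, codon-pair bias and GC optimisation
are out of scope.

## Synthetic fixtures

`make_c3_backbone` builds each repeat as a four-strand serpentine Cα
trace (3.8 Å spacing along strands, 4.8 Å strand separation), standing
the sheet parallel to the z-axis at a 7 Å radial offset — chosen so
adjacent repeats form 4–8 Å contacts without clashing, like packed
trefoil subdomains — and replicates it at exact 120° rotations, with
optional per-atom Gaussian noise.  It does not reproduce β-sheet
hydrogen-bonding geometry, side chains, or realistic loops, so passing
tests certify the geometry and bookkeeping of the pipeline, not its
behaviour on real folds.  Under noise σ applied to all atoms, matched
atoms of two repeats differ by the difference of two isotropic
Gaussians, E[RMSD²] = 6σ², so the expected pairwise repeat RMSD is
≈ σ√6 (slightly less after refitting) — the band asserted in the tests.

`evolve` samples substitutions per site from P(t) along each branch;
the root generator and the substitution sampler use separate derived
random streams so sharing one seed cannot correlate them.  `make_shell`
tiles a sphere with a Fibonacci lattice dense enough that the maximum
gap is ≤ 1 Å (refusing to build an unsealed shell) and records the
analytic cavity volume (4/3)π(r_inner − r_probe)³ in the metadata.

## Problem sizes and determinism

The validation suite and acceptance script use 47-residue repeats,
120–200-site alignments, 20-seed replicate sets, and a 50-candidate
design pool — sizes chosen so every stage's statistical check is
well-powered while a full run stays in the minutes range on one CPU.
The pipeline's `RunConfig` default remains 2000 candidates.  Every
stochastic step takes an explicit integer seed (default 1), and a rerun
with the same config and seed reproduces the candidate table
byte-for-byte.

## Known limitations

- Coarse energies are not transferable to real stability prediction;
  they order candidates by packing plausibility only.
- Rigid threading collapses the per-candidate RMSD spread (above).
- The star-tree ancestral machinery is specialised to three repeats;
  topology search and rate heterogeneity are absent by design.
- Structure-guided identity depends on the trimming cutoff near 3–4 Å;
  values within a point or two of an external program's structure-based
  alignment are expected, not exact agreement.
- The synthetic template's repeats diverge under the same model used
  for inference; no model-misspecification stress test is included.
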