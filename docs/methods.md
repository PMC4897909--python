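# Methods

`rbres` predicts which residues of a protein structure bind RNA. It
combines two structural descriptors built from first principles — a
residue electrostatic surface potential with density-clustered charged
surface patches, and a four-subtype triplet interface propensity with
secondary-structure weighting — with three standard descriptor families
(PSSM profile, surface geometry, physicochemical indices) in a
patch-expanded per-residue encoding classified by a random forest.

## Binding definition

A residue is RNA-binding when one of its heavy atoms lies within a
distance cutoff of any RNA atom. The default cutoff is 5.0 Å; 3.5 Å is
the stricter alternative used for low-redundancy evaluation. Labels at
3.5 Å are by construction a subset of those at 5 Å, and the test suite
enforces this monotonicity. Hydrogens never count as contact atoms, even
when present (e.g. after PQR protonation).

## Surface model

All surface quantities derive from a single accessible dot surface:
quasi-uniform candidate points (golden-spiral lattice, 320 per atom by
default) on each heavy atom's probe-expanded sphere (probe 1.4 Å), a
point being retained when it lies outside every other atom's expanded
sphere. This yields, per atom, the retained count N_i — the bookkeeping
unit for residue representative points — and the accessible surface area
ASA = (retained/candidate) · 4π(r+probe)². Hydrogens are excluded from
surface generation; RNA atoms never occlude the protein surface, so apo
and bound forms of the same coordinates annotate identically.

Relative solvent accessibility is reported in five categories (all,
side-chain, main-chain, non-polar side, polar side; polar = N/O/S atoms),
each normalized by the same category's area in an extended Ala-X-Ala
conformer *computed with the same dot-surface routine*. Self-consistency
is the point: a residue in the reference geometry scores exactly 100 %.
Because the reference conformers use the package's idealized side-chain
geometry, RSA values on real crystallographic side chains are
approximate in absolute terms (they can exceed 100 %); all downstream
uses are threshold- or rank-based, which this does not disturb.
Glycine's side-chain categories are defined as 0.

The CX protrusion descriptor counts heavy atoms inside a 10 Å sphere
around each atom, converts to occupied volume with a mean atomic volume
of 20.1 Å³, and forms V_ext/V_int. The raw ratio is strictly positive,
so atom values are mean-centered per complex before applying the
dented (< −0.5) / intermediate / protruded (> 0.5) thresholds; a residue
sums the centered values of its atoms with ASA > 1 Å², and a residue
with no such atom is buried (class 3, a separate categorical level).

## Electrostatic descriptor

The potential at a surface point F is a bare Coulomb sum over protein
atoms within 7 Å, with a distance-dependent dielectric ε = d, so each
atom contributes q/d². Distances are floored at 0.1 Å to bound the sum
when a charged atom coincides with a surface point. No solvent or ion
model is used — the descriptor is deliberately this simple. Per-atom
potentials average over the atom's retained dots; per-residue potentials
V_r average over the residue's surfaced atoms; unsurfaced residues have
V_r = 0.

Charges come from a PQR file when supplied (the high-fidelity path,
covering protonated structures) or from a built-in PARSE-style table:
backbone N −0.40 / C +0.55 / O −0.55 (with the amide hydrogen's +0.40
folded into N whenever the structure carries no hydrogens, keeping the
backbone net-neutral in heavy-atom-only models) and formal side-chain
charges on the terminal heavy atoms (Lys NZ +1, Arg NH1/NH2 +0.5 each,
Asp/Glu carboxylate oxygens −0.5 each). Atoms outside the table are
neutral.

Each surfaced residue is reduced to one point, the N_i-weighted centroid
of its atom coordinates. Residues with V_r > 0 (and, independently,
V_r < 0) are clustered per chain with DBSCAN at ε = 7 Å and minPts = 3,
the neighbor count including the point itself: the parameter choice
reflects the observation that a charged surface residue typically has
about two like-signed neighbors within 7 Å, i.e. three points counting
itself. The max-cardinality cluster on each side is the largest
positive (negative) patch; ties break toward the cluster containing the
smallest residue index, and points are always presented in residue
order, making border-point assignment deterministic. The 3-vector
descriptor is (V_r, in-largest-positive, in-largest-negative), all-zero
for unsurfaced residues.

## Triplet interface propensity

A surface triplet is a window of three consecutive residues (no chain
break; a break is an author-numbering gap > 1) whose all-atom RSA each
exceeds 3 %. An interface triplet additionally has an RNA-binding
center; its subtype (1–4) records which flanks also bind. For triplet
type x, subtype k and training chain p,

    R_xk = Σ_p f_{x,p,k} · ln( f_{x,p,k} / f_{x',p} )

with f_{x,p,k} = N_{x,k}/N_all (the fraction of p's RNA-contacting heavy
atoms inside subtype-k instances of x, contacts counted over all three
residues of each instance, each instance counted independently) and
f_{x',p} = T_x/T_all (x's share of p's surface triplets). Chains where x
is absent contribute zero (the f·ln f limit). The secondary-structure
propensity pools over chains:

    I_{x,s} = Σ_p #(interface x, center state s) / Σ_p #(surface x, any state)

using the DSSP 8→3 state collapse (I/G/H → helix, E/B → sheet, rest →
coil), so I_{x,s} ∈ [0,1] and Σ_s I_{x,s} ≤ 1. The per-residue feature is
(I_{x,s}·R_x1, …, I_{x,s}·R_x4) with s the center's state, and zero for
windows that are not surface triplets, cross termini/breaks, or are
unseen in the table. Prediction-time lookups use only the query's RSA
and secondary structure — never its labels; the leakage test encodes the
same coordinates with and without RNA and requires identical matrices.

When no DSSP file is supplied, a torsion-based fallback assigns the
3-state class directly from backbone φ/ψ (helix: φ ∈ (−120°, −30°),
ψ ∈ (−90°, −5°); sheet: φ ∈ (−180°, −90°], ψ > 90° or ψ < −150°; else
coil). Termini and break-adjacent residues are coil.

## PSSM and physicochemical blocks

PSSM profiles are consumed from the standard ASCII layout (first 20
log-odds columns), with rows for residues missing from the structure
dropped by subsequence alignment. The profile search itself is outside
this package; without a profile, a substitution-matrix fallback
(BLOSUM62 row per residue type) is used and flagged in metadata. Scores
are used raw.

The physicochemical block is a 10-value residue-type embedding keyed by
AAindex identifiers, min-max scaled per index over the 20 types. Two
rows (WOEC730101 polar requirement, COSI940101 electron-ion interaction
potential) are transcribed from the published scales; the other eight
are synthetic stand-ins representing the same property classes (see the
`physchem` module docstring). Since the block functions as a generic
scaled embedding, results at desk scale do not depend on the literal
values; reproducing published large-scale numbers would require the
database rows.

## Encoding

Per-residue blocks are electrostatic (3), triplet (4), PSSM (20),
geometry (6 = five RSA + shape class) and physicochemical (10). Each
block is expanded over its own patch: the center residue plus its s−1
nearest neighbors along the sequence (sequential) or by Cα–Cα distance
(structural). Default sizes are 11, 7, 5, 5, 9, giving 3·11 + 4·7 +
20·5 + 6·5 + 10·9 = 281 features. The optimal per-block patch *types*
are not published; the defaults here are structural for the spatial
descriptors (electrostatic, triplet, geometry) and sequential for the
profile/identity descriptors (PSSM, physicochemical), fully
configurable and recorded in output metadata. Patches truncated by
chain ends fill from the available side; chains shorter than s zero-pad
the missing slots, keeping the vector length fixed. Structural patches
use the Cα position (total, unlike the surface-weighted point, which is
undefined for buried residues).

## Classifier and evaluation

The classifier is a random forest with 500 trees and √d candidate
variables per split — the cited implementation's defaults — exposed as a
scikit-learn estimator with a fixed seed for bit-reproducible folds and
predictions; impurity-based feature importances are stored at fit time
and permutation importances are available on demand. Evaluation uses
SN, SP, PPV, ACC, F1 and MCC in their standard forms plus trapezoidal
ROC AUC; zero-denominator ratios report 0 with a degenerate flag.
Cross-validation partitions residues at random into five near-equal
folds (the protocol's stated unit); a chain-grouped mode exists for
stricter evaluation, and both pooled (micro) and fold-averaged (macro)
summaries are reported, pooled being the default. The ablation protocol
re-runs CV with each block removed and with each block alone.

## Synthetic study data

The fixture generator builds idealized complexes so the entire pipeline
is testable without downloads: NeRF backbones at ideal bond geometry
with per-fold (φ, ψ) (α-helix −57/−47, strand −139/135, irregular
non-reentrant coil), pseudo side chains carrying each residue type's
real heavy-atom names on a zig-zag pointing away from the local backbone
centroid, and a pseudo-RNA strand (P/C4'/N1 per nucleotide) placed 4.7 Å
beyond the side-chain tip of each designated contact residue. Generation
verifies two guarantees and raises otherwise: contact residues lie
within the 5 Å labeling cutoff and all other residues beyond 8 Å, so
ground-truth labels equal the designated face exactly. Helix side chains
use a compact 0.6 Å/bond step so that adjacent surface residues stay
within the 7 Å clustering radius, as they do on real packed surfaces;
extended folds use 1.1 Å/bond. Sequence draws place short residues in a
buffer flanking the face so the clearance guarantee is satisfiable on
any fold.

The planted multi-chain datasets (16 chains × 60 residues by default, a
12-residue contact face each, one pseudo-nucleotide per contact residue)
come in two flavors. The composition-biased flavor draws faces from
K/R/Q and plants the KRG triplet at the face boundary, so electrostatics,
triplet propensity and residue identity all carry real signal. The
identity-neutral flavor draws every position uniformly from K/E/Q/M and
instead adds an explicit +1.5 charge on the contact side-chain tips, so
*only* the electrostatic block is informative — the construction behind
the ablation check. Chains that violate the geometric guarantees are
redrawn deterministically, so every seed generates.

What passing these tests shows — and does not. The synthetic data
exercise every code path end to end and verify that planted signal of
each kind is recovered: cross-validated AUC ≥ 0.95 with signal, ≈ 0.5
with shuffled labels, the planted triplet ranked above the background
propensity median, a majority of contact residues inside the largest
positive patch, and the electrostatic block the most damaging to ablate
on the identity-neutral data. They do not certify performance on real
crystallographic complexes, whose side-chain packing, charge detail,
profile information and label noise the toys deliberately idealize;
reproducing the published large-scale numbers requires the full PDB
datasets and NR-derived PSSMs (see `reproduce/`).

## Numerical choices and degenerate inputs

- Dot counts: 320/atom default; the two-sphere occlusion test holds the
  dot-count ASA to < 2 % of the analytic spherical cap at 960 dots.
  RSA is rotation-invariant only to dot-sampling tolerance.
- Potential floor 0.1 Å; potentials are exactly linear in the charges,
  and charge negation exactly swaps the positive/negative patch roles.
- DBSCAN is matched against a brute-force ε-graph
  connected-components oracle (cores and noise must agree exactly;
  border points may attach to any neighboring cluster).
- Unseen triplets are absent from the table and look up as zeros;
  chains with no surface triplets are skipped with a warning; an empty
  training set is an error.
- First altloc kept; waters stripped; nonstandard residues become 'X'
  (physicochemical block: per-index mean; RSA: generic reference).
- Problem sizes in the shipped tests and the acceptance script (16
  chains of 60 residues, 5-fold CV, 500 trees) were chosen so the whole
  pipeline, including the 11-row ablation, completes in a few minutes on
  one CPU.

## Known limitations

- The built-in charge table is a simplified PARSE-style assignment;
  quantitative potentials on real structures should use PDB2PQR output
  via the PQR path.
- Eight of the ten physicochemical rows are synthetic stand-ins (see
  above).
- RSA references derive from idealized side-chain geometry.
- mmCIF input, sequence-database searches, and modeling of missing
  residues are out of scope; structures are used as given.
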