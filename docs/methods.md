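# Methods

This note records the models behind each analysis stage, the parameters
that matter, the numerical choices, and what the synthetic fixtures do and
do not establish about behaviour on real structures.

## Structure model and preparation

A structure is an ordered list of atoms with author residue numbering; all
cross-structure bookkeeping is by author residue number, which is shared
across the C5 depositions. Alternate locations are resolved at parse time
to the highest-occupancy conformer, ties broken to the lexicographically
first altloc identifier — the common convention, adopted because nothing
downstream can use more than one conformer. Insertion-coded residues are
excluded from CA matching so residue number remains a unique key.

Preparation keeps the chains of one copy of the molecule and removes
waters and all HETATM records (ligands, ions and N-linked glycans) by
default; `keep_glycans` retains sugar residues for surface-area runs where
that is wanted. For multi-copy asymmetric units, `infer_c5_chains` keeps
the copy containing the alphabetically first chain spanning the β-chain
range (20–565) and greedily adds non-overlapping chains covering the rest
of 20–1676. The 13-domain map (MG1–MG8, linker, C5a, CUB, C5d, C345C;
MG6 and CUB discontinuous) ships as a constant and as a plain-text config
format (`NAME start-end[,start-end]`).

## Domain displacement

Superposition is the Kabsch closed form; reflections are excluded by
flipping the sign of the smallest singular vector when det < 0, and point
sets with collinear rank are rejected (the rotation would not be unique).
After fitting the reference domain, the transform is applied to *all* CA
atoms so targets and angle vertex live in one frame.

The rotation angle needs a vertex: the centre of the superimposed
reference domain, which exists in two near-identical copies (apo, and the
transformed complex, differing by at most the fit RMSD). The default is
the apo copy — apo is the fixed frame for every comparison — with a
`vertex="complex"` switch; with an exact fit the two are identical, and a
test asserts the difference vanishes on noise-free fixtures. Vectors
shorter than 1e-6 Å make the angle ill-defined; such records report 0°
with a `degenerate` flag. Domains with fewer than 3 matched CA in either
structure are dropped pairwise, which is how unresolved C345C domains are
handled. Self-entries (the diagonal) are excluded; internally the
reference's own centre shift is asserted to be ≤ 2 × fit RMSD.

## Interface areas

SASA is Shrake–Rupley with a golden-section-spiral point lattice
(default 960 points/atom), which makes results bit-stable across runs —
there is no random orientation anywhere. Probe radius 1.4 Å; element
radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å (NACCESS/Chothia-flavoured);
hydrogens excluded by default because deposited crystal structures rarely
have them.

Buried area between domains A and B is computed with *only those two
domains present* (the chain-pair convention of interface servers), as
SASA(A) + SASA(B) − SASA(A∪B), i.e. the sum of both partners' losses.
Interface servers often headline the half-sum; `half_sum=True` switches.
The sum-rule identity holds exactly by construction, and doubling the
point count moves any reported area by < 1 % on the test fixtures. The
quadrature lattice is not inversion-symmetric, so exactly mirror-symmetric
pairs bury equal areas only up to quadrature error (~1 %).

## Loop geometry

φ/ψ follow the IUPAC sign convention; φ is undefined at a segment start
and ψ at a segment end, with unmodelled residues producing no record and
breaking helical runs. Ramachandran regions are rectangles: α is
φ∈[−100°, −30°] × ψ∈[−80°, −5°]; β is φ∈[−180°, −45°] with
ψ∈[90°, 180°] ∪ [−180°, −150°] (a broad box that includes polyproline);
everything else, including the left-handed helical region, is `other`.
The boxes are a deliberate, configurable approximation of contour-based
validators: they admit canonical helix (−57, −47) and strand (−120, 120)
and are disjoint so classification is total and unambiguous. A loop is
helical when ≥ `min_run` = 4 consecutive modelled residues classify α —
long enough to exclude isolated turns over a 9-residue window, short
enough to tolerate fraying ends.

Polar contacts are distance-only (N/O/S heavy-atom pairs ≤ 3.5 Å, the
usual molecular-viewer default) because deposited structures lack
hydrogens; salt bridges pair Arg NH1/NH2/NE, Lys NZ and His ND1/NE2
against Asp OD1/OD2 and Glu OE1/OE2 at ≤ 4.0 Å. His is counted as
potentially charged — a generous default, visible in the output kind.

## Rigidity

**Network.** Atoms are 6-DOF rigid bodies. Covalent topology comes from
residue templates for the 20 standard amino acids plus geometric rules
(peptide C–N < 1.7 Å, disulfide SG–SG < 2.3 Å, hydrogens to the nearest
heavy atom ≤ 1.35 Å, and a covalent-radius fallback for non-template
atoms). Bars: 6 for locked bonds (peptide bonds, carbonyls, carboxylate /
amide / guanidinium / imidazole / aromatic-ring template bonds), 5 for
rotatable covalent bonds and hydrogen bonds (the bar is placed on the
H···acceptor pair), 2 for hydrophobic tethers (side-chain C/S atoms whose
covalent neighbours are all C/S/H, within vdW sum + 0.25 Å, excluding
bonded and 1-3 pairs).

**Hydrogen-bond energies.** Mayo-style:
E = V₀[5(d₀/d)¹² − 6(d₀/d)¹⁰]·F with V₀ = 8 kcal/mol, d₀ = 2.8 Å and d
the donor–acceptor distance, so E(d₀, F=1) = −8 exactly. The angular
factor is cos²θ·exp(−(π−θ)⁶) times cos²φ (sp2-involving pairs) or
cos²(φ−109.5°) (sp3–sp3), clipped to [0, 1] and zero for θ < 90°; θ is
the D–H···A angle and φ the H···A–base angle (180° when the acceptor has
no base). The out-of-plane γ term of the full sp2–sp2 form is omitted —
only backbone geometry is protonated here, and the simplification is
uniform across the dilution series it thresholds. Candidate geometry:
D···A ≤ 3.6 Å and θ ≥ 100°.

**Salt bridges** are treated as strong interactions that survive every
cut-off (disable with `keep_salt_bridges=False`). They are detected both
through the H-bond route and directly from heavy atoms (basic N vs
carboxylate O ≤ 4.0 Å) with a fixed energy of −10 kcal/mol, so they work
on structures with backbone-only protonation.

**Protonation.** `place_backbone_hydrogens` adds idealised amide
hydrogens only: N–H = 1.01 Å, anti to the preceding carbonyl, in the
peptide plane; prolines and chain starts are skipped and existing
hydrogens left untouched. Side-chain donors therefore contribute no
H-mediated bonds unless the input is pre-protonated externally — a stated
fidelity limit: backbone networks (secondary structure) are captured,
side-chain H-bond networks only via the salt-bridge rule.

**Pebble game.** The (6,6) body-bar game: each body holds 6 pebbles; a
bar is independent iff 7 pebbles can be gathered onto its endpoints
(6 cover the trivial motions of the pair), pinning one pebble on a
directed edge; pebbles are recovered by reversing directed paths. Rigid
clusters: for a seed pair on which the gather caps at 6, the cluster is
the set of bodies whose only reachable free pebbles sit on the seed pair
(computed by one reverse reachability sweep); seeds probe direct
neighbours first, then the rest of the connected component, so bodies
rigid to a seed through indirect bracing are still found. Edges are
processed in a canonical sort, making the decomposition independent of
input order (the independent/redundant labelling of individual bars is
order-dependent; the cluster partition and independent count are not —
both are matroid invariants). Correctness is checked against an
independent oracle: the rank of the generic body-bar rigidity matrix
(random bar attachment points; a pair is mutually rigid iff adding six
generic welding bars leaves the rank unchanged), with exact agreement of
counts and partitions required on 200 random frameworks of ≤ 8 bodies.

**Dilution and reporting.** Decompositions at −0.5, −1.0, −1.5, −2.0
kcal/mol (geometry analysed once, bonds re-thresholded per cut-off).
Per-domain rigidity is the percentage of the domain's CA atoms inside the
twenty largest clusters *of the whole structure* at that cut-off (the
top-20-per-structure reading), colour-classed grey (0 %), light blue
(1–49 %), purple (≥ 50 %). Atoms in no multi-atom cluster are flexible
singletons and never count toward rigidity. Note that per-domain
monotonicity along the dilution is asserted empirically, not guaranteed
a priori: cluster refinement can in principle promote a previously
rank-21+ cluster into the top 20. On every fixture processed the series
is monotone, and a violation fails the test suite loudly.

## Synthetic data: what it shows and what it does not

The multi-domain toys use compact ideal-helix backbone blobs (so
per-domain superposition is well-conditioned) at non-collinear centres
~25–50 Å apart — domain-scale geometry similar to a multi-domain plasma
protein — with per-domain rigid transforms of ~20–35° and a few Å, the
magnitude of the larger real domain motions. Ground truth is closed-form
from the applied affine maps, never from the module under test. Ideal
peptides have exact (φ, ψ) everywhere and perfect amide geometry; real
loops have distortion, so the 0.5° round-trip tolerance tests the
extractor, not crystallographic reality. Frameworks are generic by
construction (random positions), matching the genericity assumption of
combinatorial rigidity. Passing tests therefore establish algorithmic
correctness and internal consistency; they do not calibrate against
experimental variability (resolution-dependent H-bond detection,
crystal contacts, unmodelled side-chain protons).

**Noise bound.** For toys with coordinate noise σ, the recovery bound on
each displacement record is the first-order 3σ propagation
3σ·sqrt(3/N_tgt + 3/N_ref + L²·Σ_pairs 1/(s_i+s_j)), where s are the
eigenvalues of the reference-domain CA second-moment matrix and L the
lever arm to the target centre: the fit's rotational noise (variance
σ²/(s_i+s_j) per principal axis) dominates through the lever arm, and a
naive 3σ/√N underestimates the error by an order of magnitude at these
geometries. The rotation-angle bound divides by the vertex–target
distance. At σ = 0.2 Å the observed worst-case error over the 50 seeded
instances is ~0.7× (translation) and ~0.9× (rotation) of the bound.

## Problem sizes

The test suite and the acceptance script run on one CPU in well under a
minute: 50 + 50 three-domain toys (20 residues/domain), 200 random
frameworks of ≤ 8 bodies, 12–16-residue peptides, 960-point SASA lattices
(up to 20 000 points in convergence checks). These sizes were chosen so
the property checks are exhaustive where it matters (exact oracle
agreement) while each individual computation stays near-instant; the same
code paths scale to full ~13 000-atom structures, where the pairwise
cluster labelling is the slowest step (minutes per dilution series).

## Known limitations

- Backbone-only protonation understates side-chain hydrogen-bond density;
  rigidity percentages on real structures are sensitive to the
  protonation source and the salt-bridge convention (both exposed flags).
- Interface areas depend on the convention (sum vs half-sum) and on
  whether glycans are retained; both are flags, neither default is
  claimed to match any specific external server's headline number.
- The Ramachandran boxes approximate contour-based validators; residues
  near box edges can flip class relative to such tools.
- No screw-axis/hinge decomposition, no flexible-motion generation, no
  normal modes; the displacement matrices describe rigid-body geometry
  only.
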