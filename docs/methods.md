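# Methods

## Structure model

A chain is a dense 0-based list of standard amino-acid residues, heavy atoms
only. Hydrogens are dropped even when present (most crystal structures lack
them; keeping them would make contact areas incomparable across inputs).
AltLoc duplicates keep the highest-occupancy conformer (first in file on
ties); an atom name duplicated *without* altLoc codes is treated as a broken
record and rejected. Common modified residues (MSE, SEP, PTR, …) are renamed
to their parent; other HET groups, waters and ligands are ignored. Only the
first model of an NMR ensemble is read. Chain breaks are not padded: residue
indices stay consecutive in file order, which is what the sequence-separation
weights below operate on.

Van der Waals radii come from a single published heavy-atom set
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, default 1.70 Å). The source data
never pins a radius set; contact areas shift by a few percent if a different
set is substituted, uniformly enough that alignments are unaffected in
practice. The set is config, not code.

## Surface and contact areas

Each residue is meshed **alone**: its density field sums quadratic kernels
over its own atoms only, and the `f(x)=1` isosurface is triangulated by
marching cubes (`skimage`) on a voxel grid (default 1.0 Å) whose origin is
the residue's padded bounding-box minimum — not a global lattice. Because
neighbouring residues do not carve into each other, buried interfaces carry
full surface, which is precisely what makes inter-residue contact areas
large and informative.

Two residues are in contact where their meshes approach within the cutoff
(default 2.8 Å). Operationally: a triangle of residue *l* is a contact
triangle with *m* iff its **centroid** lies within the cutoff of the nearest
**vertex** of *m*'s mesh (k-d tree query); `a[l][m]` sums contact-triangle
areas on both meshes, so the matrix is symmetric by construction. The
centroid-vs-vertex choice is one of several defensible readings of
"surface-to-surface distance"; it is cheap, and the test suite pins the
semantics with an exhaustive no-index oracle so it cannot drift silently.

The total contact area `T` counts each unordered residue pair once. Whether
pairs are counted once or twice only rescales `NormS` globally; the choice
is fixed in config and stated here.

Numerical behaviour worth knowing:

* a single atom's mesh area converges to `4πr²` from below as the voxel
  shrinks (≈ 8.7% low at 1.0 Å, < 1% at 0.5 Å);
* rigid motions perturb individual areas only at grid-discretisation level;
  the guaranteed envelope (tested) is 10% relative or 2 Å² absolute per
  entry, whichever is larger;
* enlarging the cutoff never decreases any entry.

Contact matrices can be cached to a sparse `l m area` TSV whose header
records voxel, smoothness, cutoff and a radius-table hash, so a cached
precalculation is never silently reused with different parameters.

## Seed generation

Local similarity uses the unit-vector RMS (URMS) between heptapeptide
windows: the six successive CA→CA unit vectors of each window are optimally
rotated onto each other (SVD), and the residual RMS is compared with the
random-heptapeptide expectation 0.917. Score matrix entries are
`10·(0.917 − URMS)/0.917`, clamped at 0; entry (l, m) scores the windows
*starting* at l and m, so the last six rows/columns are zero. (Centred
anchoring would be an equally valid reading; the choice only translates the
seed diagonals and is absorbed by the DP stage.)

Smith–Waterman with affine gap cost `g(k) = α + β(k−1)` is swept over
α ∈ {0, 5, …, 50}, β ∈ {0, 2, …, 10} with α ≥ β — 58 combinations. Each
yields one optimal and four suboptimal alignments, the suboptimals obtained
by cumulatively damping just-aligned score cells by 10% and re-running:
290 local seeds. Each is then refined by the TM-score heuristic — superpose
on the current pairs (Kabsch), rebuild `s(i,j) = 1/(1 + d²/d0²)` with the
standard length-dependent `d0 = max(0.5, 1.24·∛(L−15) − 1.8)`, re-align by
*global* DP with free end gaps and penalties (0.6, 0) — until an alignment
repeats or 20 rounds pass: 580 seeds total, de-duplicated by exact pair-list
identity before optimisation.

Traceback ties break deterministically (diagonal, then vertical, then
horizontal), and nothing in the pipeline draws random numbers, so identical
inputs give identical output, bit for bit.

A caveat discovered while validating the TM refinement: an ideal α-helix has
a screw symmetry, so a one-residue-shifted alignment of a helix onto a rigid
copy of itself is a *legitimate* superposition optimum, and the refinement
correctly stays there. Convergence-to-identity oracles therefore use
irregular (random-coil) traces.

## Contact-area scoring and iterative DP

The per-pair term for aligned pairs *i*, *j* is
`θ(i,j) = w_ij · (max(0, a^A − δ) + max(0, a^B − δ))` with
`δ = |a^A − a^B|`. Equal areas score `2a`; a contact present in one chain
and absent in the other scores 0; a strongly over-predicted contact still
earns the smaller area's worth — over-prediction is deliberately penalised
less than omission. The weight is 0 at sequence separation ≤ 1 in either
chain (this also kills the i = j diagonal terms), 1 at separation ≥ 5 in
both, and γ = 0.5 between — nearby backbone contacts carry little
evolutionary signal and would otherwise dominate.

`S` sums θ over **ordered** pairs of aligned positions (stated in the
report header; an unordered sum would halve every score uniformly and change
nothing relative).

The optimiser builds, from a current alignment, the field
`M(k) = Σ θ(i, k)` over aligned pairs *i* strictly on one side of *k* in
both chains (crossing pairs contribute nothing), smooths it along the
diagonal — `M'(k)` averages offsets −N_w…+N_w, always dividing by
`2N_w + 1`, so matrix edges are down-weighted — and runs Smith–Waterman on
`M'` with gap open 90 and extension 0. The printed form of the window sum
indexes offsets with an off-by-one relative to its own worked illustration;
the centred window implemented here follows the illustration. Per window
half-width (5, then 3, then 1) the loop runs until the alignment repeats,
`|ΔS| < 1e-9`, or 10 iterations. The true `S` of every iterate — and of the
seed itself — is recorded, and the global argmax over all seeds and
iterates is returned, so the result can never score below the best seed.
The gap-*extension* penalty of this stage is taken as 0: only the open
penalty was ever optimised, and a pure per-run cost is the natural reading;
it is exposed in config regardless.

`NormS = S/T_A^0.7 + S/T_B^0.7` removes the gross size dependency of `S`
for cross-pair ranking; the exponent 0.7 trades absolute shared area
against the shared *fraction* of each chain's contact budget.

## Evaluation metrics

"Correctly aligned position" means an exactly identical residue pair — no
±1 tolerance is granted anywhere. Agreement is `N_c/L_ref`, reliability
`N_c/L_ali`; gap positions carry no pairs and are thereby excluded. `AQ(x)`
restricts to reference positions with confidence ≥ x and is reported as
missing when none qualify. Triplet consistency follows A→B→C→A cycles: a
position enters `AL` when it is aligned in all three maps (agreement not
required) and counts as consistent when the cycle closes on it; `Cov`
normalises by the smallest protein, `Rate` by `AL`. `AL` has no canonical
published definition; the chain-coverage reading used here is pinned by an
oracle test. ROC/PRC use `scikit-learn` (trapezoidal AUC; step-wise,
right-continuous average precision), cross-checked in tests against a
Mann–Whitney pair-counting oracle with half-credit for ties.

## Synthetic fixtures

The generator emulates small single- and two-domain polypeptides:
poly-alanine chains (N, CA, C, O, CB) on ideal helix parameters (rise
1.5 Å, 100°/residue, CA radius 2.28 Å → CA–CA 3.80 Å) or a zigzag extended
trace, with optional seeded Gaussian jitter. Backbone atoms are placed from
local tangent/curvature frames with realistic bond lengths; peptide-bond
dihedrals are not modelled. The hinge pair joins two helical domains by an
extended linker and rotates everything past the central linker residue
about an axis through that residue's CA. The construction guarantees — and
regenerates with a longer linker if violated — that the two domains share
no surface contact in either conformer, so the hinge changes the contact
matrix only near the pivot (measured: < 2% of `T` at 90°).

What passing on these fixtures does *not* show: side-chain packing
diversity, real loop geometry, chain breaks, alternate conformers, or the
statistics of large benchmark sets. The fixtures isolate the method's
defining property — contact fabric invariant under domain motion — and the
structural constants of the pipeline; claims about benchmark-scale accuracy
are outside this package's scope.

## Problem sizes and defaults

Default test and reproduction runs use 20–40-residue fixtures and a
34-residue hinge pair; at these sizes the full pipeline (580 seeds,
iterative DP) completes in seconds on one core, and the structural
constants it verifies (58/290/580, DP optimality, score identities) are
size-independent by construction. All tuned constants — c = 1.5, voxel
1.0 Å, cutoff 2.8 Å, URMS reference 0.917, γ = 0.5, iterative gap open 90,
windows (5, 3, 1), exponent 0.7, TM gaps (0.6, 0) — are taken as given
defaults and are overridable through a flat `section.key = value` config
file; no re-optimisation is attempted here.

## Known limitations

* Contact areas inherit grid-discretisation noise; scores are stable but
  not bit-identical under rigid motion of the *inputs* (they are
  bit-identical for identical inputs).
* The seed stage needs ≥ 7 residues per chain (heptapeptide windows).
* `NormS` comes with no significance model (no E-values).
* mmCIF input is accepted through the same reader, but multi-model/assembly
  handling is limited to the first model, single chain.
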