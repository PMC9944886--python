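# Methods

## Gaussian shape model

Molecular volume is modeled as a sum of isotropic atomic Gaussians rather
than hard spheres: `f(r) = Σ_i p·exp(−α_i|r−c_i|²)` over the heavy-atom
centers. With a shared amplitude `p` the exponent of an atom of van der
Waals radius `r` is fixed by requiring the isolated-atom integral to equal
the hard-sphere volume:

    α = π · (3p / (4π r³))^(2/3)

We use `p = 2√2 ≈ 2.828`, the conventional amplitude for hard-sphere
calibrated Gaussian shape models, and radii (Å) C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, F 1.47, Cl 1.75, Br 1.85, I 1.98, H 1.20 (user-overridable
via a two-column text table). Unknown elements are a hard error rather
than a silent carbon fallback, because a wrong radius silently corrupts
every downstream Tanimoto.

Overlaps are defined on the density itself — `I_f = ∫f²`, `O_fg = ∫f·g` —
so every quantity is a closed-form double sum of Gaussian product
integrals, with no truncated inclusion–exclusion series. The dissimilarity
is implemented as `S = I_f + I_g − 2O`, which equals the integrated
absolute difference `∫|f−g|dV` exactly for hard characteristic functions
and is its natural Gaussian-density analogue; algebraically
`S = (I_f+I_g)(1−T)/(1+T)`, which the test suite verifies numerically.
A brute-force Riemann-sum oracle (`grid_overlap_oracle`) provides an
independent check of the analytic algebra; at 0.1 Å spacing it agrees
with the closed form to much better than 0.5% on ≤10-atom shapes.

**Hydrogens** are excluded by default (heavy-atom shape matching is the
common convention); `include_hydrogens=True` overrides.

## Rigid superposition

Alignment maximizes `O_fg` over rotations and translations only
("solid-body optimization"; conformers stay rigid). The optimizer is a
deterministic step-halving pattern search: each sweep probes ±steps along
the three translation axes and ±small rotations about the three axes
through the moving query's centroid (12 probes), accepts the best uphill
move, and halves the steps (from 0.5 Å / 0.25 rad down to 1/64 of that)
when no probe improves. Convergence is declared when no uphill move
exists at the finest step or the relative sweep gain drops below 1e−6;
the iteration cap is 200. The search only ever accepts uphill moves, so
the final overlap is never below the starting overlap. A gradient-based
optimizer would be a drop-in replacement; the pattern search was chosen
for determinism and robustness on the 6-DOF manifold.

Start poses come from three families:

1. **com** — identity rotation, centers of mass (unweighted means of the
   Gaussian centers) superimposed;
2. **random** (8 by default) — the query COM placed on a uniformly chosen
   reference atom center with a uniform random rotation. Placing starts on
   atom centers rather than uniformly in a box concentrates them where
   overlap is attainable; all randomness flows from one explicit seed
   (default 0), so runs are bit-reproducible.
3. **inertial** (always 4) — principal axes of the two shapes'
   second-moment tensors aligned, in all four proper sign-flip
   combinations. This is a deterministic third search route through the
   same shape theory; for a rigid copy with non-degenerate moments one of
   the four starts is the exact superposition, which is why seeded
   rigid-copy recovery tests reach Tanimoto 1 − 1e−7 or better. For
   shapes with degenerate moments (regular tetrahedra, symmetric rings)
   the inertial frame is arbitrary and recovery relies on the local
   search, which still lands within ~1e−6 of the optimum.

## Matching protocol

The final Tanimoto of a query pose against a database conformer is the
maximum over all 13 starts. Against a ligand it is additionally the
maximum over the conformer ensemble (truncated to 64 in input order), and
at ligand level it is symmetrized: max of (A-pose vs B-ensemble) and
(B-pose vs A-ensemble), a ligand's pose being its first conformer (the
experimental pose in PDB-derived input). All-vs-all matching evaluates
each unordered pair once and reports pairs with Tanimoto **strictly**
greater than the threshold (default 0.85). Pairs are independent work
units; parallel evaluation is permitted provided the sorted output is
identical to the sequential one.

## Affinity rules

Units normalize by fM 1e−15 … M 1; association constants (Ka, M⁻¹) are
stored as their reciprocal so all `molar_value`s live on the dissociation
scale. The preference order when several measurements exist is Kd
(including converted Ka) > Ki > IC50; within a type, exact `=` relations
beat inequalities, then the tightest value wins.

The distribution bins are `[0, 1 nM)`, `[1 nM, 1 μM)`, `[1 μM, 1 mM]`,
`(1 mM, ∞)` — left-closed at 1 nM and 1 μM with exactly 1 mM in the third
bin. Published bin tables are ambiguous about boundary membership, so
this fixed convention is documented here; a requested Kd distribution
also admits Ka records, mirroring the "Kd (or Ka⁻¹)" convention of such
tables.

The cross-database discrepancy classifier assigns exactly one category
per record pair with fixed precedence: unit-equivalent agreement (same
type, relation and ligand, molar values within 0.5% relative — enough to
absorb rounding like 0.003 μM vs 3.0 nM while separating real value
errors), then measurement-type error, inequality error, wrong-pair error,
value error. Agreement deliberately requires matching relation and
ligand: a pair differing only in relation must classify as an inequality
error even when the numbers coincide.

## Curation pipeline

Standard inclusion requires resolution ≤ 2.5 Å, ≥ 1 protein chain and
≥ 1 valid ligand; the HiQ subset adds R_free − R_work ≤ 0.05, RSR ≤ 0.2
and RSCC ≥ 0.9, all boundaries inclusive (comparisons carry a 1e−9 guard
so float rounding of differences like 0.23 − 0.18 cannot flip a
boundary case). Every discarded record carries the first failing rule in
pipeline order; missing required fields are reported and discarded.

Ligand validity is list-driven, not chemistry-perception-driven: shipped,
user-editable HET-code lists mark crystallization additives, salts,
buffers, solvents, metals and halides as invalid, and HEME groups plus
modified amino acids as part of the protein. A covalently attached ligand
is excluded with reason "covalently bound"; covalency is geometric — any
ligand heavy atom within (covalent radius sum + 0.4 Å) of a protein heavy
atom. The shipped lists are a best-effort stand-in for a full curation
vocabulary and will misclassify unusual HET codes; override them for
production use.

Families are single-linkage connected components of the graph with edges
pairwise identity ≥ threshold (0.90, 0.70 or 0.50), computed on each
complex's longest chain. Single-linkage was chosen over the literal
"all ≥ X% to each other" clique reading because it matches common
sequence-clustering practice and is threshold-monotone (lowering the
threshold only merges families). Leaders exist only at 0.90: tightest
preferred affinity, then best resolution, then lexicographic id —
"biological relevance" is not operationalizable from metadata alone, so
resolution substitutes as the documented fallback.

Identity comes from an in-repo end-gap-free global aligner (affine gaps:
first gap column −5, each further −1; match +1, mismatch 0) instead of an
external alignment binary — deterministic, dependency-free, and adequate
at desk scale (O(nm) per pair; fine for hundreds of residues, not for
proteome-scale sweeps). Identity is identical columns divided by
aligned-path length, free end overhangs excluded, so identical sequences
score exactly 1.0. Traceback tie-breaks prefer diagonal, then up, then
left; inputs are canonically ordered before alignment so the function is
exactly symmetric. `X` never counts as identical. Tests check it against
an independently formulated backward-recursion oracle and against a
reference aligner's optimal scores.

## Synthetic data

The fixtures module generates every input class deterministically:

- **Toy ligands** — linear chains (1.5 Å spacing), regular rings (1.5 Å
  edges) and tetrahedra, single-element by default so shape quantities
  have closed-form sanity checks. `perturb_ligand` applies a seeded rigid
  move, creating known-answer superposition cases whose optimal Tanimoto
  is 1 by construction.
- **Synthetic affinity sets** — record pairs realizing exact planted
  counts per discrepancy category (unit-equivalent pairs genuinely
  re-expressed in different units) and single records placed log-uniform
  within each requested distribution bin, with ground truth emitted
  alongside.
- **Toy complexes** — minimal standard-conformant PDB files (CRYST1,
  poly-alanine backbone, HETATM ligands placed within or beyond covalent
  distance per flag) plus the matching metadata record, so the real PDB
  parser and geometry code are exercised, not bypassed.

What the toys do not emulate: real chemistry (bond orders, valence,
torsional strain), realistic conformer ensembles, crystallographic noise,
or the scale of a full structure database. Passing tests therefore
demonstrate the correctness of the algebra, the optimizer contracts and
the curation rules — not virtual-screening enrichment on real ligands.
Absolute Tanimoto values on real molecules also depend on amplitude,
radii and hydrogen conventions that differ between shape tools, so
cross-tool comparisons should expect small systematic offsets.

## Problem sizes and numerical choices

The test suite and the acceptance script run on toy ligands of 1–20
atoms, conformer ensembles of ≤ 4, ligand sets of 3, sequence sets of
≤ 40-mers, and planted affinity tables up to the published per-type
totals (≈ 5.5k records); these sizes exercise every code path while
keeping a full run in well under a minute on one CPU. Full-database
all-vs-all matching (tens of thousands of ligands, ~10⁶ reported pairs)
is out of scope for this artifact and would require distributing the
pairwise work units.

Degenerate inputs are hard errors: empty conformers, zero included
atoms, unknown elements, empty sequences, duplicate ligand or PDB ids.
Overlap underflow at large separations yields exactly 0 (Tanimoto 0),
which is the correct limit. Grid-oracle boxes are padded by 4σ of the
widest Gaussian; convergence checks use coarse spacings because the
Riemann sum of a Gaussian reaches machine precision extremely fast.
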