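# moadshape

3D ligand shape matching and protein–ligand database curation tools.

`moadshape` is for computational chemists exploring **polypharmacology** —
one small molecule binding several unrelated protein targets. Two ligands
that look nothing alike in 2D can still occupy the same three-dimensional
space in a binding site, so the package scores ligand pairs by **3D shape
similarity** and couples that engine with the curation rules used by
affinity databases of protein–ligand crystal structures: structure-quality
filters, ligand-validity annotation, binding-data preference and binning,
cross-database discrepancy classification, and sequence-identity protein
families with representative leaders.

## The shape model

A molecule's volume is a sum of isotropic atomic Gaussians,

```
f(r) = Σ_i p · exp(−α_i |r − c_i|²)
```

one Gaussian per heavy atom at center `c_i`, with shared amplitude
`p = 2√2` and per-atom exponent calibrated so the isolated-atom integral
equals the hard-sphere volume `(4/3)π r_vdw³`. Every shape quantity is
then an exact Gaussian integral:

- self-overlap `I_f = ∫ f² dV`,
- cross-overlap `O_fg = ∫ f·g dV`,
- **shape Tanimoto** `T = O_fg / (I_f + I_g − O_fg)` ∈ (0, 1], equal to 1
  exactly when the densities coincide,
- dissimilarity `S = I_f + I_g − 2·O_fg = (I_f + I_g)(1 − T)/(1 + T)`.

Alignment is a **solid-body optimization**: a deterministic pattern search
maximizes `O_fg` over the six rigid degrees of freedom from 13 start
poses — the center-of-mass start, 8 seeded random placements of the query
COM on reference atoms, and 4 principal-axes alignments. The final
Tanimoto for a pair is the maximum over all starts, over the database
ligand's conformer ensemble (≤ 64 rigid conformers), and over both
pose-vs-ensemble directions. All-vs-all matching over a ligand set reports
pairs with Tanimoto strictly above 0.85, the database's reporting cutoff.

## Worked example

```python
from moadshape.fixtures import make_toy_ligand, perturb_ligand
from moadshape.shape_protocol import match_ligands
from moadshape.polypharm_db import all_vs_all_match

ring = make_toy_ligand("ring", 6, ligand_id="benzene_like")
copy = perturb_ligand(ring, seed=1)          # rigidly moved copy
decoy = make_toy_ligand("linear", 20, ligand_id="long_chain")

m = match_ligands(ring, copy)
print(m.query_id, m.db_id, f"{m.tanimoto:.6f}", m.best_start_family)
# benzene_like benzene_like_perturbed 1.000000 inertial

print(f"{match_ligands(ring, decoy).tanimoto:.6f}")
# 0.181811

for mm in all_vs_all_match([ring, copy, decoy], threshold=0.85):
    print(mm.query_id, mm.db_id, f"{mm.tanimoto:.6f}")
# benzene_like benzene_like_perturbed 1.000000
```

The rigidly moved copy is recovered at Tanimoto 1.000000 (the
principal-axes start finds the exact superposition), the 20-atom chain
scores 0.18 against the 6-ring, and only the copy pair clears the 0.85
reporting threshold.

The same protocol runs from the shell:

```bash
moadshape match --db ligands.sdf --threshold 0.85 --seed 0 --out matches.tsv
moadshape pair --query q.sdf --db d.sdf --seed 0 --report-json pair.json
moadshape affinity compare --left moad.tsv --right other.tsv --report report.tsv
moadshape curate --meta meta.tsv --seqs seqs.fasta --mode hiq --families 0.90 --out report/
```

Ligands are read from SDF (multi-record files collapse by title into
conformer ensembles), MOL2, or PDB files (HETATM extraction with water
and altloc handling). Affinity tables are TSV with columns
`pdb_id, ligand_id, type, relation, value, unit`.

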