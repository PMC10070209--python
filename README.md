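# mnox

Per-ion **Mn oxidation-state prediction from coordination geometry**, with
bond-valence-sum cross-checks and catalytic S-state assignment for 4-Mn
clusters (photosystem II OEC-style).

The method reduces every octahedral Mn site to two features — the mean
equatorial (**E**) and mean axial (**A**) Mn–ligand bond length, separable
because Jahn–Teller distortion elongates the axial pair of d⁴ Mn(III) —
then classifies the site as Mn(II)/Mn(III)/Mn(IV) with a Gaussian naive
Bayes or entropy decision tree trained on K-means-corrected labels.  For a
four-Mn cluster the predicted charges are summed and mapped to an S index
(total charge 13, 14, 15, 16 → S₀…S₃, extended to negative indices for
over-reduced structures).

## Layout

| module | role |
|---|---|
| `mnox.structure_io` | PDB/mmCIF reading (Biopython-backed), Mn-site extraction with ligand shells and a rejection report |
| `mnox.geometry_features` | antipodal ligand pairing (exhaustive over the 15 matchings) and the (E, A) features |
| `mnox.training` | feature-table curation, K-means label correction, GNB and decision-tree classifiers, evaluation, JSON model serialization, rule export |
| `mnox.bvs` | bond-valence sums v = Σ exp((R₀−Rᵢ)/B), candidate-state assignment, R₀ recalibration |
| `mnox.oec_pipeline` | 4-Mn cluster extraction (named or dangler-heuristic ordering), per-monomer prediction, S-state assignment, reported-vs-predicted reports |
| `mnox.synthetic_data` | seeded generators: Gaussian-mixture feature tables with label noise, octahedron/OEC PDB fixtures with exact ground truth |
| `mnox.cli` | `mnox` command with `simulate`, `features`, `train`, `evaluate`, `predict`, `bvs` |

Reference data shipped in `mnox/data/`: bond-valence R₀/B parameters
(external literature values, editable TSV) and a 38-structure PSII
reported-vs-predicted S-state survey used by the report builder tests.

## CLI quick start

```sh
# synthetic feature table (3-class mixture, 5% label noise) and a model
mnox simulate table --seed 1 --out table.csv
mnox train table.csv --kind dt --seed 0 --out model.json --rules-out rules.txt

# evaluate (holdout or k-fold)
mnox evaluate table.csv --kind gnb --scheme kfold:10

# synthetic OEC fixture and end-to-end prediction
mnox simulate oec --pattern III,IV,IV,III --monomers 2 --out oec.pdb
mnox predict oec.pdb --model model.json --out report.csv

# bond-valence cross-check on any Mn-containing structure
mnox bvs oec.pdb
```

Real structures work the same way: `mnox features 6dhe.pdb --out f.csv`,
`mnox predict 6dhe.cif --model model.json --out report.csv`.

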