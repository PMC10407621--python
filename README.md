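# roqsar

QSAR modeling of emerging-contaminant rejection by reverse-osmosis membranes.

The package reimplements, as a tested and reusable pipeline, a
structure–activity study linking four molecular descriptors to the percent
rejection of 72 organic micropollutants by an RO membrane:

* **molgraph** — SMILES/SDF parsing, hydrogen-included and hydrogen-depleted
  graphs, bond-indexed edge-adjacency matrices, topological distances, and a
  seeded ETKDG+MMFF fallback for 3D coordinates.
* **descriptors** — the four selected descriptors and their families:
  `SIC1` (order-1 structural information content), `ESpm14u`
  (log-transformed 14th spectral moment of the edge adjacency), `EEig03d`
  (third eigenvalue of the dipole-weighted edge adjacency) and `R2e`
  (lag-2 GETAWAY autocorrelation weighted by Sanderson electronegativity).
  Element/bond parameter tables ship as editable YAML.
* **dataset** — the packaged 72-compound study table (names, SMILES,
  experimental and model-predicted rejections, train/test/validation labels,
  censoring flags) plus dataset assembly and lossless CSV IO.
* **feature_selection** — the filtering cascade: zero-variance removal,
  |r| > 0.90 correlation pruning, forward stepwise p-value ranking, top-k
  selection.
* **ann** — min–max scaling to [−1, 1], a 4-4-1 log-sigmoid/linear
  feedforward network, Levenberg–Marquardt and delta-rule training with
  validation-based early stopping, Garson connection-weight importance.
* **mlr** — ordinary least squares baseline and the published reference
  equation.
* **evaluation** — R²/MSE/RMSE/MPE fit statistics and leverage-based
  applicability-domain analysis (Williams plot data, h* = 3(m+1)/n).
* **synthetic** — seeded generators for QSAR-like tables with planted
  zero-variance columns, correlated pairs, informative descriptors and
  bounded nonlinear responses, for ground-truth recovery tests.
* **pipeline / cli** — end-to-end orchestration with manifests.

Conventions that were fixed by matching the study's printed descriptor
values: bond orders never enter adjacency structure (a double bond is one
graph edge); hydrogens are excluded from edge-adjacency descriptors and
included in information-content and GETAWAY descriptors; `ESpm` is
`ln(1 + trace(B^k))`; carbon–carbon bonds carry zero dipole weight.

## CLI

```sh
roqsar dataset export --out data/         # write the packaged study table
roqsar descriptors --out descriptors.csv  # fixture descriptors (or --in x.smi)
roqsar select --in table.csv --k 4        # filtering cascade -> JSON report
roqsar train --data dataset.csv --seed 1  # train the 4-4-1 network
roqsar importance --weights model.json    # Garson importance table
roqsar mlr --data dataset.csv             # linear baseline + metrics
roqsar evaluate --pred p.csv --truth d.csv --by
roqsar ad --model model.json --data dataset.csv --out williams.tsv
roqsar simulate --seed 11 --n 200         # synthetic dataset + ground truth
roqsar run --out run1 --seed 1            # full study pipeline on the fixture
roqsar sweep --data dataset.csv --nodes 1-7
```

`roqsar run` writes descriptor/selection/model/metrics/applicability-domain
artifacts plus a manifest with config and checksums; reruns with the same
seed are byte-identical.

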