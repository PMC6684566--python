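# nmrshift

Per-atom NMR chemical shift prediction with quantified uncertainty.

The chemical shift of a spin-active nucleus (here ¹³C and ¹H) is determined
by its local molecular environment, which makes it both the workhorse
observable of structure elucidation and a natural target for machine
learning on molecular graphs. `nmrshift` implements:

* a **bond-order-aware residual graph convolutional network** that predicts,
  for every atom of a molecule, a shift estimate μ (ppm) *and* a per-atom
  uncertainty σ (ppm),
* the classical **HOSE-code nearest-neighbor baseline**, whose matched
  concentric-sphere depth provides a discrete confidence, and
* the **confidence-fraction evaluation protocol** that compares such methods
  at matched coverage: the MAE over the *f* most-confident predictions, as
  *f* varies.

## The model

Per-atom features (37 per vertex: atomic number, element / valence /
hybridization / formal-charge / default-valence / ring-size one-hots,
aromaticity) are stacked into an M×D matrix *L*, with M = 64 the padding
size. Bonds are split into four adjacency matrices G₁, G₁.₅, G₂, G₃ by bond
order (aromatic = 1.5), each symmetrically normalized with self-loops,

    G̃ = D^(-1/2) (G + I) D^(-1/2),   D = diag(rowsums(G + I)).

Each network layer applies one shared weight matrix per layer across the
four channels and aggregates by an elementwise max, with a residual
connection from the second layer on:

    L⁽ⁿ⁺¹⁾ = relu( max_k G̃_k L⁽ⁿ⁾ W⁽ⁿ⁾ ) + L⁽ⁿ⁾.

Two heads map the final per-vertex embedding to μ (three residual blocks of
width 128 plus linear layers) and to σ (two linear layers, softplus
positivity). Training minimizes the heteroscedastic loss, averaged over
observed nuclei and exactly zero at unobserved ones:

    (y − μ)² / (2σ²) + σ,

which is stationary at σ = |y − μ|^(2/3) — so the trained σ tracks each
atom's expected error. Separate models are trained per nucleus. The
reference scale is 10 layers × 2048 features; the default desk profile
(4 × 128) trains in minutes on one CPU. The network is implemented directly
in NumPy (forward, analytic backward, Adam), so there is no deep-learning
framework dependency.

## Worked example

Every dataset here is synthetic: random valence-respecting molecules over
{H, C, O, N, P, S, F, Cl} whose "true" shifts come from a deterministic
1-bond-environment oracle plus controlled Gaussian noise, so recovery can
be measured exactly.

```python
from nmrshift import (
    GraphConvShiftRegressor, HoseShiftRegressor, SyntheticShiftOracle,
    assign_shifts, confidence_curve, error_metrics, generate_molecules,
    prediction_table, split_by_structure,
)
from nmrshift.synthetic import targets_from_assignments

mols = generate_molecules(500, seed=5000, max_atoms=16,
                          aromatic_prob=0.35, ring_prob=0.35)
oracle = SyntheticShiftOracle()
oracle.noise_sd["C"] = 0.5          # 0.5 ppm measurement noise on 13C
assigns = assign_shifts(mols, oracle, seed=5001, nuclei=("C13",))

split = split_by_structure(mols, test_fraction=0.2, seed=5002)
train = [g for g in mols if g.mol_id in split.train_ids]
test = [g for g in mols if g.mol_id in split.test_ids]
y_train = targets_from_assignments(train, assigns, "C13")
y_test = targets_from_assignments(test, assigns, "C13")

gnn = GraphConvShiftRegressor(n_layers=4, width=128, head_width=64,
                              m_max=16, epochs=30, learning_rate=3e-3,
                              patience=10**6, seed=0).fit(train, y_train)
table = prediction_table(test, y_test, gnn.predict_dist(test), nucleus="C13")
m = error_metrics(table)
print(f"GNN  held-out MAE {m.mae:.2f} ppm   mol MAE {m.mol_mae:.2f}   "
      f"mol RMSE {m.mol_rmse:.2f}")

hose = HoseShiftRegressor(spheres=6).fit(train, y_train)
hose_table = prediction_table(test, y_test,
                              hose.predict_with_confidence(test),
                              nucleus="C13").dropna(subset=["mu"])
print(f"HOSE held-out MAE {error_metrics(hose_table).mae:.2f} ppm "
      f"on {len(hose_table)}/{len(table)} matched nuclei")

curve = confidence_curve(table, fractions=[0.5, 0.95, 1.0])
for f, mae in zip(curve.fractions, curve.mae):
    print(f"GNN MAE over the {f:.0%} most-confident nuclei: {mae:.2f} ppm")
```

Output:

```
GNN  held-out MAE 0.76 ppm   mol MAE 0.98   mol RMSE 1.36
HOSE held-out MAE 1.08 ppm on 479/479 matched nuclei
GNN MAE over the 50% most-confident nuclei: 0.51 ppm
GNN MAE over the 95% most-confident nuclei: 0.66 ppm
GNN MAE over the 100% most-confident nuclei: 0.76 ppm
```

The GNN beats the nearest-neighbor baseline at full coverage (0.76 vs
1.08 ppm), and its σ is informative: restricting to the half of nuclei it
is most confident about drops the MAE to 0.51 ppm, near the injected
0.5 ppm noise floor. `mol MAE`/`mol RMSE` aggregate the absolute error per
molecule first, then across molecules.

The same pipeline is scriptable from the shell — `nmrshift synth`,
`ingest`, `featurize`, `train`, `predict`, `hose-build`, `hose-predict`,
`evaluate` (see `nmrshift --help`). Real data enters through
`nmrshift ingest`, which reads multi-record V2000 SDF files with either
per-atom `Spectrum 13C/1H` property tags or a CSV assignment sidecar, and
applies the standard inclusion filters (elements ⊆ {H,C,O,N,P,S,F,Cl},
≤ 64 atoms counting explicit hydrogens, sanitization).

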