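# Methods

## Problem setting

A molecule is an undirected graph whose vertices are atoms (hydrogens
explicit, so ¹H nuclei have prediction sites) and whose edges carry a bond
order in {1, 1.5, 2, 3}, aromatic bonds being 1.5. For each spin-active
nucleus (¹³C or ¹H) with an assigned chemical shift y (ppm), the model
predicts an estimate μ and an uncertainty σ. Separate models are trained
per nucleus; the estimator itself is nucleus-agnostic and simply receives
per-atom targets with NaN at unobserved atoms.

## Network

**Inputs.** Each atom contributes a 37-entry feature vector in fixed block
order: atomic number (1), element one-hot over {H,C,O,N,P,S,F,Cl} (8),
valence scalar (1), valence one-hot 1–6 (6), aromaticity flag (1),
hybridization one-hot s…sp³d² (6), formal-charge one-hot {−1,0,+1} (3),
default-valence one-hot 1–6 (6), ring-size one-hot 3–7 (5). "Valence" is
total connectivity including hydrogens; "default valence" is the element's
standard valence from the periodic-table defaults. Out-of-range categorical
values encode as all-zero blocks rather than clamping, since the ranges are
closed; an atom in several rings sets the position of its smallest ring
(one-hot discipline forces a single choice; smallest-ring is the standard
convention). Features are stacked into an M×37 matrix padded to M (64 by
default; desk configurations shrink M to the fixture's maximum molecule
size purely to save compute).

**Adjacency.** One 0/1 adjacency matrix per bond order; each bond lives in
exactly one channel, and aromatic bonds appear only in the 1.5 channel (no
kekulized duplicate — aromaticity is perceived before adjacency
construction). Each channel is normalized as G̃ = D^(−1/2)(G+I)D^(−1/2)
with D the diagonal of row sums of G+I, computed on the valid submatrix
only, so padding never inflates degrees; the identity is added only on the
valid diagonal. The vector-valued normalizer notation r^(−1/2) is read as
this diagonal matrix of inverse square-root row sums, the standard
symmetric graph-convolution normalization.

**Layers.** A layer computes relu(max_k G̃_k L W) with one weight matrix W
shared across the four channels, the max taken elementwise across channel
outputs before the nonlinearity, then adds the residual L when input and
output widths match. The first layer (37 → width) has no residual. Conv
layers are bias-free and padded rows are re-zeroed after every layer, so
padding cannot leak through nonlinearities. Equivalence with the per-vertex
definition (a weighted sum over the neighborhood including the self-loop)
is enforced by a brute-force oracle test on small random graphs.

**Heads.** From the final per-vertex embedding, the σ branch is
linear+relu (width → head), linear (head → 1), then softplus + 10⁻⁴ ppm;
softplus avoids the exponential blow-up that an exp-parameterization shows
early in training, and the ε floor keeps the loss finite. The μ branch is
linear+relu (width → head), three residual blocks (relu(xW+b)+x), a further
linear+relu, and a final linear with no relu (shifts can sit near 0 ppm,
and fluorine shifts are negative on common references).

**Loss.** Mean over observed atoms of (y−μ)²/(2σ²) + σ; unobserved atoms
contribute exactly zero regardless of their predictions (tested by
arbitrary perturbation at masked atoms). The per-atom minimizer in σ is
σ* = r^(2/3) for residual r, which is what makes the trained σ an error
estimate; stationarity at σ* is asserted analytically in the tests.

## Training

The optimizer is Adam (minibatches of 32, learning rate 3·10⁻³ for the
desk profile) with global gradient-norm clipping at 5 — the clipping and
the rate are this package's choices, as is everything else about the
schedule. Targets are z-scored over observed training atoms (σ is mapped
back to ppm on output) and input feature columns are standardized over real
atoms; both make one learning rate serve the ~200 ppm ¹³C scale and the
~10 ppm ¹H scale. Output layers are initialized small with the σ bias set
so that σ starts near 1 in standardized units, keeping the 1/σ² term tame
at initialization; all other weights are He-initialized. A validation
fraction (default 10%) is carved from the training molecules; training
keeps the best-validation-loss checkpoint and stops early after a patience
of 10 epochs. For σ-calibration experiments early stopping is disabled
(patience effectively infinite): μ converges before σ does, and a
prematurely restored checkpoint would leave σ uncalibrated. Everything —
data split, weight init, batch order — derives from a single seed, and the
whole computation is deterministic NumPy, so identical seeds give identical
loss curves.

The reference architecture is 10 layers of width 2048 with 128-wide heads;
the test and acceptance runs use 4 layers of width 128 (64-wide heads) on
500 molecules of ≤ 16 atoms, which trains in well under a minute on one
CPU while leaving the learning problem non-trivial. These sizes are stated
here as the package's desk profile; nothing about the architecture changes
with scale.

## HOSE-code baseline

The baseline summarises each atom's environment in concentric bond-distance
spheres (default 6): sphere 0 is the focus element, sphere k the atoms k
bonds away with bond symbols (aromatic `*`, double `=`, triple `%`, single
unmarked) and `&` ring-closure markers. Branches are ordered by
symmetry-invariant canonical atom ranks (Morgan-style, no tie-breaking),
then element and bond symbol, which makes codes independent of input
numbering and identical for symmetry-equivalent atoms; stereo and charge
symbols are omitted because the models are connectivity-only — a
documented simplification of the historical grammar. Prediction looks up
the deepest sphere prefix with training matches and returns their
unweighted mean, with the matched depth as a discrete confidence. Exact
recall — every training atom matched at full depth against its own
database — is a tested invariant.

## Evaluation

Confidence-fraction curves select, for each fraction f, the ⌈fN⌉
most-confident predictions (σ ascending for the network, matched sphere
descending for HOSE; ties in stable input order — note that with ties the
realized fraction is still exactly ⌈fN⌉/N, not a level boundary) and
report their MAE; at f = 1 this equals the global MAE identically. `mol
MAE`/`mol RMSE` first average absolute error within each molecule, then
take the mean / root-mean-square across molecules; mol RMSE ≥ mol MAE by
the power-mean inequality, which the tests assert. Stratified breakdowns
group by observed-shift bin (fixed widths, 10 ppm for ¹³C and 0.5 ppm for
¹H by convention) or by bonded partner element, where a nucleus bonded to
several distinct elements appears in each such stratum. Uncertainty on
group means is the seeded percentile bootstrap of the mean (default 10,000
resamples, 95%).

## Synthetic data

The generator grows random valence-respecting heavy-atom trees (optionally
seeded with a benzene ring), upgrades some single bonds to double/triple
bonds, occasionally closes an aliphatic ring, fills remaining valence with
explicit hydrogens, and rejects anything that fails sanitization or the
atom cap — so every fixture passes the standard dataset filters unchanged.
Ground-truth shifts come from a deterministic oracle over the 1-bond
environment: a base value per element plus additive terms per bonded
partner element and per bond order, plus aromatic and ring offsets, mapped
through a per-element scale so carbon lands on a ¹³C-like ~60–200 ppm range
and hydrogen on a ¹H-like ~2–10 ppm range. Restricting the oracle to the
1-bond environment is deliberate: any network with at least one
convolution layer has a sufficient receptive field, and a plain
environment-lookup table attains near-zero error on noiseless data, so
recovery failures indict the implementation, not the task. Gaussian noise
is added per noise class — by element, or with carbon refined into
aromatic / ring / chain classes for heteroscedastic-recovery experiments —
and repeated-measurement mode draws several spectra with fresh noise,
whose mean absolute deviation has the closed form s/√π for two repeats.

What passing these tests does **not** show: real shift corpora have
long-range (multi-bond, conjugation, solvent, temperature) effects the
oracle lacks, heavy-tailed user-contributed noise rather than Gaussian
classes, and chemistry far outside the generator's coverage. Desk-scale
recovery demonstrates that the machinery learns what it should from what
it sees, not that it attains any particular accuracy on experimental data.

## Degenerate inputs and numerical choices

Empty observation sets raise at fit time; a molecule with no valid
normalization target (no bonds) reduces to the identity self-loop; σ ≤ 0 at
an observed atom raises rather than silently clamping; assignments to
out-of-range atom indices or to atoms of the wrong element are dropped with
a logged warning while the molecule is kept; unparseable or
unsanitizable SDF records are skipped and counted. Train/test splits group
molecules by stereo-free canonical SMILES (the models ignore
stereochemistry, so stereoisomers must never straddle a split) and the
atom cap counts explicit hydrogens — the conservative reading, since
hydrogens are vertices here.
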