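# Methods

## Molecular graph representation

A compound is parsed with RDKit and kept as its heavy-atom skeleton
(hydrogens implicit — the standard convention for molecular GCNs, and the
same convention the ≤50-atom preprocessing filter counts). For each bond
type t in the configured set T (default: single, double, triple, aromatic,
following RDKit's aromaticity perception) a binary adjacency matrix A⁽ᵗ⁾ is
built; a given atom pair carries at most one bond type. The stored A⁽ᵗ⁾ has
a zero diagonal; self-loops enter only through normalization,
Ã⁽ᵗ⁾ = D̃^(−1/2)(A⁽ᵗ⁾+I)D̃^(−1/2) with D̃ the degree matrix of A⁽ᵗ⁾+I (the
Kipf–Welling renormalization, applied per bond type). On a d-regular graph
every nonzero entry of Ã is exactly 1/(d+1), which the tests exploit as a
closed-form oracle.

Atom features are block-structured and explicitly configured
(`FeatureConfig`), defaulting to element one-hot over
(C, N, O, S, P, F, Cl, Br, I, other), formal charge (scalar), hybridization
one-hot (sp, sp², sp³, other) and an aromaticity flag (D = 16). A degree
one-hot block is available but off by default. Out-of-vocabulary elements
map to the trailing "other" slot. The configuration is serialized with every
trained model and dataset archive, so featurization at predict time is
provably the same as at training time.

Multi-fragment molecules are kept as one block-diagonal graph: the gather
layer sums over all nodes regardless of connectivity.

## Network layers and training

The three graph layers are

* graph convolution X⁽ˡ⁺¹⁾ = σ(Σₜ Ã⁽ᵗ⁾ X⁽ˡ⁾ W⁽ˡ⁾ₜ) — one parameter matrix
  per bond type;
* graph dense X⁽ˡ⁺¹⁾ = X⁽ˡ⁾W⁽ˡ⁾ — node-wise; deliberately bias-free so
  padded (all-zero) rows stay zero and batch padding cannot leak into the
  readout;
* graph gather — column sums over the node axis, giving a
  permutation-invariant graph vector.

Batch normalization in convolution blocks operates per channel,
pre-activation, with statistics pooled over *real* (unmasked) nodes only;
outputs are re-masked afterwards. Together with bias-free graph layers this
makes predictions invariant to padding width (tested to 1e-5). Running
means/variances (momentum 0.9) are used at inference.

Classification heads emit two logits per task; each task is an independent
two-class softmax trained with cross-entropy averaged over *observed*
(compound, task) entries. A missing label contributes zero loss and — since
its head columns receive no gradient — leaves those parameters bitwise
unchanged, which the tests verify both by finite differences and after five
epochs of Adam.

Training uses Adam (default step 1e-3, β = 0.9/0.999), mini-batches of 32,
inverted dropout after the graph dense layer and post-gather hidden dense
layers, and He/Xavier-style seeded initialization. Every random choice
(initialization, shuffling, dropout) is driven by explicit seeds, so a
training trajectory is exactly reproducible on one machine; the CLI writes
the seeds and configuration to a manifest.

All forward/backward computation runs on a small reverse-mode automatic
differentiation tape over NumPy arrays (`molgcn._autograd`), implemented in
this package and checked against central finite differences. At the problem
sizes this package targets (≤50 atoms, a few thousand compounds) dense
NumPy batches are faster than any sparse bookkeeping would be.

### Sequence modality

The multi-modal variant encodes an amino-acid sequence (20-letter alphabet
plus pad and unknown tokens) by learned embedding → width-3 1-D convolution
→ ReLU → masked global max-pool (with a zero sentinel, so pad positions
contribute nothing and an all-pad sequence pools to zero) → dense. The
encoded vector is concatenated with the gathered graph vector before the
dense head. Vector-valued modalities (precomputed descriptors) pass through
unchanged at the same fusion point.

## Integrated gradients

Attribution uses the right-endpoint Riemann approximation

I(x) = (x/M) Σₖ₌₁..M ∇S((k/M)x),  M = 100 by default,

with an all-zero feature baseline. Only the feature matrix is interpolated;
adjacency is structural, not a differentiable input, and is held fixed, as
are other modality inputs (so the attribution covers compound atoms only).
S is the pre-softmax logit of the attributed task's active class — logits
are better conditioned than probabilities; the choice is recorded in the
result (`score_kind`) and probability-space attribution is available as an
option. Atom importance is the per-atom row sum of I(x).

For a linear scorer the Riemann sum is exact at any M (constant gradient);
for piecewise-linear (ReLU) scorers the completeness identity
Σ I(x) = S(x) − S(0) holds with an O(1/M) residual, reported as
`completeness_gap`. One caveat: a bias-free ReLU network upstream of the
readout is positively homogeneous, so scaling the input never flips a gate
and integration is exact for trivial reasons — the test scorers therefore
place the nonlinearity after the gather where biases exist. Rendering maps
importance to a symmetric diverging scale normalized by max |importance|:
red positive, blue negative, white at zero; SVG or PNG by file extension,
with a JSON sidecar carrying the raw values and M.

## Preprocessing protocol

* **Atom filter**: compounds with more than `max_atoms` (default 50) heavy
  atoms are removed; the boundary keeps exactly 50.
* **Negative balancing**: per task, inactives are drawn uniformly without
  replacement (seeded) from a caller-supplied pool — compounds inactive or
  unlabeled for that task, after the same atom filter — until negative and
  positive counts match; already-balanced tasks are untouched. Appended
  compounds are labelled 0 for the balanced task and missing elsewhere. The
  CLI uses input compounds without a label row as the pool.
* **Splits/folds**: seeded permutation; test size = round(n·fraction);
  k folds differ in size by at most one.
* Unparseable SDF/SMILES entries are skipped and counted in a report rather
  than aborting a batch run; label cells must be 0, 1 or empty (missing) —
  anything else is an error, never silently dropped.

## Synthetic benchmark (what it does and does not show)

The fixture generator assembles valence-valid SMILES from a closed fragment
vocabulary (alkyl chains, ethers, amines, benzene/cyclohexane/pyridine
rings; ≤30 heavy atoms, ≤3 fragments) and grafts the activity motif —
default `C(=O)NO`, a hydroxamic-acid-like group chosen because it is the
classic zinc-binding moiety of MMP inhibitors — onto every even-indexed
molecule, so exactly half are active before noise. Inactive molecules get
decoy tails (amide, ester, alcohol, amine) that share atoms and bonds with
the motif, forcing the model to resolve bonding patterns rather than count
elements. Labels are motif presence with independent flip noise (default
5%); ground-truth motif atom indices are recorded for attribution scoring
via a rank-based enrichment (the ROC-AUC of motif vs non-motif atom
importances within a molecule).

Default study conditions: 200 molecules, 5% noise, 80/20 split or five
folds. Under these conditions the default architecture reaches held-out
ROC-AUC ≥ 0.9 and mean motif enrichment ≥ 0.7 on correctly-classified
actives. The benchmark is deliberately separable and small: passing it
shows the pipeline learns and localizes a genuine structure–activity rule
end to end, not that the architecture matches state of the art on real
assay data. Real bioactivity data differ in scaffold diversity, activity
cliffs, class imbalance and label noise structure; the fixture emulates none
of these.

## Hyper-parameter optimization

The space covers, at minimum, the number of graph-convolution layers, the
number of post-gather dense layers, the dropout rate and the learning rate
(log scale). Search runs `n_initial` scrambled-Sobol points followed by
acquisition-driven points: a Gaussian-process surrogate
(constant × Matérn-5/2 + white noise, scikit-learn) is fitted to objective
values in the unit cube and the next point maximizes expected improvement
(jitter 0.01) over 512 uniform candidates plus 128 local perturbations of
the incumbent. Integer and categorical axes use continuous relaxation with
rounding. Failed trials (exceptions, non-finite objectives) are recorded
and enter the surrogate at worst-observed − 1, flagged `penalized`. The
default objective is cross-validated mean ROC-AUC (configurable); the whole
run is deterministic given its seed. The toy-objective checks in the test
suite use matched budgets (5 + 15) against a dense-grid/random-search
reference.

## Numerical and design notes

* Sigmoid inputs are clipped at ±500 to avoid overflow; softmax/logsumexp
  use max-subtraction; BN uses ε = 1e-5.
* Ties: `max` routes gradients to the first argmax; ROC-AUC counts ties as
  one half (Mann–Whitney), cross-checked against brute-force pair counting
  and scikit-learn.
* Dataset archives store V2000 molblocks (atom order preserved) and
  re-featurize on load, keeping archives small and featurization provenance
  explicit; model archives store the JSON spec, feature configuration and
  parameter arrays with a version header.
* CV reports are serialized with sorted keys and no timestamps, so equal
  seeds give byte-identical files.
* Problem sizes in tests and the acceptance script (200-molecule benchmark,
  60 training epochs, 30-epoch CV folds) were chosen as the smallest sizes
  at which the planted rule is reliably learnable; they run in seconds on
  one CPU core.

## Known limitations

* Binary classification only (no regression heads); graph attention and
  learned pooling are out of scope.
* The gather readout is a plain sum, so very large molecules produce larger
  activations than small ones; BN upstream mitigates but does not remove
  the size dependence.
* Aromaticity and hybridization follow RDKit's perception; no
  standardization (salt stripping, tautomer canonicalization) is performed
  beyond RDKit parsing.
* The GP treats rounded integer dimensions as continuous, which can stall
  on spaces dominated by categorical structure.
* Integrated gradients are computed sequentially per division; M = 100 on a
  50-atom molecule costs ~0.1 s, which is fine for inspection but not for
  attributing millions of compounds.
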