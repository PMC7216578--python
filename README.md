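# molgcn

Graph convolutional networks for molecular property prediction, with
per-bond-type convolutions, integrated-gradients atom attribution, Gaussian-
process hyper-parameter optimization, and a batch command-line pipeline.

`molgcn` is aimed at computational chemists and machine-learning researchers
in drug discovery who want to train QSAR-style classifiers directly on
molecular graphs (from SDF or SMILES inputs), inspect *which atoms* drive a
prediction, and automate model selection — all reproducibly from seeds,
without a GPU.

## The model

A molecule with N heavy atoms is represented as a pair (A, F):

- **A** = {A⁽ᵗ⁾}: one binary N×N adjacency matrix per bond type
  t ∈ {single, double, triple, aromatic}, A⁽ᵗ⁾ᵢⱼ = 1 iff a bond of type t
  joins atoms i and j;
- **F**: an N×D atom-feature matrix (element one-hot, formal charge,
  hybridization one-hot, aromaticity flag by default).

Each adjacency is degree-normalized with self-loops,
Ã⁽ᵗ⁾ = D̃^(−1/2)(A⁽ᵗ⁾+I)D̃^(−1/2), and three layer types are stacked:

- graph convolution: X⁽ˡ⁺¹⁾ = σ(Σₜ Ã⁽ᵗ⁾ X⁽ˡ⁾ W⁽ˡ⁾ₜ) — a weight matrix per
  bond type, with batch normalization and ReLU;
- graph dense: X⁽ˡ⁺¹⁾ = X⁽ˡ⁾ W⁽ˡ⁾ — node-wise, no mixing;
- graph gather: xⱼ = Σᵢ Xᵢⱼ — permutation-invariant readout to one vector.

Ordinary dense layers then produce two logits per task; each task is an
independent two-class softmax trained with cross-entropy masked over
observed labels, so multi-task data with missing labels is handled natively.
Multi-modal models concatenate an encoded second input (e.g. a tokenized
protein sequence passed through an embedding, 1-D convolution and masked
max-pool) with the gathered graph vector.

Predictions are explained by **integrated gradients**: with score S (the
active-class logit) and M divisions (default 100),

    I(x) = (x / M) · Σₖ₌₁..M ∇S((k/M)·x)

and the per-atom importance is the row sum of I(x); rendering paints atoms
red (positive contribution) to blue (negative). Hyper-parameters (number of
convolution/dense layers, dropout rate, learning rate) are tuned by Bayesian
optimization with a Gaussian-process surrogate and expected improvement,
scored by cross-validated mean ROC-AUC.

## Worked example

The built-in synthetic benchmark plants a substructure→activity rule: half
of 200 generated molecules carry a hydroxamic-acid-like motif `C(=O)NO`
(the canonical zinc-binding group of matrix-metalloprotease inhibitors) and
are labelled active, with 5% label noise.

```python
import molgcn as mg

fx = mg.generate_fixture(mg.FixtureSpec(n_molecules=200, label_noise=0.05, seed=7))
data = mg.assemble_dataset(fx.records, fx.labels)
train, test = mg.split_dataset(data, test_fraction=0.2, seed=7)

results = mg.GraphConvModel(mg.default_model_spec(seed=0), train).fit(epochs=60, seed=0)
print(results.summary())

auc = mg.evaluate_auc(results.predict(test), test.labels, test.label_mask)
print(f"held-out ROC-AUC: {auc[0]:.3f}")

att = mg.integrated_gradients(results.trained, data.graphs[0], task=0, M=100)
print(f"score S(x)={att.score:.3f}, completeness gap={att.completeness_gap:.4f}")
```

prints

```
Graph Convolutional Classifier Results
======================================================
No. compounds:            160
No. tasks:                1
Bond types:               single, double, triple, aromatic
Atom features:            16
No. parameters:           3202
Epochs:                   60
Loss (first -> final):    12.3990 -> 0.1829
------------------------------------------------------
layer          out_dim  activation  batch_norm
graph_conv          32        relu        True
graph_dense         32        relu       False
graph_gather         -    identity       False
dense                2     softmax       False
------------------------------------------------------
train ROC-AUC task0:      0.974

held-out ROC-AUC: 1.000
score S(x)=3.592, completeness gap=0.0348
```

The model recovers the planted rule on held-out molecules (ROC-AUC 1.000
here), and the attribution's top-ranked atoms ([17, 18, 16] for the first
molecule) fall inside its true motif atoms (15–18): the classifier is right
*for the right atoms*. `mg.render_importance(record, att.atom_importance,
"mol.svg")` writes the red/blue depiction plus a JSON sidecar.

The same pipeline runs from the shell:

```bash
molgcn preprocess --smiles mols.smi --labels labels.csv --tasks task0 --out data.npz
molgcn run train     --dataset data.npz --out-dir model/ --epochs 60
molgcn run predict   --dataset data.npz --model model/model.npz --out-dir pred/
molgcn run cv        --dataset data.npz --out-dir cv/ --k 5
molgcn run visualize --dataset data.npz --model model/model.npz --out-dir viz/
molgcn opt           --dataset data.npz --out-dir opt/ --n-initial 5 --n-iterations 15
```

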