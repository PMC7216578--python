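"""Integrated-gradients attribution over atom features, and rendering.

For a trained model with score function ``S`` (by default the pre-softmax
logit of the attributed task's active class) and an input feature matrix
``x``, the attribution is the right-endpoint Riemann approximation of the
path integral from the all-zero baseline to ``x``::

    I(x) = (x / M) * sum_{k=1..M} grad S( (k/M) * x )

with ``M = 100`` divisions by default.  Only the feature matrix is scaled
along the path; the adjacency structure is fixed (it is a discrete graph,
not a differentiable input).  The per-atom importance is the row sum of
``I(x)``, and completeness — ``sum I(x) ~= S(x) - S(0)`` — holds in the
limit of large ``M``; the residual is reported as ``completeness_gap``.

Rendering paints atoms on a symmetric diverging scale: red for positive
contribution to the predicted activity, blue for negative, white at zero.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from rdkit.Chem.Draw import rdMolDraw2D

from . import graphrep
from ._autograd import Tensor
from .errors import AttributionError, RenderError
from .gcncore import TrainedModel


@dataclass
class AttributionResult:
    """Per-feature IG values and derived per-atom importances for one molecule."""

    ig_values: np.ndarray  # (N, D)
    atom_importance: np.ndarray  # (N,)
    score: float  # S(x)
    baseline_score: float  # S(0)
    completeness_gap: float  # | sum(IG) - (S(x) - S(0)) |
    M: int
    task: int
    score_kind: str = "logit"

    def to_dict(self) -> dict:
        return {
            "atom_importance": [float(v) for v in self.atom_importance],
            "score": self.score,
            "baseline_score": self.baseline_score,
            "completeness_gap": self.completeness_gap,
            "M": self.M,
            "task": self.task,
            "score_kind": self.score_kind,
        }


def _score(model: TrainedModel, batch: graphrep.GraphBatch, features: Tensor,
           task: int, modalities, score_kind: str) -> Tensor:
    logits = model.logits(batch, modalities=modalities, features=features)
    active = logits[0, task, 1]
    if score_kind == "logit":
        return active
    if score_kind == "prob":
        inactive = logits[0, task, 0]
        return (active - inactive).sigmoid()  # softmax over 2 classes
    raise AttributionError(f"unknown score kind {score_kind!r}")


def integrated_gradients(
    model: TrainedModel,
    graph: graphrep.NormalizedGraph | graphrep.MolecularGraph,
    task: int = 0,
    M: int = 100,
    modalities: dict[str, np.ndarray] | None = None,
    score_kind: str = "logit",
) -> AttributionResult:
    """Attribute one molecule's prediction to its input feature entries.

    ``modalities`` (per-compound rows, batch of one) are held at their actual
    values while the compound features are scaled — so the attribution covers
    compound atoms only, also for multi-modal models.
    """
    if M < 1:
        raise AttributionError("M must be >= 1")
    if not 0 <= task < model.spec.n_tasks:
        raise AttributionError(f"task index {task} out of range (n_tasks={model.spec.n_tasks})")
    if isinstance(graph, graphrep.MolecularGraph):
        graph = graphrep.normalize_adjacency(graph)
    batch = graphrep.pad_and_batch([graph])
    x = batch.features.copy()  # (1, N, D)
    grad_sum = np.zeros_like(x)
    for k in range(1, M + 1):
        xt = Tensor(x * (k / M), requires_grad=True)
        s = _score(model, batch, xt, task, modalities, score_kind)
        s.backward()
        grad_sum += xt.grad
    ig = (x / M) * grad_sum
    score = float(_score(model, batch, Tensor(x), task, modalities, score_kind).data)
    baseline = float(_score(model, batch, Tensor(np.zeros_like(x)), task, modalities,
                            score_kind).data)
    ig2d = ig[0]
    return AttributionResult(
        ig_values=ig2d,
        atom_importance=ig2d.sum(axis=1),
        score=score,
        baseline_score=baseline,
        completeness_gap=abs(float(ig2d.sum()) - (score - baseline)),
        M=M,
        task=task,
        score_kind=score_kind,
    )


def atom_importance(result: AttributionResult) -> np.ndarray:
    """Per-atom importance: the sum of each atom's IG values over its features."""
    return result.ig_values.sum(axis=1)


def _diverging_color(v: float) -> tuple[float, float, float]:
    # v in [-1, 1]: -1 -> blue, 0 -> white, +1 -> red
    if v >= 0:
        return (1.0, 1.0 - v, 1.0 - v)
    return (1.0 + v, 1.0 + v, 1.0)


def render_importance(record, importance: np.ndarray, out_path: str,
                      sidecar: dict | None = None) -> str:
    """Draw the molecule with atoms colored by importance; write SVG/PNG by
    extension plus a JSON sidecar with the per-atom values.  Returns the
    sidecar path."""
    mol = record.structure
    importance = np.asarray(importance, dtype=float)
    if importance.shape != (mol.GetNumAtoms(),):
        raise RenderError(
            f"importance length {importance.size} != heavy-atom count {mol.GetNumAtoms()}"
        )
    scale = float(np.max(np.abs(importance)))
    rel = importance / scale if scale > 0 else np.zeros_like(importance)
    colors = {i: _diverging_color(float(v)) for i, v in enumerate(rel)}
    ext = os.path.splitext(out_path)[1].lower()
    if ext == ".svg":
        drawer = rdMolDraw2D.MolDraw2DSVG(400, 400)
    elif ext == ".png":
        drawer = rdMolDraw2D.MolDraw2DCairo(400, 400)
    else:
        raise RenderError(f"unsupported image extension {ext!r} (use .svg or .png)")
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol,
        highlightAtoms=list(range(mol.GetNumAtoms())),
        highlightAtomColors=colors,
        highlightBonds=[],
    )
    drawer.FinishDrawing()
    data = drawer.GetDrawingText()
    mode = "w" if ext == ".svg" else "wb"
    with open(out_path, mode) as fh:
        fh.write(data)
    sidecar_path = os.path.splitext(out_path)[0] + ".json"
    payload = {"id": record.id, "atom_importance": [float(v) for v in importance]}
    payload.update(sidecar or {})
    with open(sidecar_path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
    return sidecar_path
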