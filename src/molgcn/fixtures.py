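"""Synthetic molecules with a planted substructure -> activity rule.

The generator assembles valence-valid SMILES by concatenating fragments from
a closed vocabulary (alkyl chains, ethers, amines, benzene/cyclohexane/
pyridine rings), then grafts an activity-defining motif — by default a
hydroxamic-acid-like group ``C(=O)NO``, the canonical zinc-binding moiety of
matrix-metalloprotease inhibitors — onto half of the molecules.  Labels are
motif presence, optionally corrupted by independent flips, so every pipeline
stage (training, cross-validation, attribution) can be exercised and scored
against a known ground truth: the motif atom indices of each molecule are
returned for attribution checks.

Decoy tail groups on the inactive half (plain amide, ester, alcohol) share
atoms and bonds with the motif, so activity is not predictable from element
counts alone — the model has to resolve the local bonding pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemio import CompoundRecord, LabelTable
from .errors import GenerationError
from .gcncore import roc_auc

DEFAULT_MOTIF = "C(=O)NO"  # -C(=O)NHOH with implicit hydrogens

_SCAFFOLD_FRAGMENTS = (
    "CC", "CCC", "CCCC", "COC", "CNC", "CCN", "CCO",
    "c1ccccc1", "C1CCCCC1", "c1ccncc1", "CC(C)C",
)
_DECOY_TAILS = ("C(=O)N", "C(=O)OC", "CO", "CN", "C(=O)C", "")


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic benchmark."""

    n_molecules: int = 200
    motif: str | list[str] = DEFAULT_MOTIF
    label_noise: float = 0.05
    n_tasks: int = 1
    seed: int = 0
    max_scaffold_fragments: int = 3

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise GenerationError("label_noise must lie in [0, 0.5)")
        if self.n_molecules < 10:
            raise GenerationError("n_molecules must be >= 10")
        motifs = self.motif if isinstance(self.motif, list) else [self.motif]
        if len(motifs) not in (1, self.n_tasks):
            raise GenerationError("motif must be shared or one per task")

    @property
    def motifs(self) -> list[str]:
        m = self.motif if isinstance(self.motif, list) else [self.motif]
        return m * self.n_tasks if len(m) == 1 else list(m)


@dataclass
class FixtureData:
    """Generated SMILES + labels + ground-truth motif atom indices."""

    smiles: list[str]
    records: list[CompoundRecord]
    labels: LabelTable
    motif_atoms: list[dict[int, tuple[int, ...]]]  # per molecule: task -> atom indices
    clean_labels: np.ndarray = field(default=None)  # pre-noise motif presence


def _random_scaffold(rng: np.random.Generator, max_fragments: int) -> str:
    n = int(rng.integers(1, max_fragments + 1))
    idx = rng.integers(0, len(_SCAFFOLD_FRAGMENTS), size=n)
    return "".join(_SCAFFOLD_FRAGMENTS[i] for i in idx)


def generate_fixture(spec: FixtureSpec) -> FixtureData:
    """Build the synthetic dataset; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    motifs = spec.motifs
    unique_motifs = sorted(set(motifs))
    patterns = {m: Chem.MolFromSmiles(m) for m in unique_motifs}
    if any(p is None for p in patterns.values()):
        raise GenerationError(f"unparseable motif in {unique_motifs}")

    smiles_list: list[str] = []
    records: list[CompoundRecord] = []
    motif_atoms: list[dict[int, tuple[int, ...]]] = []
    presence = np.zeros((spec.n_molecules, spec.n_tasks))
    for i in range(spec.n_molecules):
        active_any = i % 2 == 0  # first of each pair carries motif(s)
        for _attempt in range(50):
            scaffold = _random_scaffold(rng, spec.max_scaffold_fragments)
            if active_any:
                # graft every distinct motif (shared-motif specs have one)
                smi = scaffold + "".join(unique_motifs)
            else:
                smi = scaffold + _DECOY_TAILS[int(rng.integers(0, len(_DECOY_TAILS)))]
            mol = Chem.MolFromSmiles(smi)
            if mol is None or mol.GetNumAtoms() > 30:
                continue
            found = {m: mol.GetSubstructMatch(patterns[m]) for m in unique_motifs}
            ok = all(bool(found[m]) == active_any for m in unique_motifs)
            if ok:
                break
        else:
            raise GenerationError(f"could not build molecule {i} after 50 attempts")
        smiles_list.append(smi)
        records.append(CompoundRecord(id=f"mol{i}", structure=mol, source_index=i))
        per_task = {}
        for t in range(spec.n_tasks):
            match = found[motifs[t]]
            presence[i, t] = 1.0 if match else 0.0
            if match:
                per_task[t] = tuple(match)
        motif_atoms.append(per_task)

    flips = rng.random(presence.shape) < spec.label_noise
    labels = np.where(flips, 1.0 - presence, presence)
    table = LabelTable(
        compound_ids=[r.id for r in records],
        tasks=[f"task{t}" for t in range(spec.n_tasks)],
        values=labels,
    )
    return FixtureData(
        smiles=smiles_list,
        records=records,
        labels=table,
        motif_atoms=motif_atoms,
        clean_labels=presence,
    )


def motif_enrichment_score(importance: np.ndarray, motif_atoms) -> float:
    """Rank-based score in [0, 1]: the ROC-AUC of per-atom importances for
    motif atoms versus the molecule's remaining atoms (ties count half)."""
    importance = np.asarray(importance, dtype=float)
    motif = set(int(a) for a in motif_atoms)
    if not motif or not motif.issubset(range(importance.size)):
        raise ValueError("motif_atoms must be a nonempty subset of atom indices")
    if len(motif) == importance.size:
        return float("nan")
    labels = np.array([1.0 if i in motif else 0.0 for i in range(importance.size)])
    return roc_auc(importance, labels)
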