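"""Compound and label I/O, preprocessing filters, dataset assembly and splits.

Readers accept SDF (V2000 molblocks) and one-SMILES-per-line files; labels
come from a CSV with one row per compound and one {0, 1, empty} column per
task.  Preprocessing mirrors a common QSAR protocol: compounds with more
than ``max_atoms`` heavy atoms are removed, and per-task negatives can be
drawn from a pool to equalize positive/negative counts.  Splits and k-fold
assignments are seeded and reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from . import graphrep
from .errors import (
    BalanceError,
    EmptyDatasetError,
    InputError,
    SchemaError,
    SplitError,
    ValueCoercionError,
)

RDLogger.DisableLog("rdApp.*")  # parse failures are reported, not printed

MISSING = np.nan


@dataclass
class CompoundRecord:
    """A parsed compound: identifier, RDKit molecule, position in its file."""

    id: str
    structure: Chem.Mol
    source_index: int

    @property
    def n_heavy_atoms(self) -> int:
        return self.structure.GetNumAtoms()


@dataclass
class ParseReport:
    """Counts of parseable vs skipped entries for one input file."""

    n_read: int = 0
    n_skipped: int = 0
    skipped: list[int] = field(default_factory=list)  # 0-based source indices

    def to_dict(self) -> dict:
        return {"n_read": self.n_read, "n_skipped": self.n_skipped, "skipped": list(self.skipped)}


@dataclass
class LabelTable:
    """Per-compound binary task labels; NaN marks a missing value."""

    compound_ids: list[str]
    tasks: list[str]
    values: np.ndarray  # (n_compounds, n_tasks), entries in {0.0, 1.0, NaN}

    @property
    def mask(self) -> np.ndarray:
        return (~np.isnan(self.values)).astype(np.float64)

    def row(self, compound_id: str) -> np.ndarray:
        return self.values[self.compound_ids.index(compound_id)]


@dataclass
class GraphDataset:
    """Aligned graphs, labels with missingness mask, optional extra modalities."""

    graphs: list[graphrep.MolecularGraph]
    labels: np.ndarray  # (n, n_tasks) in {0, 1}; arbitrary where mask == 0
    label_mask: np.ndarray  # (n, n_tasks) in {0, 1}
    ids: list[str]
    tasks: list[str]
    feature_config: graphrep.FeatureConfig
    bond_types: tuple[str, ...] = graphrep.DEFAULT_BOND_TYPES
    modalities: dict[str, np.ndarray] = field(default_factory=dict)
    fold_assignment: np.ndarray | None = None
    molblocks: list[str] | None = None  # for later rendering; RDKit order preserved

    def __post_init__(self):
        n = len(self.graphs)
        if not (len(self.ids) == self.labels.shape[0] == self.label_mask.shape[0] == n):
            raise ValueError("per-compound fields must share length")

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def n_tasks(self) -> int:
        return self.labels.shape[1]

    def subset(self, indices) -> "GraphDataset":
        indices = np.asarray(indices, dtype=int)
        return GraphDataset(
            graphs=[self.graphs[i] for i in indices],
            labels=self.labels[indices].copy(),
            label_mask=self.label_mask[indices].copy(),
            ids=[self.ids[i] for i in indices],
            tasks=list(self.tasks),
            feature_config=self.feature_config,
            bond_types=self.bond_types,
            modalities={k: v[indices].copy() for k, v in self.modalities.items()},
            fold_assignment=None
            if self.fold_assignment is None
            else self.fold_assignment[indices].copy(),
            molblocks=None if self.molblocks is None else [self.molblocks[i] for i in indices],
        )


# ---------------------------------------------------------------------------
# readers


def read_sdf(path: str) -> tuple[list[CompoundRecord], ParseReport]:
    """Read an SDF file; unparseable molecule blocks are skipped and counted."""
    if not os.path.exists(path):
        raise InputError(f"SDF file not found: {path}")
    try:
        supplier = Chem.SDMolSupplier(path, removeHs=True, sanitize=True)
    except OSError as exc:  # e.g. an empty file with no molecule block at all
        raise EmptyDatasetError(f"no parseable molecules in {path}") from exc
    records, report = [], ParseReport()
    for i, mol in enumerate(supplier):
        if mol is None:
            report.n_skipped += 1
            report.skipped.append(i)
            continue
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        records.append(CompoundRecord(id=name or str(i), structure=mol, source_index=i))
        report.n_read += 1
    if not records:
        raise EmptyDatasetError(f"no parseable molecules in {path}")
    return records, report


def read_smiles(path: str) -> tuple[list[CompoundRecord], ParseReport]:
    """Read one SMILES per line; an optional second token is the compound id."""
    if not os.path.exists(path):
        raise InputError(f"SMILES file not found: {path}")
    records, report = [], ParseReport()
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    idx = -1
    for ln in lines:
        if not ln:
            continue
        idx += 1
        tokens = ln.split()
        mol = Chem.MolFromSmiles(tokens[0])
        if mol is None:
            report.n_skipped += 1
            report.skipped.append(idx)
            continue
        cid = tokens[1] if len(tokens) > 1 else str(idx)
        records.append(CompoundRecord(id=cid, structure=mol, source_index=idx))
        report.n_read += 1
    if not records:
        raise EmptyDatasetError(f"no parseable molecules in {path}")
    return records, report


def read_labels_csv(path: str, id_column: str, task_columns: list[str]) -> LabelTable:
    """Load binary task labels; empty cells become missing, anything else errors."""
    if not os.path.exists(path):
        raise InputError(f"label CSV not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in [id_column, *task_columns]:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} absent from {path}")
    ids = df[id_column].tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()].tolist()
    if dup:
        raise SchemaError(f"duplicate compound id(s): {sorted(set(dup))}")
    values = np.full((len(df), len(task_columns)), MISSING)
    for j, task in enumerate(task_columns):
        for i, cell in enumerate(df[task].tolist()):
            cell = cell.strip()
            if cell == "":
                continue
            if cell in ("0", "1"):
                values[i, j] = float(cell)
            else:
                raise ValueCoercionError(
                    f"row {i} ({ids[i]!r}), task {task!r}: non-binary value {cell!r}"
                )
    return LabelTable(compound_ids=ids, tasks=list(task_columns), values=values)


# ---------------------------------------------------------------------------
# preprocessing


def filter_by_atom_count(records: list[CompoundRecord], max_atoms: int = 50) -> list[CompoundRecord]:
    """Keep compounds with at most ``max_atoms`` heavy atoms (order preserved)."""
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    return [r for r in records if r.n_heavy_atoms <= max_atoms]


def assemble_dataset(
    records: list[CompoundRecord],
    labels: LabelTable,
    feature_config: graphrep.FeatureConfig | None = None,
    bond_types: tuple[str, ...] = graphrep.DEFAULT_BOND_TYPES,
    modalities: dict[str, np.ndarray] | None = None,
) -> GraphDataset:
    """Featurize records and align them with their label rows by compound id.

    Records without a label row, and rows with no observed value, are dropped.
    """
    cfg = feature_config or graphrep.FeatureConfig()
    index = {cid: i for i, cid in enumerate(labels.compound_ids)}
    graphs, rows, ids, kept_pos, blocks = [], [], [], [], []
    for pos, rec in enumerate(records):
        if rec.id not in index:
            continue
        row = labels.values[index[rec.id]]
        if np.all(np.isnan(row)):
            continue
        graphs.append(graphrep.featurize(rec, cfg, bond_types))
        rows.append(row)
        ids.append(rec.id)
        kept_pos.append(pos)
        blocks.append(Chem.MolToMolBlock(rec.structure))
    if not graphs:
        raise EmptyDatasetError("no compound has both a structure and an observed label")
    values = np.asarray(rows)
    mods = {}
    if modalities:
        keep = np.asarray(kept_pos, dtype=int)
        mods = {k: np.asarray(v)[keep] for k, v in modalities.items()}
    return GraphDataset(
        graphs=graphs,
        labels=np.nan_to_num(values, nan=0.0),
        label_mask=(~np.isnan(values)).astype(np.float64),
        ids=ids,
        tasks=list(labels.tasks),
        feature_config=cfg,
        bond_types=bond_types,
        modalities=mods,
        molblocks=blocks,
    )


def balance_negatives(
    dataset: GraphDataset,
    task: str,
    negative_pool: list[CompoundRecord],
    seed: int,
    max_atoms: int = 50,
) -> GraphDataset:
    """Equalize a task's negative count with its positive count.

    Negatives are drawn uniformly without replacement from ``negative_pool``
    (after the same heavy-atom filter applied to the dataset) until counts
    match; a dataset already at or above parity is returned unchanged.
    Appended compounds are labelled 0 for ``task`` and missing elsewhere.
    """
    t = dataset.tasks.index(task)
    obs = dataset.label_mask[:, t] == 1
    n_pos = int(np.sum(dataset.labels[obs, t] == 1))
    n_neg = int(np.sum(dataset.labels[obs, t] == 0))
    if n_pos < 1:
        raise BalanceError(f"task {task!r} has no observed positives")
    if n_neg >= n_pos:
        return dataset
    need = n_pos - n_neg
    pool = [r for r in filter_by_atom_count(negative_pool, max_atoms) if r.id not in set(dataset.ids)]
    if len(pool) < need:
        raise BalanceError(
            f"task {task!r}: need {need} negatives but pool holds {len(pool)} (shortfall {need - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=need, replace=False)]
    new_graphs = [graphrep.featurize(r, dataset.feature_config, dataset.bond_types) for r in chosen]
    add_labels = np.zeros((need, dataset.n_tasks))
    add_mask = np.zeros((need, dataset.n_tasks))
    add_mask[:, t] = 1.0
    if dataset.modalities:
        raise BalanceError("cannot balance a dataset with extra modalities (no pool values)")
    return GraphDataset(
        graphs=dataset.graphs + new_graphs,
        labels=np.vstack([dataset.labels, add_labels]),
        label_mask=np.vstack([dataset.label_mask, add_mask]),
        ids=dataset.ids + [r.id for r in chosen],
        tasks=list(dataset.tasks),
        feature_config=dataset.feature_config,
        bond_types=dataset.bond_types,
        molblocks=None
        if dataset.molblocks is None
        else dataset.molblocks + [Chem.MolToMolBlock(r.structure) for r in chosen],
    )


# ---------------------------------------------------------------------------
# dataset archives

DATASET_VERSION = 1


def save_dataset(dataset: GraphDataset, path: str) -> None:
    """Write a versioned ``.npz`` dataset archive (labels + molblocks + config).

    Graphs are stored as V2000 molblocks (atom order preserved) and
    re-featurized on load with the archived feature configuration, so the
    archive stays compact and the featurization provenance explicit.
    """
    if dataset.molblocks is None:
        raise ValueError("dataset lacks molblocks; assemble it via assemble_dataset")
    meta = {
        "version": DATASET_VERSION,
        "ids": dataset.ids,
        "tasks": dataset.tasks,
        "feature_config": dataset.feature_config.to_dict(),
        "bond_types": list(dataset.bond_types),
        "molblocks": dataset.molblocks,
        "modality_names": sorted(dataset.modalities),
    }
    arrays = {
        "labels": dataset.labels,
        "label_mask": dataset.label_mask,
    }
    if dataset.fold_assignment is not None:
        arrays["fold_assignment"] = dataset.fold_assignment
    for name in sorted(dataset.modalities):
        arrays[f"modality/{name}"] = dataset.modalities[name]
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **arrays,
    )


def load_dataset(path: str) -> GraphDataset:
    if not os.path.exists(path):
        raise InputError(f"dataset archive not found: {path}")
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != DATASET_VERSION:
            raise SchemaError(f"unsupported dataset archive version in {path}")
        labels = z["labels"].copy()
        mask = z["label_mask"].copy()
        folds = z["fold_assignment"].copy() if "fold_assignment" in z.files else None
        modalities = {
            name: z[f"modality/{name}"].copy() for name in meta["modality_names"]
        }
    cfg = graphrep.FeatureConfig.from_dict(meta["feature_config"])
    bond_types = tuple(meta["bond_types"])
    graphs = []
    for i, block in enumerate(meta["molblocks"]):
        mol = Chem.MolFromMolBlock(block, removeHs=True)
        if mol is None:
            raise SchemaError(f"corrupt molblock for compound {meta['ids'][i]!r}")
        rec = CompoundRecord(id=meta["ids"][i], structure=mol, source_index=i)
        graphs.append(graphrep.featurize(rec, cfg, bond_types))
    return GraphDataset(
        graphs=graphs,
        labels=labels,
        label_mask=mask,
        ids=list(meta["ids"]),
        tasks=list(meta["tasks"]),
        feature_config=cfg,
        bond_types=bond_types,
        modalities=modalities,
        fold_assignment=folds,
        molblocks=list(meta["molblocks"]),
    )


def records_from_dataset(dataset: GraphDataset) -> list[CompoundRecord]:
    """Rebuild CompoundRecords (RDKit atom order preserved) from molblocks."""
    if dataset.molblocks is None:
        raise ValueError("dataset lacks molblocks")
    out = []
    for i, (cid, block) in enumerate(zip(dataset.ids, dataset.molblocks)):
        mol = Chem.MolFromMolBlock(block, removeHs=True)
        out.append(CompoundRecord(id=cid, structure=mol, source_index=i))
    return out


# ---------------------------------------------------------------------------
# splits


def split_dataset(
    dataset: GraphDataset, test_fraction: float, seed: int
) -> tuple[GraphDataset, GraphDataset]:
    """Seeded disjoint train/test partition with ``round(n * test_fraction)`` test rows."""
    if not 0 < test_fraction < 1:
        raise SplitError("test_fraction must lie strictly between 0 and 1")
    n = len(dataset)
    n_test = int(round(n * test_fraction))
    if n_test == 0 or n_test == n:
        raise SplitError(f"split of n={n} at fraction {test_fraction} leaves an empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    return dataset.subset(np.sort(perm[n_test:])), dataset.subset(np.sort(perm[:n_test]))


def make_cv_folds(dataset: GraphDataset, k: int, seed: int) -> GraphDataset:
    """Assign each compound to one of ``k`` folds; sizes differ by at most one."""
    n = len(dataset)
    if k < 2 or n < k:
        raise SplitError(f"cannot make {k} folds from {n} compounds")
    perm = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % k
    out = dataset.subset(np.arange(n))
    out.fold_assignment = assignment
    return out
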