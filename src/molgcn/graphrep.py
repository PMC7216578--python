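"""Molecule-to-graph featurization.

A molecule with ``N`` heavy atoms becomes a pair ``(A, F)``:

* ``A`` — one binary ``N x N`` adjacency matrix per bond type ``t`` (single,
  double, triple, aromatic by default), with ``A[t][i, j] = 1`` iff a bond of
  type ``t`` joins atoms ``i`` and ``j``.  Diagonals are zero; self-loops are
  introduced only by normalization.
* ``F`` — an ``N x D`` atom-feature matrix whose blocks (element one-hot,
  formal charge, hybridization one-hot, degree one-hot, aromaticity flag)
  are chosen by a :class:`FeatureConfig`.

Normalization follows the renormalization trick of Kipf & Welling:
``Atilde = Dtilde^{-1/2} (A + I) Dtilde^{-1/2}`` applied per bond type, with
``Dtilde`` the degree matrix of ``A + I``.

Hydrogens are implicit throughout: graphs are built on the heavy-atom
skeleton, which is also the convention used by the atom-count filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem

from .errors import FeaturizationError, SpecError

DEFAULT_BOND_TYPES: tuple[str, ...] = ("single", "double", "triple", "aromatic")

_RDKIT_BOND_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

_HYBRIDIZATIONS = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


@dataclass
class FeatureConfig:
    """Which atom-property blocks enter the feature matrix, and their widths.

    ``blocks`` is an ordered subset of {"element", "formal_charge",
    "hybridization", "degree", "aromatic"}.  Out-of-vocabulary elements and
    hybridizations map to a trailing "other" slot.  The config is serialized
    with every trained model so featurization is reproducible at predict time.
    """

    blocks: tuple[str, ...] = ("element", "formal_charge", "hybridization", "aromatic")
    element_vocab: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
    hybridization_vocab: tuple[str, ...] = ("sp", "sp2", "sp3")
    max_degree: int = 5
    _KNOWN = ("element", "formal_charge", "hybridization", "degree", "aromatic")

    def __post_init__(self):
        if not self.blocks:
            raise SpecError("feature_config must list at least one block")
        for b in self.blocks:
            if b not in self._KNOWN:
                raise SpecError(f"unknown feature block {b!r}")

    @property
    def n_features(self) -> int:
        widths = {
            "element": len(self.element_vocab) + 1,
            "formal_charge": 1,
            "hybridization": len(self.hybridization_vocab) + 1,
            "degree": self.max_degree + 1,
            "aromatic": 1,
        }
        return sum(widths[b] for b in self.blocks)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("blocks", "element_vocab", "hybridization_vocab"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            blocks=tuple(d["blocks"]),
            element_vocab=tuple(d["element_vocab"]),
            hybridization_vocab=tuple(d["hybridization_vocab"]),
            max_degree=int(d["max_degree"]),
        )


@dataclass
class MolecularGraph:
    """One compound as per-bond-type adjacency + atom features."""

    n_nodes: int
    adjacency: dict[str, np.ndarray]
    features: np.ndarray
    atom_symbols: list[str]
    id: str


@dataclass
class NormalizedGraph:
    """Degree-normalized adjacency (self-loops folded in) + features."""

    n_nodes: int
    norm_adjacency: dict[str, np.ndarray]
    features: np.ndarray
    atom_symbols: list[str] = field(default_factory=list)
    id: str = ""


@dataclass
class GraphBatch:
    """Zero-padded dense batch of normalized graphs."""

    max_nodes: int
    bond_types: tuple[str, ...]
    adjacency: np.ndarray  # (B, |T|, max_nodes, max_nodes)
    features: np.ndarray  # (B, max_nodes, D)
    node_mask: np.ndarray  # (B, max_nodes)
    ids: list[str]

    def __len__(self) -> int:
        return self.features.shape[0]


def build_adjacency(record, bond_types: tuple[str, ...] = DEFAULT_BOND_TYPES) -> dict[str, np.ndarray]:
    """Per-bond-type binary adjacency matrices for one compound.

    Atom indexing is 0-based in RDKit order.  A bond whose type is outside
    ``bond_types`` raises :class:`FeaturizationError` naming the type.
    """
    mol = record.structure
    n = mol.GetNumAtoms()
    adj = {t: np.zeros((n, n), dtype=np.float64) for t in bond_types}
    for bond in mol.GetBonds():
        name = _RDKIT_BOND_NAMES.get(bond.GetBondType())
        if name is None or name not in adj:
            label = name or str(bond.GetBondType())
            raise FeaturizationError(
                f"molecule {record.id!r}: bond type {label!r} not in configured set {bond_types}"
            )
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[name][i, j] = adj[name][j, i] = 1.0
    return adj


def extract_atom_features(record, feature_config: FeatureConfig | None = None) -> np.ndarray:
    """``N x D`` feature matrix with rows in atom-index order."""
    cfg = feature_config or FeatureConfig()
    mol = record.structure
    rows = []
    for atom in mol.GetAtoms():
        parts = []
        for block in cfg.blocks:
            if block == "element":
                v = np.zeros(len(cfg.element_vocab) + 1)
                sym = atom.GetSymbol()
                v[cfg.element_vocab.index(sym) if sym in cfg.element_vocab else -1] = 1.0
                parts.append(v)
            elif block == "formal_charge":
                parts.append(np.array([float(atom.GetFormalCharge())]))
            elif block == "hybridization":
                v = np.zeros(len(cfg.hybridization_vocab) + 1)
                name = _HYBRIDIZATIONS.get(atom.GetHybridization())
                v[cfg.hybridization_vocab.index(name) if name in cfg.hybridization_vocab else -1] = 1.0
                parts.append(v)
            elif block == "degree":
                v = np.zeros(cfg.max_degree + 1)
                v[min(atom.GetDegree(), cfg.max_degree)] = 1.0
                parts.append(v)
            elif block == "aromatic":
                parts.append(np.array([1.0 if atom.GetIsAromatic() else 0.0]))
        rows.append(np.concatenate(parts))
    return np.asarray(rows, dtype=np.float64).reshape(mol.GetNumAtoms(), cfg.n_features)


def featurize(
    record,
    feature_config: FeatureConfig | None = None,
    bond_types: tuple[str, ...] = DEFAULT_BOND_TYPES,
) -> MolecularGraph:
    """Assemble the full ``(A, F)`` representation for one compound."""
    mol = record.structure
    return MolecularGraph(
        n_nodes=mol.GetNumAtoms(),
        adjacency=build_adjacency(record, bond_types),
        features=extract_atom_features(record, feature_config),
        atom_symbols=[a.GetSymbol() for a in mol.GetAtoms()],
        id=record.id,
    )


def normalize_adjacency(graph: MolecularGraph) -> NormalizedGraph:
    """Kipf renormalization per bond type: ``Dtilde^{-1/2}(A+I)Dtilde^{-1/2}``."""
    n = graph.n_nodes
    eye = np.eye(n)
    norm = {}
    for t, a in graph.adjacency.items():
        a_hat = a + eye
        d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
        norm[t] = a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return NormalizedGraph(
        n_nodes=n,
        norm_adjacency=norm,
        features=graph.features.copy(),
        atom_symbols=list(graph.atom_symbols),
        id=graph.id,
    )


def pad_and_batch(graphs: list[NormalizedGraph], max_nodes: int | str = "auto") -> GraphBatch:
    """Zero-pad normalized graphs to a common node count and stack them."""
    if not graphs:
        raise ValueError("cannot batch zero graphs")
    bond_types = tuple(graphs[0].norm_adjacency.keys())
    if max_nodes == "auto":
        max_nodes = max(g.n_nodes for g in graphs)
    for g in graphs:
        if g.n_nodes > max_nodes:
            raise ValueError(f"graph {g.id!r} has {g.n_nodes} nodes > max_nodes={max_nodes}")
    b, d = len(graphs), graphs[0].features.shape[1]
    adjacency = np.zeros((b, len(bond_types), max_nodes, max_nodes))
    features = np.zeros((b, max_nodes, d))
    node_mask = np.zeros((b, max_nodes))
    for gi, g in enumerate(graphs):
        n = g.n_nodes
        for ti, t in enumerate(bond_types):
            adjacency[gi, ti, :n, :n] = g.norm_adjacency[t]
        features[gi, :n, :] = g.features
        node_mask[gi, :n] = 1.0
    return GraphBatch(
        max_nodes=int(max_nodes),
        bond_types=bond_types,
        adjacency=adjacency,
        features=features,
        node_mask=node_mask,
        ids=[g.id for g in graphs],
    )


def unbatch(batch: GraphBatch) -> list[NormalizedGraph]:
    """Recover each graph exactly from a padded batch."""
    out = []
    for gi in range(len(batch)):
        n = int(batch.node_mask[gi].sum())
        out.append(
            NormalizedGraph(
                n_nodes=n,
                norm_adjacency={
                    t: batch.adjacency[gi, ti, :n, :n].copy()
                    for ti, t in enumerate(batch.bond_types)
                },
                features=batch.features[gi, :n, :].copy(),
                id=batch.ids[gi],
            )
        )
    return out
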