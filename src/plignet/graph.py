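"""Protein-ligand interaction graph (PLIG) assembly and serialization.

The model input is a graph with the topology of the ligand: one node per
ligand heavy atom, one undirected edge per covalent bond.  Node features
concatenate, in order,

* a 10-slot element one-hot over (B, C, N, O, F, P, S, Cl, Br, I),
* five scalar atom descriptors (valence, heavy degree, H count,
  aromaticity, ring membership),
* the atom's radial AEV (length 352 with defaults),

for a default node width of 10 + 5 + 352 = 367.  Edge features are a
4-slot bond-order one-hot over (single, aromatic, double, triple).  The
protein enters only through the AEV block, so the graph is invariant to
rigid motions and mirrors of the complex and to protein atom reordering.

Graphs are stored in a self-describing, versioned NPZ container
("plignet-graphs" format, version 1): flat feature/edge arrays with
per-graph offsets plus a JSON header carrying ids, labels and the
AEV parameters.  Round-trips are bit-exact.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .aev import AEVParams, compute_radial_aevs
from .complex_io import BOND_ORDERS, ComplexRecord, LIGAND_ELEMENTS

FORMAT_NAME = "plignet-graphs"
FORMAT_VERSION = 1

_ELEMENT_SLOT = {e: i for i, e in enumerate(LIGAND_ELEMENTS)}
_ORDER_SLOT = {o: i for i, o in enumerate(BOND_ORDERS)}

N_DESCRIPTORS = 5


def node_feature_length(params: AEVParams = AEVParams()) -> int:
    return len(LIGAND_ELEMENTS) + N_DESCRIPTORS + params.length


@dataclass
class PLIGraph:
    """One featurized complex: node features, bond edges, optional pK label."""

    node_features: np.ndarray          # (n_nodes, D) float64
    edges: np.ndarray                  # (n_edges, 2) int, undirected, stored once
    edge_features: np.ndarray          # (n_edges, 4) float64 one-hot
    label: Optional[float] = None
    ids: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.edge_features = np.asarray(self.edge_features, dtype=float).reshape(
            -1, len(BOND_ORDERS)
        )
        n = self.node_features.shape[0]
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge references missing node")
        if self.edges.shape[0] != self.edge_features.shape[0]:
            raise ValueError("edge/edge-feature count mismatch")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def build_graph(
    complex_record: ComplexRecord, params: AEVParams = AEVParams()
) -> PLIGraph:
    """Assemble the PLIG for one complex; node order = ligand atom order."""
    lig = complex_record.ligand
    if lig.n_atoms < 1:
        raise ValueError("ligand has no heavy atoms")
    coords = lig.coords
    if not np.all(np.isfinite(coords)):
        raise ValueError("ligand coordinates missing or non-finite")
    if not np.all(np.isfinite(complex_record.protein.coords)):
        raise ValueError("protein coordinates missing or non-finite")

    aevs = compute_radial_aevs(coords, complex_record.protein, params)
    n = lig.n_atoms
    feats = np.zeros((n, node_feature_length(params)))
    for i, atom in enumerate(lig.atoms):
        feats[i, _ELEMENT_SLOT[atom.element]] = 1.0
        feats[i, 10:15] = (
            atom.explicit_valence,
            atom.heavy_degree,
            atom.h_count,
            float(atom.is_aromatic),
            float(atom.in_ring),
        )
    feats[:, 15:] = aevs

    edges = np.array([(i, j) for i, j, _ in lig.bonds], dtype=int).reshape(-1, 2)
    efeat = np.zeros((len(lig.bonds), len(BOND_ORDERS)))
    for k, (_, _, order) in enumerate(lig.bonds):
        efeat[k, _ORDER_SLOT[order]] = 1.0

    ids = {"complex_id": complex_record.complex_id,
           "target_id": complex_record.target_id}
    if complex_record.series_id is not None:
        ids["series_id"] = complex_record.series_id
    return PLIGraph(feats, edges, efeat, label=complex_record.pk, ids=ids)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

class GraphFormatError(ValueError):
    pass


def serialize_graphs(
    graphs: Sequence[PLIGraph], path: str, params: Optional[AEVParams] = None
) -> None:
    """Write graphs to a versioned NPZ container (lossless)."""
    node_counts = np.array([g.n_nodes for g in graphs], dtype=int)
    edge_counts = np.array([g.n_edges for g in graphs], dtype=int)
    width = graphs[0].node_features.shape[1] if graphs else 0
    header = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "n_graphs": len(graphs),
        "node_width": width,
        "labels": [g.label for g in graphs],
        "ids": [g.ids for g in graphs],
        "aev_params": params.to_dict() if params is not None else None,
    }
    arrays = {
        "node_counts": node_counts,
        "edge_counts": edge_counts,
        "node_features": (
            np.concatenate([g.node_features for g in graphs], axis=0)
            if graphs else np.zeros((0, 0))
        ),
        "edges": (
            np.concatenate([g.edges for g in graphs], axis=0)
            if graphs else np.zeros((0, 2), dtype=int)
        ),
        "edge_features": (
            np.concatenate([g.edge_features for g in graphs], axis=0)
            if graphs else np.zeros((0, len(BOND_ORDERS)))
        ),
        "header": np.frombuffer(
            json.dumps(header).encode("utf-8"), dtype=np.uint8
        ).copy(),
    }
    # write through a handle so the given filename is used verbatim
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def deserialize_graphs(path: str) -> list[PLIGraph]:
    """Read a graph container written by :func:`serialize_graphs`."""
    try:
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
    except (OSError, ValueError, zipfile.BadZipFile, KeyError) as exc:
        raise GraphFormatError(f"cannot read graph container {path}: {exc}") from exc
    try:
        header = json.loads(bytes(arrays["header"]).decode("utf-8"))
    except (KeyError, ValueError) as exc:
        raise GraphFormatError(f"missing/corrupt header in {path}: {exc}") from exc
    if header.get("format") != FORMAT_NAME:
        raise GraphFormatError(f"not a {FORMAT_NAME} container: {path}")
    if header.get("version") != FORMAT_VERSION:
        raise GraphFormatError(
            f"container version {header.get('version')} != supported {FORMAT_VERSION}"
        )
    node_counts = arrays["node_counts"]
    edge_counts = arrays["edge_counts"]
    if int(node_counts.sum()) != arrays["node_features"].shape[0]:
        raise GraphFormatError(f"truncated node data in {path}")
    if int(edge_counts.sum()) != arrays["edges"].shape[0]:
        raise GraphFormatError(f"truncated edge data in {path}")
    graphs = []
    n_off = e_off = 0
    for k in range(int(header["n_graphs"])):
        nn, ne = int(node_counts[k]), int(edge_counts[k])
        graphs.append(
            PLIGraph(
                arrays["node_features"][n_off:n_off + nn],
                arrays["edges"][e_off:e_off + ne],
                arrays["edge_features"][e_off:e_off + ne],
                label=header["labels"][k],
                ids=header["ids"][k],
            )
        )
        n_off += nn
        e_off += ne
    return graphs


def container_aev_params(path: str) -> Optional[AEVParams]:
    """AEV parameters recorded in a graph container, if any."""
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(bytes(data["header"]).decode("utf-8"))
    d = header.get("aev_params")
    return AEVParams.from_dict(d) if d else None
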