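"""Graph attention network for binding-affinity regression.

Architecture: five GATv2 layers, each with three attention heads whose
outputs are concatenated; global pooling concatenating elementwise max and
mean over nodes; and a four-layer MLP ending in a single pK output.  The
model prediction is the arithmetic mean of an ensemble of identically
configured members trained from different random seeds.

Per head, with source/target/edge transforms W_s, W_t, W_e and attention
vector b (all learnable, shared over the layer), the attention coefficient
of neighbour v for centre node u is

    a_uv = softmax_{k in N(u) u {u}} b^T LeakyReLU(W_s x_u + W_t x_k + W_e e_uk)

and the updated node feature is h_u = sigma( sum_v a_uv W_t x_v ).
Self-loops carry a zero edge-feature vector (a self-loop has no bond
order).  sigma is ReLU between layers; the LeakyReLU inside the attention
uses negative slope 0.2.  The MLP input width is derived from the pooled
dimension (2 x heads x head_dim); with the published head width 256 that is
1536.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .graph import PLIGraph
from .nn import Tensor

CHECKPOINT_FORMAT = "plignet-ensemble"
CHECKPOINT_VERSION = 1

DEFAULT_SEEDS = tuple(range(10))


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 5
    n_heads: int = 3
    head_dim: int = 256
    mlp_hidden: tuple[int, ...] = (1024, 512, 256)
    activation: str = "relu"
    leaky_slope: float = 0.2
    ensemble_size: int = 10
    seed_list: tuple[int, ...] = DEFAULT_SEEDS

    def __post_init__(self):
        if self.ensemble_size != len(self.seed_list):
            raise ValueError("ensemble_size must equal len(seed_list)")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unsupported activation {self.activation!r}")

    @property
    def node_width(self) -> int:
        """Post-layer node width (heads concatenated)."""
        return self.n_heads * self.head_dim

    @property
    def pooled_width(self) -> int:
        """Max+mean pooled graph-vector width."""
        return 2 * self.node_width

    def to_dict(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "head_dim": self.head_dim,
            "mlp_hidden": list(self.mlp_hidden),
            "activation": self.activation,
            "leaky_slope": self.leaky_slope,
            "ensemble_size": self.ensemble_size,
            "seed_list": list(self.seed_list),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["mlp_hidden"] = tuple(d["mlp_hidden"])
        d["seed_list"] = tuple(d["seed_list"])
        return cls(**d)


@dataclass
class EnsemblePrediction:
    mean_pk: np.ndarray       # (n_graphs,)
    member_pks: np.ndarray    # (n_members, n_graphs)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """Several graphs packed as one disjoint union.

    ``src``/``dst`` are directed edges (both directions per bond) plus one
    self-loop per node with a zero edge-feature row; the neighbourhood of u
    in the attention sum is exactly {v : (src=v, dst=u)}.
    """

    x: np.ndarray             # (n_nodes, D)
    src: np.ndarray           # (n_dir_edges,)
    dst: np.ndarray
    edge_attr: np.ndarray     # (n_dir_edges, 4)
    node_graph: np.ndarray    # (n_nodes,) graph id per node
    n_graphs: int
    labels: Optional[np.ndarray] = None


def pack_batch(graphs: Sequence[PLIGraph]) -> Batch:
    xs, srcs, dsts, eattrs, gids = [], [], [], [], []
    labels = []
    offset = 0
    edge_dim = graphs[0].edge_features.shape[1] if graphs else 4
    for gid, g in enumerate(graphs):
        n = g.n_nodes
        xs.append(g.node_features)
        if g.n_edges:
            e = g.edges + offset
            srcs.extend([e[:, 0], e[:, 1]])
            dsts.extend([e[:, 1], e[:, 0]])
            eattrs.extend([g.edge_features, g.edge_features])
        loop = np.arange(offset, offset + n)
        srcs.append(loop)
        dsts.append(loop)
        eattrs.append(np.zeros((n, edge_dim)))
        gids.append(np.full(n, gid))
        labels.append(g.label)
        offset += n
    return Batch(
        x=np.concatenate(xs, axis=0),
        src=np.concatenate(srcs),
        dst=np.concatenate(dsts),
        edge_attr=np.concatenate(eattrs, axis=0),
        node_graph=np.concatenate(gids),
        n_graphs=len(graphs),
        labels=(np.array([l for l in labels], dtype=float)
                if all(l is not None for l in labels) else None),
    )


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def attention_coefficients(
    x: np.ndarray,
    src: np.ndarray,
    dst: np.ndarray,
    edge_attr: np.ndarray,
    Ws: np.ndarray,
    Wt: np.ndarray,
    We: np.ndarray,
    b: np.ndarray,
    leaky_slope: float = 0.2,
) -> np.ndarray:
    """Attention coefficients a_uv per directed edge (numpy, inference-only).

    Softmax is taken over all edges sharing a destination (centre) node;
    with self-loops included, the coefficients for each node sum to 1.
    """
    xs = x @ Ws
    xt = x @ Wt
    xe = edge_attr @ We
    z = xs[dst] + xt[src] + xe
    score = (np.where(z > 0, z, leaky_slope * z) @ b).reshape(-1)
    n = x.shape[0]
    m = np.full(n, -np.inf)
    np.maximum.at(m, dst, score)
    ez = np.exp(score - m[dst])
    denom = np.zeros(n)
    np.add.at(denom, dst, ez)
    return ez / denom[dst]


class GATv2Model:
    """One ensemble member: 5x GATv2 (3 heads) + max/mean pool + MLP."""

    def __init__(self, node_dim: int, edge_dim: int = 4,
                 config: ModelConfig = ModelConfig(), seed: int = 0):
        self.node_dim = node_dim
        self.edge_dim = edge_dim
        self.config = config
        self.seed = seed
        # optional per-feature affine normalisation fitted by the trainer
        self.feature_loc: Optional[np.ndarray] = None
        self.feature_scale: Optional[np.ndarray] = None
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        d_in = node_dim
        dh = config.head_dim
        for layer in range(config.n_layers):
            for head in range(config.n_heads):
                p = f"l{layer}h{head}"
                self.params[f"{p}_Ws"] = nn.glorot_uniform(rng, d_in, dh)
                self.params[f"{p}_Wt"] = nn.glorot_uniform(rng, d_in, dh)
                self.params[f"{p}_We"] = nn.glorot_uniform(rng, edge_dim, dh)
                self.params[f"{p}_b"] = nn.glorot_uniform(rng, dh, 1)
            d_in = config.node_width
        dims = (config.pooled_width,) + config.mlp_hidden + (1,)
        for k, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.params[f"mlp{k}_W"] = nn.glorot_uniform(rng, a, b)
            self.params[f"mlp{k}_b"] = Tensor(np.zeros((1, b)), requires_grad=True)

    # -- forward ----------------------------------------------------------

    def _activation(self, t: Tensor) -> Tensor:
        if self.config.activation == "relu":
            return nn.relu(t)
        return nn.leaky_relu(t, self.config.leaky_slope)

    def _layer(self, layer: int, x: Tensor, batch: Batch, e: Tensor) -> Tensor:
        cfg = self.config
        n = x.shape[0]
        heads = []
        for head in range(cfg.n_heads):
            p = f"l{layer}h{head}"
            xs = x @ self.params[f"{p}_Ws"]
            xt = x @ self.params[f"{p}_Wt"]
            xe = e @ self.params[f"{p}_We"]
            z = nn.gather_rows(xs, batch.dst) + nn.gather_rows(xt, batch.src) + xe
            score = nn.leaky_relu(z, cfg.leaky_slope) @ self.params[f"{p}_b"]
            # stabilising shift; constant w.r.t. gradients
            m = np.full(n, -np.inf)
            np.maximum.at(m, batch.dst, score.data[:, 0])
            ez = nn.exp(score - Tensor(m[batch.dst][:, None]))
            denom = nn.segment_sum(ez, batch.dst, n)
            a = ez / nn.gather_rows(denom, batch.dst)
            msg = a * nn.gather_rows(xt, batch.src)
            heads.append(nn.segment_sum(msg, batch.dst, n))
        return self._activation(nn.concat(heads, axis=1))

    def forward(self, batch: Batch) -> Tensor:
        if batch.x.shape[1] != self.node_dim:
            raise ValueError(
                f"node feature width {batch.x.shape[1]} != model width "
                f"{self.node_dim}; check that the AEV parameters used for "
                f"featurization match training"
            )
        if batch.x.shape[0] == 0:
            raise ValueError("empty graph batch")
        xin = batch.x
        if self.feature_loc is not None:
            xin = (xin - self.feature_loc) / self.feature_scale
        x = Tensor(xin)
        e = Tensor(batch.edge_attr)
        for layer in range(self.config.n_layers):
            x = self._layer(layer, x, batch, e)
        pooled = nn.concat(
            [
                nn.segment_max(x, batch.node_graph, batch.n_graphs),
                nn.segment_sum(x, batch.node_graph, batch.n_graphs)
                / Tensor(np.bincount(batch.node_graph,
                                     minlength=batch.n_graphs)[:, None].astype(float)),
            ],
            axis=1,
        )
        h = pooled
        n_mlp = len(self.config.mlp_hidden) + 1
        for k in range(n_mlp):
            h = h @ self.params[f"mlp{k}_W"] + self.params[f"mlp{k}_b"]
            if k < n_mlp - 1:
                h = self._activation(h)
        return h

    def predict(self, graphs: Sequence[PLIGraph]) -> np.ndarray:
        """Deterministic inference: predicted pK per graph."""
        with nn.no_grad():
            return self.forward(pack_batch(graphs)).data[:, 0]

    # -- state ------------------------------------------------------------

    def set_feature_normalization(self, loc: np.ndarray, scale: np.ndarray) -> None:
        loc = np.asarray(loc, dtype=float).reshape(-1)
        scale = np.asarray(scale, dtype=float).reshape(-1)
        if loc.size != self.node_dim or scale.size != self.node_dim:
            raise ValueError("normalisation width must match node features")
        self.feature_loc = loc
        self.feature_scale = np.maximum(scale, 1e-8)

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.params.items()}
        if self.feature_loc is not None:
            state["_feature_loc"] = self.feature_loc.copy()
            state["_feature_scale"] = self.feature_scale.copy()
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            if k not in state or state[k].shape != p.data.shape:
                raise ValueError(f"checkpoint missing/mismatched parameter {k}")
            p.data = np.array(state[k], dtype=float)
        if "_feature_loc" in state:
            self.set_feature_normalization(state["_feature_loc"],
                                           state["_feature_scale"])


def global_pool(node_features: np.ndarray) -> np.ndarray:
    """[elementwise max || elementwise mean] over a single graph's nodes."""
    x = np.asarray(node_features, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("pooling needs at least one node")
    return np.concatenate([x.max(axis=0), x.mean(axis=0)])


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

class Ensemble:
    """A set of independently trained members; predictions are their mean."""

    def __init__(self, members: Sequence[GATv2Model]):
        if not members:
            raise ValueError("empty ensemble")
        self.members = list(members)

    @property
    def config(self) -> ModelConfig:
        return self.members[0].config

    def predict(self, graphs: Sequence[PLIGraph]) -> EnsemblePrediction:
        batch = pack_batch(graphs)
        with nn.no_grad():
            member_pks = np.stack(
                [m.forward(batch).data[:, 0] for m in self.members]
            )
        return EnsemblePrediction(
            mean_pk=member_pks.mean(axis=0), member_pks=member_pks
        )

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "format": CHECKPOINT_FORMAT,
            "version": CHECKPOINT_VERSION,
            "n_members": len(self.members),
            "node_dim": self.members[0].node_dim,
            "edge_dim": self.members[0].edge_dim,
            "config": self.config.to_dict(),
            "member_seeds": [m.seed for m in self.members],
        }
        with open(os.path.join(directory, "ensemble.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        for i, m in enumerate(self.members):
            np.savez(os.path.join(directory, f"member_{i:02d}.npz"),
                     **m.state_arrays())

    @classmethod
    def load(cls, directory: str) -> "Ensemble":
        with open(os.path.join(directory, "ensemble.json")) as fh:
            meta = json.load(fh)
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"not a {CHECKPOINT_FORMAT} checkpoint: {directory}")
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta.get('version')} != "
                f"supported {CHECKPOINT_VERSION}"
            )
        config = ModelConfig.from_dict(meta["config"])
        members = []
        for i in range(int(meta["n_members"])):
            model = GATv2Model(
                node_dim=int(meta["node_dim"]),
                edge_dim=int(meta["edge_dim"]),
                config=config,
                seed=int(meta["member_seeds"][i]),
            )
            with np.load(os.path.join(directory, f"member_{i:02d}.npz")) as data:
                model.load_state({k: data[k] for k in data.files})
            members.append(model)
        return cls(members)
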