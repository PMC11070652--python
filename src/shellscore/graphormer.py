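"""Per-shell graph transformer encoder with spatial and edge-path biases.

The attention score between nodes i and j is

    A_ij = (h_i W_Q)(h_j W_K)^T / sqrt(d_head) + b_phi(i,j) + c_ij

where ``b`` is a learnable scalar looked up (per head) from the shortest-path
hop count phi(i, j) -- with a dedicated slot for the unreachable sentinel -1 --
and ``c_ij`` averages dot-products of the edge features along one shortest
path with position-indexed learnable weights:

    c_ij = (1/N) sum_{p=1..N} x_{e_p} . w^E_p ,   N <= hop_max.

No centrality (degree) encoding is used anywhere: in ablations it does not
help this task.  Graph readout goes through a virtual token that attends to
every node (its pairs use their own learnable bias slot), so the embedding is
invariant to node ordering.  Pre-norm residual blocks keep small models stable
without warmup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .shells import DEFAULT_HOP_MAX, ShellGraph

__all__ = [
    "GraphormerConfig", "init_graphormer_params", "spatial_bias", "edge_bias",
    "biased_attention", "encode_shell_graph", "EMBEDDING_DIM",
]

#: Width of the per-shell embedding handed to the MLP head.
EMBEDDING_DIM = 128


@dataclass(frozen=True)
class GraphormerConfig:
    """Hyperparameters of one shell encoder (all shells use the same sizes)."""

    d_hidden: int = 128
    n_heads: int = 4
    n_layers: int = 4
    out_dim: int = EMBEDDING_DIM
    hop_max: int = DEFAULT_HOP_MAX
    node_dim: int = 171
    edge_dim: int = 8

    def __post_init__(self):
        if self.d_hidden % self.n_heads:
            raise ValueError("d_hidden must be divisible by n_heads")

    @property
    def bias_slots(self) -> int:
        # phi in {-1, 0, 1, ..., hop_max} plus one slot for virtual-token pairs
        return self.hop_max + 3

    @property
    def virtual_slot(self) -> int:
        return self.bias_slots - 1


def init_graphormer_params(config: GraphormerConfig,
                           rng: np.random.Generator) -> dict[str, Tensor]:
    """Fresh parameter tensors for one shell encoder."""
    d = config.d_hidden

    def w(*shape, scale=None):
        scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
        return Tensor(rng.normal(0.0, scale, size=shape))

    params: dict[str, Tensor] = {
        "w_in": w(config.node_dim, d),
        "b_in": Tensor(np.zeros(d)),
        "virt": Tensor(rng.normal(0.0, 0.02, size=d)),
        "bias_table": Tensor(np.zeros((config.n_heads, config.bias_slots))),
        "w_edge": Tensor(np.zeros((config.n_heads, config.hop_max,
                                   config.edge_dim))),
        "ln_f.g": Tensor(np.ones(d)),
        "ln_f.b": Tensor(np.zeros(d)),
        "w_out": w(d, config.out_dim),
        "b_out": Tensor(np.zeros(config.out_dim)),
    }
    for layer in range(config.n_layers):
        p = f"l{layer}."
        params[p + "ln1.g"] = Tensor(np.ones(d))
        params[p + "ln1.b"] = Tensor(np.zeros(d))
        params[p + "w_q"] = w(d, d)
        params[p + "w_k"] = w(d, d)
        params[p + "w_v"] = w(d, d)
        params[p + "w_o"] = w(d, d)
        params[p + "ln2.g"] = Tensor(np.ones(d))
        params[p + "ln2.b"] = Tensor(np.zeros(d))
        params[p + "w_ff1"] = w(d, 2 * d)
        params[p + "b_ff1"] = Tensor(np.zeros(2 * d))
        params[p + "w_ff2"] = w(2 * d, d)
        params[p + "b_ff2"] = Tensor(np.zeros(d))
    return params


def spatial_bias(phi: np.ndarray, bias_table: Tensor,
                 hop_max: int | None = None) -> Tensor:
    """Per-head bias matrix: entry (i, j) = table[phi(i, j)].

    Table slot 0 holds the unreachable sentinel (phi = -1); slots 1..hop_max+1
    hold hop counts 0..hop_max.
    """
    phi = np.asarray(phi)
    hop_max = bias_table.shape[-1] - 3 if hop_max is None else hop_max
    if phi.min() < -1 or phi.max() > hop_max:
        raise ValueError(f"phi values outside {{-1..{hop_max}}}")
    return ad.gather(bias_table, phi + 1)


def edge_bias(path_feats: np.ndarray, path_len: np.ndarray,
              w_edge: Tensor) -> Tensor:
    """Edge-encoding bias c_ij for every node pair (per head).

    Pairs with no path (phi in {0, -1}) have path_len 0 and get c = 0; paths
    must arrive already truncated to hop_max entries.
    """
    hop_max = w_edge.shape[1]
    if path_len.max(initial=0) > hop_max:
        raise ValueError("edge paths longer than hop_max; truncate first")
    inv_len = np.zeros(path_len.shape)
    nz = path_len > 0
    inv_len[nz] = 1.0 / path_len[nz]
    return ad.edge_path_bias(np.asarray(path_feats, dtype=float), inv_len, w_edge)


def biased_attention(h: Tensor, w_q: Tensor, w_k: Tensor, w_v: Tensor,
                     w_o: Tensor, bias: Tensor, n_heads: int) -> Tensor:
    """Multi-head scaled dot-product attention with an additive bias matrix.

    ``bias`` has shape (n_heads, m, m); with a zero bias this reduces to plain
    transformer attention.
    """
    m, d = h.shape
    if w_q.shape != (d, d):
        raise ValueError("projection width does not match node representation")
    if bias.shape != (n_heads, m, m):
        raise ValueError("bias must be (n_heads, m, m)")
    dh = d // n_heads

    def split(x):  # (m, d) -> (heads, m, dh)
        return ad.transpose(ad.reshape(x, (m, n_heads, dh)), (1, 0, 2))

    q = split(h @ w_q)
    k = split(h @ w_k)
    v = split(h @ w_v)
    scores = ad.scale(q @ ad.transpose(k, (0, 2, 1)), 1.0 / np.sqrt(dh))
    attn = ad.softmax(scores + bias)
    out = ad.reshape(ad.transpose(attn @ v, (1, 0, 2)), (m, d))
    return out @ w_o


def _bias_matrices(graph: ShellGraph, params: dict[str, Tensor],
                   config: GraphormerConfig) -> Tensor:
    """Spatial + edge biases extended with the virtual-token row/column."""
    m = graph.n_nodes
    hop = config.hop_max
    idx = np.full((m + 1, m + 1), config.virtual_slot, dtype=np.int64)
    idx[1:, 1:] = graph.phi + 1
    b_spatial = ad.gather(params["bias_table"], idx)

    pf = graph.path_feature_tensor()
    path_feats = np.zeros((m + 1, m + 1, hop, config.edge_dim))
    path_feats[1:, 1:] = pf
    path_len = np.zeros((m + 1, m + 1), dtype=np.int64)
    path_len[1:, 1:] = graph.path_len
    b_edge = edge_bias(path_feats, path_len, params["w_edge"])
    return b_spatial + b_edge


def _affine_ln(x: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
    return ad.layer_norm(x) * gain + bias


def encode_shell_graph(graph: ShellGraph, params: dict[str, Tensor],
                       config: GraphormerConfig) -> Tensor:
    """Embed one shell graph into a fixed-length vector (default 128).

    The 171-dim node features are projected to ``d_hidden``, a virtual readout
    token is prepended, the biased attention stack runs, and the readout
    token's final representation is projected to ``out_dim``.
    """
    if graph.n_nodes < 1:
        raise ValueError("shell graph has no nodes")
    if graph.node_features.shape[1] != config.node_dim:
        raise ValueError("node feature width does not match the configuration")
    h = Tensor(graph.node_features) @ params["w_in"] + params["b_in"]
    h = ad.concat([ad.reshape(params["virt"], (1, config.d_hidden)), h], axis=0)
    bias = _bias_matrices(graph, params, config)
    for layer in range(config.n_layers):
        p = f"l{layer}."
        hn = _affine_ln(h, params[p + "ln1.g"], params[p + "ln1.b"])
        h = h + biased_attention(hn, params[p + "w_q"], params[p + "w_k"],
                                 params[p + "w_v"], params[p + "w_o"],
                                 bias, config.n_heads)
        hn = _affine_ln(h, params[p + "ln2.g"], params[p + "ln2.b"])
        ff = ad.relu(hn @ params[p + "w_ff1"] + params[p + "b_ff1"])
        h = h + (ff @ params[p + "w_ff2"] + params[p + "b_ff2"])
    readout = ad.take_row(_affine_ln(h, params["ln_f.g"], params["ln_f.b"]), 0)
    # keep operands 2-D through the projection, then flatten to (out_dim,)
    out = ad.reshape(readout, (1, config.d_hidden)) @ params["w_out"]
    return ad.reshape(out, (config.out_dim,)) + params["b_out"]
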