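"""Query-based pocket points decoder (PPPD) with a predicted-aligned-error head.

Learnable query rows — four pocket-point blocks plus one PAE query — are
refined against the encoder's per-node embeddings by alternating
self-attention, query-to-graph cross-attention and graph-to-query feedback.
Pocket coordinates are then read out as attention-weighted (convex)
combinations of the source graph's node coordinates, which makes every
predicted pocket point lie inside the convex hull of that graph and keeps the
whole readout SE(3)-equivariant.  The PAE query is mapped by an MLP through a
softplus to a non-negative scalar trained to match the RMSD of protein2, so
lower PAE means higher confidence.

The same decoder serves both operating modes: molecular-glue mode populates
all five query blocks; PROTAC mode keeps only the PAE query (the pocket
points come from unbound binary poses instead of the decoder).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import autograd.numpy as anp
import numpy as np

from . import nn
from .encoder import EncoderState

__all__ = [
    "DecoderConfig",
    "QuerySet",
    "PocketPointSet",
    "PAEEstimate",
    "init_decoder_params",
    "attention",
    "decoder_forward",
    "extract_pocket_points",
    "predict_pae",
]

POCKET_BLOCKS = ("lig", "p1_lig", "p2", "p1_p2")


@dataclass
class DecoderConfig:
    """PPPD hyper-parameters.

    Single-head attention is the default throughout; ``n_heads`` exists only
    for the ablation showing multi-head hurts coordinate extraction.
    """

    n_layers: int = 4
    n_queries: int = 10
    hidden_dim: int = 64
    n_heads: int = 1


@dataclass
class QuerySet:
    """The five decoder query blocks (pocket blocks are None in PROTAC mode)."""

    q_lig: Optional[np.ndarray]
    q_p1_lig: Optional[np.ndarray]
    q_p2: Optional[np.ndarray]
    q_p1_p2: Optional[np.ndarray]
    q_pae: np.ndarray
    mode: str = "mgd"  # "mgd" | "protac"

    def blocks(self):
        return {
            "lig": self.q_lig,
            "p1_lig": self.q_p1_lig,
            "p2": self.q_p2,
            "p1_p2": self.q_p1_p2,
        }


@dataclass
class PocketPointSet:
    """An ordered 3D point set on one side of a binding interface."""

    points: np.ndarray
    source: str = "predicted"  # predicted | unbound | ground_truth
    interface_tag: str = ""

    def __post_init__(self):
        pts = np.asarray(getattr(self.points, "_value", self.points), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("pocket points must be (n, 3)")

    def __len__(self):
        return np.shape(self.points)[0]


@dataclass
class PAEEstimate:
    """Predicted aligned error of protein2 (A); non-negative by construction."""

    value: float

    def __post_init__(self):
        v = float(getattr(self.value, "_value", self.value))
        if v < 0:
            raise ValueError("PAE must be non-negative")


def init_decoder_params(config: DecoderConfig, seed: int = 0) -> nn.Params:
    rng = np.random.default_rng(seed + 1)
    d, nq = config.hidden_dim, config.n_queries
    params: nn.Params = {}
    for b in POCKET_BLOCKS:
        params[f"dec/Q_{b}"] = rng.normal(0, 1.0, size=(nq, d))
    params["dec/q_pae"] = rng.normal(0, 1.0, size=(1, d))
    for r in ("lig", "p1", "p2"):
        params[f"dec/e_{r}"] = rng.normal(0, 0.1, size=d)
    for l in range(config.n_layers):
        for blk in ("self", "cross1", "cross2"):
            _init_attention(params, f"dec/{l}/{blk}", d, rng)
        nn.init_mlp(params, f"dec/{l}/phi", [d, d, d], rng)
    _init_attention(params, "dec/final", d, rng)
    nn.init_mlp(params, "dec/final/phi", [d, d, d], rng)
    for b in POCKET_BLOCKS:
        _init_attention(params, f"dec/pocket_{b}", d, rng, values=False)
    nn.init_mlp(params, "dec/pae_head", [d, d, 1], rng)
    return params


def _init_attention(params, name, d, rng, values=True):
    nn.init_mlp(params, f"{name}/phi_q", [d, d], rng)
    nn.init_mlp(params, f"{name}/phi_k", [d, d], rng)
    if values:
        params[f"{name}/W"] = rng.normal(0, np.sqrt(1.0 / d), size=(d, d))


def attention_weights(params, name, Q, K, n_heads: int = 1):
    """Row-stochastic attention matrix a(Q, K); one softmax row per query."""
    d = np.shape(Q)[1]
    q = nn.mlp(params, f"{name}/phi_q", nn.layer_norm(Q))
    k = nn.mlp(params, f"{name}/phi_k", nn.layer_norm(K))
    if n_heads == 1:
        return nn.softmax(q @ k.T / np.sqrt(d), axis=1)
    dh = d // n_heads
    mats = []
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        mats.append(nn.softmax(q[:, sl] @ k[:, sl].T / np.sqrt(dh), axis=1))
    return mats


def attention(params, name, Q, K, V, n_heads: int = 1):
    """Attn(Q, K, V) = a(Q, K) W V  (single-head unless ablating)."""
    W = params[f"{name}/W"]
    a = attention_weights(params, name, Q, K, n_heads)
    if n_heads == 1:
        return a @ (V @ W.T)
    d = np.shape(V)[1]
    dh = d // n_heads
    outs = []
    for h, ah in enumerate(a):
        sl = slice(h * dh, (h + 1) * dh)
        outs.append(ah @ (V @ W.T)[:, sl])
    return anp.concatenate(outs, axis=1)


def _stack_queries(params, mode: str) -> np.ndarray:
    if mode == "protac":
        return anp.array(params["dec/q_pae"])
    blocks = [params[f"dec/Q_{b}"] for b in POCKET_BLOCKS] + [params["dec/q_pae"]]
    return anp.concatenate(blocks, axis=0)


def decoder_forward(params, config: DecoderConfig, state: EncoderState,
                    mode: str = "mgd"):
    """Refine the query blocks against the encoder output.

    Returns (QuerySet, refined per-graph H dict).  Encoder coordinates are
    left untouched — the decoder updates latents only.
    """
    if mode not in ("mgd", "protac"):
        raise ValueError(f"unknown mode {mode!r}")
    sizes = {r: np.shape(state.H[r])[0] for r in ("lig", "p1", "p2")}
    H = anp.concatenate(
        [state.H[r] + params[f"dec/e_{r}"][None, :] for r in ("lig", "p1", "p2")],
        axis=0,
    )
    Q = _stack_queries(params, mode)
    nh = config.n_heads
    # residual (pre-norm) transformer blocks: the skip connections preserve
    # per-query identity, without which near-uniform early attention would
    # collapse every query row onto the same vector
    for l in range(config.n_layers):
        Q = Q + attention(params, f"dec/{l}/self", Q, Q, Q, nh)
        Qp = Q + nn.mlp(params, f"dec/{l}/phi",
                        attention(params, f"dec/{l}/cross1", Q, H, H, nh))
        H = H + attention(params, f"dec/{l}/cross2", H, Qp, Qp, nh)
        Q = Qp
    Q = Q + nn.mlp(params, "dec/final/phi",
                   attention(params, "dec/final", Q, H, H, nh))
    # unfold
    n1, n2 = sizes["lig"], sizes["lig"] + sizes["p1"]
    H_out = {"lig": H[:n1], "p1": H[n1:n2], "p2": H[n2:]}
    if mode == "protac":
        qs = QuerySet(None, None, None, None, Q, mode="protac")
    else:
        nq = config.n_queries
        qs = QuerySet(
            q_lig=Q[0:nq],
            q_p1_lig=Q[nq: 2 * nq],
            q_p2=Q[2 * nq: 3 * nq],
            q_p1_p2=Q[3 * nq: 4 * nq],
            q_pae=Q[4 * nq: 4 * nq + 1],
            mode="mgd",
        )
    return qs, H_out


# which (graph latents, graph coordinates) each pocket block reads from
_BLOCK_SOURCE = {"lig": "lig", "p1_lig": "p1", "p2": "p2", "p1_p2": "p1"}
_BLOCK_TAG = {
    "lig": "lig|p1",
    "p1_lig": "p1|lig",
    "p2": "p2|p1",
    "p1_p2": "p1|p2",
}


def extract_pocket_points(params, config: DecoderConfig, queries: QuerySet,
                          H_out: Dict[str, np.ndarray],
                          state: EncoderState) -> Dict[str, PocketPointSet]:
    """Pocket coordinates as attention-weighted sums of graph coordinates.

    Each point is a convex combination of its source graph's node
    coordinates (the attention row is a softmax).  MG(D) mode only.
    """
    if queries.mode != "mgd":
        raise ValueError("pocket-point extraction requires MG(D) mode queries")
    out = {}
    for b, q in queries.blocks().items():
        src = _BLOCK_SOURCE[b]
        a = attention_weights(params, f"dec/pocket_{b}", q, H_out[src], n_heads=1)
        pts = a @ state.X[src]
        out[b] = PocketPointSet(points=pts, source="predicted",
                                interface_tag=_BLOCK_TAG[b])
    return out


def predict_pae(params, q_pae) -> PAEEstimate:
    """Non-negative confidence scalar (softplus-activated MLP head)."""
    raw = nn.mlp(params, "dec/pae_head", q_pae)
    value = nn.softplus(raw[0, 0])
    return PAEEstimate(value=value)
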