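"""Ternary independent E(3)-equivariant graph matching encoder.

Three geometric graphs (ligand, protein1, protein2) are refined by M layers
that alternate

* intra-graph message passing over edges (invariant messages built from
  latent embeddings, squared edge lengths and initial edge features),
* ternary inter-graph attention, where each graph's nodes attend over the
  union of the other two graphs' nodes,
* an equivariant coordinate update that moves each node along the unit
  directions to its neighbours, scaled by a learned function of the message,
* a convex latent update h <- (1-beta) h + beta phi_h(h, m, mu, f).

Latent embeddings are E(3)-invariant by construction; coordinates transform
exactly with any rigid motion applied independently to each input graph.
The two protein parameter groups are shared by default, so the network is
symmetric under swapping protein1 and protein2.  After the final layer the
ligand coordinates are taken as the ligand's conformation inside the
predicted ternary complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import autograd.numpy as anp
import numpy as np

from . import nn
from .graphs import EntityGraph

__all__ = [
    "EncoderConfig",
    "EncoderState",
    "NumericalInstabilityError",
    "init_encoder_params",
    "intra_messages",
    "ternary_attention",
    "update_coords",
    "update_features",
    "encode",
    "distance_constraint_projection",
]

ROLES = ("lig", "p1", "p2")


class NumericalInstabilityError(RuntimeError):
    pass


@dataclass
class EncoderConfig:
    """Architecture and training-time knobs for the encoder.

    ``beta`` is the trade-off weight of the convex latent update.
    ``noise_level`` is the training-noise standard deviation in Angstrom
    (applied by the engine as noise_level/scale in the normalized frame).
    ``distance_constraint`` switches the post-layer projection Psi that
    restores the ligand's local (1-2 and 1-3) distances; identity otherwise.
    """

    n_layers: int = 8
    hidden_dim: int = 64
    beta: float = 0.5
    noise_level: float = 2.0
    shared_protein_weights: bool = True
    distance_constraint: bool = False
    lig_feat_dim: int = 20
    prot_feat_dim: int = 21
    lig_edge_dim: int = 9
    prot_edge_dim: int = 9

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


@dataclass
class EncoderState:
    """Per-graph latent matrices H and coordinates X after some layers."""

    H: Dict[str, np.ndarray]
    X: Dict[str, np.ndarray]
    layer_index: int = 0
    f0: Dict[str, np.ndarray] = field(default_factory=dict)


def _group(config: EncoderConfig, role: str) -> str:
    if role == "lig":
        return "lig"
    return "prot" if config.shared_protein_weights else role


def init_encoder_params(config: EncoderConfig, seed: int = 0) -> nn.Params:
    """Seeded parameter store.  p1/p2 share the 'prot' group when configured."""
    rng = np.random.default_rng(seed)
    d = config.hidden_dim
    params: nn.Params = {}
    nn.init_mlp(params, "enc/embed_lig", [config.lig_feat_dim, d, d], rng)
    nn.init_mlp(params, "enc/embed_prot", [config.prot_feat_dim, d, d], rng)
    params["enc/pocket_lig"] = rng.normal(0, 0.1, size=d)
    params["enc/pocket_prot"] = rng.normal(0, 0.1, size=d)
    groups = ["lig", "prot"] if config.shared_protein_weights else ["lig", "p1", "p2"]
    for l in range(config.n_layers):
        for g in groups:
            edim = config.lig_edge_dim if g == "lig" else config.prot_edge_dim
            nn.init_mlp(params, f"enc/{l}/{g}/phi_e", [2 * d + 1 + edim, d, d], rng)
            nn.init_mlp(params, f"enc/{l}/{g}/phi_x", [d, d, 1], rng)
            # zero-init the coordinate-update head: layers start as the
            # identity on coordinates and learn displacements gradually
            params[f"enc/{l}/{g}/phi_x/W1"] = np.zeros_like(
                params[f"enc/{l}/{g}/phi_x/W1"])
            nn.init_mlp(params, f"enc/{l}/{g}/phi_h", [4 * d, d, d], rng)
            nn.init_mlp(params, f"enc/{l}/{g}/phi_q", [d, d], rng)
            nn.init_mlp(params, f"enc/{l}/{g}/phi_k", [d, d], rng)
            params[f"enc/{l}/{g}/W"] = rng.normal(0, np.sqrt(1.0 / d), size=(d, d))
    return params


def _agg_matrices(graph: EntityGraph):
    """(mean-aggregation, sum-aggregation) node x edge matrices."""
    n, E = graph.n_nodes, graph.n_edges
    S = np.zeros((n, E))
    if E:
        dst = graph.edge_index[1]
        S[dst, np.arange(E)] = 1.0
    deg = S.sum(axis=1)
    A = S / np.maximum(deg, 1.0)[:, None]  # empty neighbourhood -> zero message
    return A, S


def intra_messages(params, config: EncoderConfig, layer: int, role: str,
                   H, X, graph: EntityGraph):
    """Edge messages m_{j->i} and their per-node means m_i.

    m_{j->i} = phi_e(h_i, h_j, ||x_i - x_j||^2, f_{j->i}); nodes with no
    neighbours receive the zero message.
    """
    g = _group(config, role)
    A, _ = _agg_matrices(graph)
    if graph.n_edges == 0:
        m_edges = anp.zeros((0, config.hidden_dim))
        return m_edges, anp.zeros((graph.n_nodes, config.hidden_dim))
    src, dst = graph.edge_index[0], graph.edge_index[1]
    d2 = anp.sum((X[dst] - X[src]) ** 2, axis=1, keepdims=True)
    Hn = nn.layer_norm(H)
    inp = anp.concatenate([Hn[dst], Hn[src], d2, graph.edge_features], axis=1)
    m_edges = nn.mlp(params, f"enc/{layer}/{g}/phi_e", inp)
    m_nodes = A @ m_edges
    return m_edges, m_nodes


def ternary_attention(params, config: EncoderConfig, layer: int, query_role: str,
                      H: Dict[str, np.ndarray]):
    """Cross-graph attention: queries from one graph, keys/values from the
    union of the other two.  Returns (attention matrix, cross message mu).

    Inner products are scaled by 1/sqrt(hidden_dim) for stability (the scale
    is absorbed into phi_q relative to the unscaled formulation).
    """
    g = _group(config, query_role)
    others = [r for r in ROLES if r != query_role]
    H_kv = nn.layer_norm(anp.concatenate([H[r] for r in others], axis=0))
    q = nn.mlp(params, f"enc/{layer}/{g}/phi_q", nn.layer_norm(H[query_role]))
    k = nn.mlp(params, f"enc/{layer}/{g}/phi_k", H_kv)
    logits = q @ k.T / np.sqrt(config.hidden_dim)
    a = nn.softmax(logits, axis=1)
    mu = a @ (H_kv @ params[f"enc/{layer}/{g}/W"].T)
    return a, mu


def update_coords(params, config: EncoderConfig, layer: int, role: str,
                  X, graph: EntityGraph, m_edges, reference_coords=None):
    """Equivariant coordinate update along unit neighbour directions.

    Zero-distance pairs contribute nothing (removable singularity).  When
    ``config.distance_constraint`` is set and a ligand reference conformation
    is supplied, the result is projected back onto the reference's local
    distance geometry (Psi); otherwise Psi is the identity.
    """
    g = _group(config, role)
    if graph.n_edges == 0:
        return X
    _, S = _agg_matrices(graph)
    src, dst = graph.edge_index[0], graph.edge_index[1]
    diff = X[dst] - X[src]
    d2 = anp.sum(diff**2, axis=1, keepdims=True)
    valid = (np.asarray(getattr(d2, "_value", d2)) > 1e-16).astype(float)
    d_safe = anp.sqrt(anp.where(np.asarray(valid, dtype=bool), d2, 1.0))
    scale = nn.mlp(params, f"enc/{layer}/{g}/phi_x", m_edges)
    contrib = diff / d_safe * scale * valid
    X_new = X + S @ contrib
    if config.distance_constraint and role == "lig" and reference_coords is not None:
        X_new = distance_constraint_projection(X_new, reference_coords)
    return X_new


def distance_constraint_projection(coords, reference, n_sweeps: int = 20,
                                   bond_cutoff: float = 1.8):
    """Gauss-Seidel restoration of the reference's 1-2 and 1-3 distances.

    Pairs closer than ``bond_cutoff`` A in the reference conformation are
    treated as bonds; pairs sharing a bonded neighbour as 1-3 pairs.  Each
    sweep moves both partners of every constrained pair symmetrically along
    their axis to the reference distance.
    """
    ref = np.asarray(reference, dtype=float)
    n = ref.shape[0]
    dref = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
    bonded = (dref < bond_cutoff) & ~np.eye(n, dtype=bool)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if bonded[i, j]:
                pairs.append((i, j, dref[i, j]))
    adj = [set(np.flatnonzero(bonded[i])) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if not bonded[i, j] and adj[i] & adj[j]:
                pairs.append((i, j, dref[i, j]))
    rows = [coords[i] for i in range(n)]
    for _ in range(n_sweeps):
        for i, j, d0 in pairs:
            axis = rows[i] - rows[j]
            d = anp.sqrt(anp.sum(axis**2) + 1e-12)
            corr = 0.5 * (d - d0) / d
            rows[i] = rows[i] - corr * axis
            rows[j] = rows[j] + corr * axis
    return anp.stack(rows)


def update_features(params, config: EncoderConfig, layer: int, role: str,
                    H, m_nodes, mu, f0):
    """Convex combination h <- (1-beta) h + beta phi_h(h, m, mu, f)."""
    g = _group(config, role)
    inp = anp.concatenate([nn.layer_norm(H), m_nodes, mu, f0], axis=1)
    return (1.0 - config.beta) * H + config.beta * nn.mlp(
        params, f"enc/{layer}/{g}/phi_h", inp
    )


def initial_latents(params, graph: EntityGraph):
    """Embed raw node features; flagged pocket nodes get the learnable
    pocket embedding added by summation."""
    name = "enc/embed_lig" if graph.role == "lig" else "enc/embed_prot"
    pocket = params["enc/pocket_lig" if graph.role == "lig" else "enc/pocket_prot"]
    f = nn.mlp(params, name, graph.node_features())
    mask = graph.pocket_mask().astype(float)[:, None]
    return f + mask * pocket[None, :]


def encode(params, lig: EntityGraph, p1: EntityGraph, p2: EntityGraph,
           config: EncoderConfig, noise_std: float = 0.0,
           rng: Optional[np.random.Generator] = None) -> EncoderState:
    """Run all M layers over the three graphs.

    ``noise_std`` (training only) adds zero-mean Gaussian noise to the input
    coordinates and initial latent embeddings.  Raises
    :class:`NumericalInstabilityError` naming the layer if an intermediate
    becomes non-finite.
    """
    graphs = {"lig": lig, "p1": p1, "p2": p2}
    for r, g in graphs.items():
        if g.n_nodes == 0:
            raise ValueError(f"graph {r} is empty")
    X = {r: anp.array(g.positions()) for r, g in graphs.items()}
    f0 = {r: initial_latents(params, g) for r, g in graphs.items()}
    if noise_std > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        X = {r: x + rng.normal(0, noise_std, size=np.shape(x)) for r, x in X.items()}
        f0 = {r: f + rng.normal(0, noise_std, size=np.shape(f)) for r, f in f0.items()}
    H = dict(f0)
    lig_ref = np.asarray(getattr(X["lig"], "_value", X["lig"]))
    for l in range(config.n_layers):
        msgs = {r: intra_messages(params, config, l, r, H[r], X[r], graphs[r])
                for r in ROLES}
        cross = {r: ternary_attention(params, config, l, r, H)[1] for r in ROLES}
        X = {r: update_coords(params, config, l, r, X[r], graphs[r], msgs[r][0],
                              reference_coords=lig_ref if r == "lig" else None)
             for r in ROLES}
        H = {r: update_features(params, config, l, r, H[r], msgs[r][1], cross[r], f0[r])
             for r in ROLES}
        for r in ROLES:
            hv = np.asarray(getattr(H[r], "_value", H[r]))
            xv = np.asarray(getattr(X[r], "_value", X[r]))
            if not (np.all(np.isfinite(hv)) and np.all(np.isfinite(xv))):
                raise NumericalInstabilityError(
                    f"non-finite intermediate in layer {l} ({r})"
                )
    return EncoderState(H=H, X=X, layer_index=config.n_layers, f0=f0)
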