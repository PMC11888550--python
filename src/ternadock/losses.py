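"""The six-term training objective.

total = L_lig + L_kabsch_lig + L_ot1 + L_ot2 + L_intersection + L_PAE
(an unweighted sum; per-term weights are exposed but default to 1).

* L_lig — mean squared error between predicted and native ligand coordinates.
* L_kabsch_lig — the same MSE after optimal rigid superposition, isolating
  conformational error from placement error; never exceeds L_lig.
* L_ot1 / L_ot2 — optimal-transport cost (squared-Euclidean ground cost,
  uniform marginals) between predicted and target pocket points, for the
  ligand<->protein1 and protein2<->protein1 interfaces respectively.
* L_intersection — a steric-overlap penalty over the three inter-entity
  pairs: per entity-pair, the mean over atoms of
  relu(sum_b exp(-d_ab^2 / sigma^2) - gamma).  It is exactly zero whenever
  the summed Gaussian overlap at every atom stays below the clash onset
  gamma, which holds for any non-clashing (>= 2 A separation) geometry at
  the default sigma = 1.5 A, gamma = 1.
* L_PAE — L1 loss between the predicted aligned error and the (unaligned)
  coordinate RMSD of protein2 in protein1's frame.

All functions trace under autograd; combinatorial sub-solves (assignment /
transport plan, Kabsch rotation) are computed on detached values and treated
as constants, which leaves the gradients exact at the optimum (envelope
argument) for the Kabsch term and standard for the fixed transport plan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from scipy.optimize import linear_sum_assignment, linprog

from .assembly import DegenerateAlignmentError, TernaryComplex, kabsch
from .graphs import DegenerateInputError

__all__ = [
    "LossBundle",
    "ligand_mse",
    "kabsch_ligand_mse",
    "ot_pocket_loss",
    "intersection_penalty",
    "pae_loss",
    "total_loss",
    "rmsd",
]


@dataclass
class LossBundle:
    lig: float
    kabsch_lig: float
    ot1: float
    ot2: float
    intersection: float
    pae: float

    @property
    def total(self):
        return (self.lig + self.kabsch_lig + self.ot1 + self.ot2
                + self.intersection + self.pae)

    def as_dict(self):
        return {
            "lig": self.lig, "kabsch_lig": self.kabsch_lig,
            "ot1": self.ot1, "ot2": self.ot2,
            "intersection": self.intersection, "pae": self.pae,
            "total": self.total,
        }


def _detach(x):
    return np.asarray(getattr(x, "_value", x), dtype=float)


def _coords(x):
    return getattr(x, "points", x)


def ligand_mse(pred, truth):
    """Mean over atoms of the squared Euclidean deviation."""
    pred, truth = _coords(pred), _coords(truth)
    if np.shape(pred) != np.shape(truth):
        raise ValueError(f"shape mismatch: {np.shape(pred)} vs {np.shape(truth)}")
    return anp.mean(anp.sum((pred - truth) ** 2, axis=1))


def kabsch_ligand_mse(pred, truth):
    """MSE after optimal rigid superposition of pred onto truth.

    Falls back to the unaligned MSE (with a warning) when the point set is
    too degenerate to superpose.
    """
    pred, truth = _coords(pred), _coords(truth)
    try:
        tf = kabsch(_detach(pred), _detach(truth))
    except DegenerateAlignmentError:
        warnings.warn("degenerate point set; kabsch-aligned MSE falls back to plain MSE")
        return ligand_mse(pred, truth)
    aligned = pred @ tf.R.T + tf.t
    return anp.mean(anp.sum((aligned - truth) ** 2, axis=1))


def _transport_plan(cost: np.ndarray) -> np.ndarray:
    """Exact OT plan for uniform marginals (LP; assignment when square)."""
    n, m = cost.shape
    if n == m:
        rows, cols = linear_sum_assignment(cost)
        plan = np.zeros_like(cost)
        plan[rows, cols] = 1.0 / n
        return plan
    # uniform-marginal transport LP on the flattened plan
    c = cost.ravel()
    A_eq = np.zeros((n + m, n * m))
    for i in range(n):
        A_eq[i, i * m: (i + 1) * m] = 1.0
    for j in range(m):
        A_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return res.x.reshape(n, m)


def ot_pocket_loss(predicted, target):
    """Exact optimal-transport cost between two pocket point sets.

    Squared-Euclidean ground cost, uniform marginals; cardinalities may
    differ.  Zero iff the two empirical distributions coincide.
    """
    P, T = _coords(predicted), _coords(target)
    if np.shape(P)[0] == 0 or np.shape(T)[0] == 0:
        raise DegenerateInputError("empty pocket point set")
    cost = anp.sum((P[:, None, :] - T[None, :, :]) ** 2, axis=2)
    plan = _transport_plan(_detach(cost))
    return anp.sum(plan * cost)


def ot_pair_loss(pred_a, pred_b, target):
    """Shared-plan optimal transport for one interface's pocket-point pair.

    Both predicted sides of an interface (e.g. P_lig and P_p1->lig) are
    transported to the same native interface point set under a single plan:
    cost(k, j) = ||a_k - t_j||^2 + ||b_k - t_j||^2.  The shared plan ties the
    two sides together index-by-index, so at convergence row k of both sides
    coincides on the same physical interface point — exactly what the
    index-correspondence Kabsch alignment in the assembly step requires.
    """
    A, B, T = _coords(pred_a), _coords(pred_b), _coords(target)
    if np.shape(A)[0] != np.shape(B)[0]:
        raise ValueError("pocket pair must share cardinality")
    if np.shape(A)[0] == 0 or np.shape(T)[0] == 0:
        raise DegenerateInputError("empty pocket point set")
    cost = (anp.sum((A[:, None, :] - T[None, :, :]) ** 2, axis=2)
            + anp.sum((B[:, None, :] - T[None, :, :]) ** 2, axis=2))
    plan = _transport_plan(_detach(cost))
    return anp.sum(plan * cost)


def intersection_penalty(complex: TernaryComplex, sigma: float = 1.5,
                         gamma: float = 1.0, scale: float = 1.0):
    """Summed Gaussian-overlap clash penalty over the three entity pairs.

    ``sigma`` is in Angstrom; ``scale`` converts it when coordinates are in
    a normalized frame (sigma_effective = sigma / scale).  Non-negative,
    zero for well-separated entities, and non-decreasing as entities
    interpenetrate.
    """
    sig = sigma / scale
    ents = complex.entities() if hasattr(complex, "entities") else dict(complex)
    pairs = (("p1", "p2"), ("p1", "lig"), ("p2", "lig"))
    penalty = 0.0
    for a, b in pairs:
        A, B = ents[a], ents[b]
        d2 = anp.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=2)
        overlap_a = anp.sum(anp.exp(-d2 / sig**2), axis=1)  # per atom of A
        overlap_b = anp.sum(anp.exp(-d2 / sig**2), axis=0)
        relu = lambda x: anp.maximum(x, 0.0)
        penalty = penalty + 0.5 * (anp.mean(relu(overlap_a - gamma))
                                   + anp.mean(relu(overlap_b - gamma)))
    return penalty


def rmsd(pred, truth):
    """Unaligned coordinate RMSD."""
    pred, truth = _coords(pred), _coords(truth)
    if np.shape(pred) != np.shape(truth):
        raise ValueError("shape mismatch")
    return anp.sqrt(anp.mean(anp.sum((pred - truth) ** 2, axis=1)))


def pae_loss(predicted_pae, p2_pred, p2_truth):
    """L1 between the PAE estimate and protein2's coordinate RMSD.

    The RMSD target is the unaligned RMSD of protein2 in protein1's frame
    and is treated as a constant label.
    """
    value = getattr(predicted_pae, "value", predicted_pae)
    target = rmsd(_detach(p2_pred), _detach(p2_truth))
    return anp.abs(value - target)


def total_loss(pred_lig, truth_lig, interface1, interface2,
               complex: TernaryComplex, predicted_pae, p2_pred, p2_truth,
               weights=None, sigma: float = 1.5, scale: float = 1.0) -> LossBundle:
    """Assemble the six-term bundle (unweighted sum by default).

    ``interface1`` is (pred_side_a, pred_side_b, native_points) for the
    ligand<->protein1 interface, fed to the shared-plan pair transport;
    ``interface2`` is the same for protein2<->protein1.  Per-term weights
    default to 1, matching the unweighted sum of the objective.
    """
    w = {"lig": 1.0, "kabsch_lig": 1.0, "ot1": 1.0, "ot2": 1.0,
         "intersection": 1.0, "pae": 1.0}
    if weights:
        w.update(weights)
    return LossBundle(
        lig=w["lig"] * ligand_mse(pred_lig, truth_lig),
        kabsch_lig=w["kabsch_lig"] * kabsch_ligand_mse(pred_lig, truth_lig),
        ot1=w["ot1"] * ot_pair_loss(*interface1),
        ot2=w["ot2"] * ot_pair_loss(*interface2),
        intersection=w["intersection"] * intersection_penalty(
            complex, sigma=sigma, scale=scale),
        pae=w["pae"] * pae_loss(predicted_pae, p2_pred, p2_truth),
    )
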