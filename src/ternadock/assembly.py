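"""Rigid-body assembly of the final ternary complex.

Protein1 defines the fixed frame.  The ligand and protein2 are placed by
Kabsch superposition of corresponding pocket-point sets:

* PROTAC mode: the PROTAC is first aligned onto the unbound anchor pocket of
  protein1; the (now placed) warhead atoms then serve as the target for
  aligning protein2's unbound pose.
* Molecular-glue mode: the ligand and protein2 are each aligned directly into
  protein1's frame using the decoder's predicted pocket-point pairs.

Convention: ``kabsch(P, Q)`` returns the proper rigid transform mapping the
FIRST argument onto the SECOND, so the update equations read literally as
"move the entity carrying P onto the target points Q".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .graphs import RigidTransform

__all__ = [
    "CorrespondenceError",
    "DegenerateAlignmentError",
    "TernaryComplex",
    "kabsch",
    "assemble_protac",
    "assemble_mgd",
    "write_pdb",
    "write_cif",
    "write_transform_log",
]


class CorrespondenceError(ValueError):
    pass


class DegenerateAlignmentError(ValueError):
    pass


@dataclass
class TernaryComplex:
    """Assembled p1 / ligand / p2 coordinates in protein1's frame.

    p1 coordinates are bitwise the input p1; ligand and p2 are rigidly
    placed, so their internal geometry is preserved.
    """

    p1_coords: np.ndarray
    lig_coords: np.ndarray
    p2_coords: np.ndarray
    mode: str = "mgd"  # "protac" | "mgd"
    transforms: Dict[str, RigidTransform] = field(default_factory=dict)
    p1_labels: Optional[Sequence[str]] = None
    p2_labels: Optional[Sequence[str]] = None
    lig_elements: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.p1_coords = np.asarray(self.p1_coords, dtype=float)
        self.lig_coords = np.asarray(self.lig_coords, dtype=float)
        self.p2_coords = np.asarray(self.p2_coords, dtype=float)

    def entities(self):
        return {"p1": self.p1_coords, "lig": self.lig_coords, "p2": self.p2_coords}


def _points(x) -> np.ndarray:
    pts = getattr(x, "points", x)
    return np.asarray(getattr(pts, "_value", pts), dtype=float)


def kabsch(P, Q, allow_degenerate: bool = False) -> RigidTransform:
    """Least-squares rigid superposition of P onto Q (index correspondence).

    Returns the proper rotation/translation minimizing sum ||R p_i + t - q_i||^2.
    Reflections are corrected by flipping the sign of the smallest singular
    vector.  Raises for mismatched cardinalities, fewer than 3 points, or
    rank-deficient (collinear/coincident) configurations unless
    ``allow_degenerate``.
    """
    P, Q = _points(P), _points(Q)
    if P.shape != Q.shape:
        raise CorrespondenceError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise DegenerateAlignmentError("need at least 3 corresponding points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    C = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(C)
    if not allow_degenerate and S[1] <= 1e-9 * max(1.0, S[0]):
        raise DegenerateAlignmentError("point set is (near-)collinear; rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return RigidTransform(R, t)


def kabsch_residual_rmsd(P, Q, tf: Optional[RigidTransform] = None) -> float:
    P, Q = _points(P), _points(Q)
    if tf is None:
        tf = kabsch(P, Q)
    return float(np.sqrt(np.mean(np.sum((tf.apply(P) - Q) ** 2, axis=1))))


def assemble_protac(
    lig_pred: np.ndarray,
    p1_coords: np.ndarray,
    p2_unbound: np.ndarray,
    pocket_p1,
    pocket_p2,
    anchor_mask: Sequence[int],
    warhead_mask: Sequence[int],
    **labels,
) -> TernaryComplex:
    """Place the PROTAC and protein2 using unbound binary pockets.

    ``pocket_p1`` holds the anchor atoms' coordinates in protein1's frame
    (from the anchor-E3 binary pose); ``pocket_p2`` the warhead atoms in
    protein2's unbound frame.  ``anchor_mask`` / ``warhead_mask`` index those
    atoms within the PROTAC, index-aligned with the pocket poses.

    Step 1 aligns the predicted PROTAC conformation onto the anchor pocket;
    step 2 re-expresses the warhead in protein1's frame; step 3 aligns the
    unbound protein2 (via its warhead pose) onto those warhead positions.
    Protein1 is untouched.
    """
    lig_pred = np.asarray(getattr(lig_pred, "_value", lig_pred), dtype=float)
    anchor_mask = np.asarray(anchor_mask, dtype=int)
    warhead_mask = np.asarray(warhead_mask, dtype=int)
    if len(anchor_mask) < 3 or len(warhead_mask) < 3:
        raise DegenerateAlignmentError("anchor/warhead masks need >= 3 atoms")
    tf_lig = kabsch(lig_pred[anchor_mask], pocket_p1)
    x_lig = tf_lig.apply(lig_pred)
    warhead_placed = x_lig[warhead_mask]  # == tf_lig applied to P_lig->p2
    tf_p2 = kabsch(pocket_p2, warhead_placed)
    x_p2 = tf_p2.apply(np.asarray(p2_unbound, dtype=float))
    return TernaryComplex(
        p1_coords=np.asarray(p1_coords, dtype=float),
        lig_coords=x_lig,
        p2_coords=x_p2,
        mode="protac",
        transforms={"lig": tf_lig, "p2": tf_p2},
        **labels,
    )


def assemble_mgd(
    lig_start: np.ndarray,
    p2_start: np.ndarray,
    p1_coords: np.ndarray,
    pocket_lig,
    pocket_p1_lig,
    pocket_p2,
    pocket_p1_p2,
    strict: bool = True,
    **labels,
) -> TernaryComplex:
    """Direct alignment for molecular glues.

    The ligand moves by kabsch(P_lig, P_p1->lig); protein2 moves by
    kabsch(P_p2, P_p1->p2); both land in protein1's frame.  ``strict=False``
    tolerates (near-)collinear predicted pockets instead of raising — used
    by the inference path, where an undertrained model can emit nearly flat
    point sets.
    """
    P_lig, P_p1_lig = _points(pocket_lig), _points(pocket_p1_lig)
    P_p2, P_p1_p2 = _points(pocket_p2), _points(pocket_p1_p2)
    for a, b in ((P_lig, P_p1_lig), (P_p2, P_p1_p2)):
        if a.shape[0] != b.shape[0]:
            raise CorrespondenceError("pocket pair cardinality mismatch")
        if a.shape[0] < 3:
            raise DegenerateAlignmentError("pocket pair needs >= 3 points")
    tf_lig = kabsch(P_lig, P_p1_lig, allow_degenerate=not strict)
    tf_p2 = kabsch(P_p2, P_p1_p2, allow_degenerate=not strict)
    lig_start = np.asarray(getattr(lig_start, "_value", lig_start), dtype=float)
    p2_start = np.asarray(getattr(p2_start, "_value", p2_start), dtype=float)
    return TernaryComplex(
        p1_coords=np.asarray(p1_coords, dtype=float),
        lig_coords=tf_lig.apply(lig_start),
        p2_coords=tf_p2.apply(p2_start),
        mode="mgd",
        transforms={"lig": tf_lig, "p2": tf_p2},
        **labels,
    )


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def _to_atom_array(complex: TernaryComplex):
    import biotite.structure as struc

    n = len(complex.p1_coords) + len(complex.p2_coords) + len(complex.lig_coords)
    arr = struc.AtomArray(n)
    i = 0
    for coords, chain, labels, hetero in (
        (complex.p1_coords, "A", complex.p1_labels, False),
        (complex.p2_coords, "B", complex.p2_labels, False),
        (complex.lig_coords, "C", None, True),
    ):
        for j, xyz in enumerate(coords):
            arr.coord[i] = xyz
            arr.chain_id[i] = chain
            arr.hetero[i] = hetero
            if hetero:
                arr.res_id[i] = 1
                arr.res_name[i] = "LIG"
                elem = (
                    complex.lig_elements[j]
                    if complex.lig_elements is not None
                    else "C"
                )
                arr.atom_name[i] = f"{elem}{j + 1}"
                arr.element[i] = elem
            else:
                arr.res_id[i] = j + 1
                arr.res_name[i] = labels[j] if labels is not None else "ALA"
                arr.atom_name[i] = "CA"
                arr.element[i] = "C"
            i += 1
    return arr


def write_pdb(complex: TernaryComplex, path: str):
    """Multi-chain PDB: chain A = p1, B = p2, ligand as HETATM residue LIG."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    f.set_structure(_to_atom_array(complex))
    f.write(str(path))


def write_cif(complex: TernaryComplex, path: str):
    import biotite.structure.io.pdbx as pdbx

    f = pdbx.CIFFile()
    pdbx.set_structure(f, _to_atom_array(complex))
    f.write(str(path))


def write_transform_log(complex: TernaryComplex, path: str):
    log = {
        "mode": complex.mode,
        "transforms": {
            k: {"R": tf.R.tolist(), "t": tf.t.tolist()}
            for k, tf in complex.transforms.items()
        },
    }
    with open(str(path), "w") as fh:
        json.dump(log, fh, indent=1)
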