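"""Synthetic toy ternary complexes with full ground truth.

Every fixture is built at runtime: two self-avoiding random-walk "protein"
backbones (Calpha-only, 3.8 A steps, random residue types) facing each other
across a small interface, bridged by a random-coil "ligand" chain whose
first ``anchor_size`` atoms contact protein1 and last ``warhead_size`` atoms
contact protein2 (each within 4 A of at least three distinct residues).  The
generator guarantees the complex passes the curation contact (>= 3 contacts
per protein) and clash (no inter-entity pair < 2 A) filters and that the
protein-protein interface has native contacts under the 5 A DockQ rule.

Along with the native pose the fixture carries:

* ground-truth interface point sets (contact-pair midpoints) for the
  ligand<->protein1 and protein2<->protein1 interfaces, used both as pocket
  training targets and as exact inputs for the assembly round trip;
* per-side pocket node indices (the 4 A membership rule);
* a PROTAC-style unbound pocket bundle: a rigidly displaced copy of
  protein2 with its warhead pose and the anchor pose in protein1's frame,
  plus exact atom-index maps;
* a conformer "pool" for the toy ligand (rigidly perturbed copies of the
  native conformation — toy ligands have no rotamer chemistry);
* synthetic protein "sequences" so dataset clustering/splitting can run.

Chemically realistic energetics are out of scope; atoms carry real element
types (C/N/O) so featurization vocabularies are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import json
import numpy as np

from .assembly import TernaryComplex, write_pdb
from .curation import ComplexRecord
from .decoder import PocketPointSet
from .graphs import (
    AtomNode,
    ConformerPool,
    EntityGraph,
    ResidueNode,
    RigidTransform,
    build_ligand_graph,
    build_protein_graph,
)

__all__ = ["ToyComplexSpec", "ToyComplex", "make_toy_complex", "make_toy_dataset",
           "GenerationError"]

AA3 = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL")
AA1 = "ARNDCQEGHILKMFPSTWYV"
ELEMENTS = ("C", "N", "O")

CA_STEP = 3.8  # A, consecutive Calpha spacing
CONTACT = 4.0  # A, ligand-protein contact rule
PP_POCKET = 10.0  # A, protein-protein interface rule


class GenerationError(RuntimeError):
    pass


@dataclass
class ToyComplexSpec:
    n_res_p1: int = 10
    n_res_p2: int = 10
    n_lig_atoms: int = 9
    anchor_size: int = 3
    warhead_size: int = 3
    interface_separation: float = 4.8
    max_interface_points: int = 8  # pocket-target cap (farthest-point subsample)
    seed: int = 0

    def __post_init__(self):
        if self.anchor_size < 3 or self.warhead_size < 3:
            raise ValueError("anchor/warhead sizes must be >= 3")
        if self.anchor_size + self.warhead_size > self.n_lig_atoms:
            raise ValueError("anchor + warhead exceeds ligand size")


@dataclass
class ToyComplex:
    """A native toy ternary complex plus everything needed to test each stage."""

    spec: ToyComplexSpec
    native: TernaryComplex
    lig_graph: EntityGraph
    p1_graph: EntityGraph
    p2_graph: EntityGraph
    # one native target point set per interface (contact-pair midpoints)
    interface_points: Dict[str, np.ndarray]
    # per-side pocket node indices (4 A / 10 A membership)
    pocket_indices: Dict[str, np.ndarray]
    anchor_mask: np.ndarray
    warhead_mask: np.ndarray
    # PROTAC-style unbound inputs
    p2_unbound: np.ndarray
    p2_unbound_transform: RigidTransform
    anchor_pocket: np.ndarray   # anchor atoms in p1's frame
    warhead_pocket: np.ndarray  # warhead atoms in p2's unbound frame
    pool: ConformerPool
    sequences: Dict[str, str]
    complex_id: str = "TOY0 A B LIG"
    pae_target: float = 0.0

    def ground_truth_pockets(self) -> Dict[str, PocketPointSet]:
        """The four pocket point sets at ground truth (both sides of an
        interface share the interface's native point set)."""
        t1, t2 = self.interface_points["lig_p1"], self.interface_points["p2_p1"]
        return {
            "lig": PocketPointSet(t1, source="ground_truth", interface_tag="lig|p1"),
            "p1_lig": PocketPointSet(t1, source="ground_truth", interface_tag="p1|lig"),
            "p2": PocketPointSet(t2, source="ground_truth", interface_tag="p2|p1"),
            "p1_p2": PocketPointSet(t2, source="ground_truth", interface_tag="p1|p2"),
        }


def _random_walk(rng, n, step=CA_STEP, min_sep=3.4, max_tries=200):
    """Self-avoiding random walk with direction persistence."""
    pts = [np.zeros(3)]
    direction = _unit(rng.normal(size=3))
    for _ in range(n - 1):
        for _ in range(max_tries):
            cand_dir = _unit(0.7 * direction + 0.7 * rng.normal(size=3) * 0.6)
            cand = pts[-1] + step * cand_dir
            if all(np.linalg.norm(cand - p) >= min_sep for p in pts[:-1]):
                pts.append(cand)
                direction = cand_dir
                break
        else:
            raise GenerationError("self-avoiding walk stalled")
    return np.stack(pts)


def _unit(v):
    return v / np.linalg.norm(v)


def _min_cross_dist(a, b):
    return float(np.min(np.linalg.norm(a[:, None] - b[None, :], axis=-1)))


def _spread_ok(points, min_second_sv=0.25):
    """Reject (near-)collinear point sets; Kabsch needs planar spread."""
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return len(s) > 1 and s[1] / np.sqrt(len(points)) > min_second_sv


def _build_geometry(spec: ToyComplexSpec, rng):
    """One attempt at the native geometry; raises GenerationError on failure.

    Construction is ligand-first: a zig-zag chain in the interface plane at
    the origin (anchor block dipping toward protein1, warhead block toward
    protein2), then each flattened protein blob slides in along the
    interface normal until its closest approach to the ligand sits in
    [2.35, 2.7] A — inside the 4 A contact rule and clear of the 2 A clash
    rule.  Finally a few protein2 residues laterally clear of the ligand are
    pulled toward their nearest protein1 partner to the target interface
    separation, creating the native protein-protein contacts DockQ needs.
    """
    from scipy.spatial.transform import Rotation

    u = _unit(rng.normal(size=3))  # interface normal; p1 below, p2 above
    w = _unit(np.cross(u, rng.normal(size=3)))  # in-plane chain direction

    n = spec.n_lig_atoms
    ks = np.arange(n) - (n - 1) / 2.0
    alt = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    zig = 0.3 * alt
    # blocks keep their dip toward the protein they bind but stay
    # non-collinear (the pocket Kabsch needs planar spread)
    zig[: spec.anchor_size] = -0.5 + 0.2 * alt[: spec.anchor_size]
    zig[n - spec.warhead_size:] = 0.5 + 0.2 * alt[n - spec.warhead_size:]
    lig = (np.outer(ks * 1.5, w) + np.outer(zig, u)
           + 0.08 * rng.normal(size=(n, 3)))

    lateral = lambda pts: pts - np.outer(pts @ u, u)

    def flattened_blob(n_res, block_centroid, sign):
        # squash the walk along u so the interface face is broad, not pointy,
        # and centre its face laterally under the ligand block it must bind
        blob = _random_walk(rng, n_res)
        blob = (Rotation.random(random_state=rng).as_matrix() @ blob.T).T
        blob = blob - blob.mean(axis=0)
        blob = blob - 0.72 * np.outer(blob @ u, u)
        face = blob[np.argsort(blob @ (sign * u))[-max(3, n_res // 3):]]
        target = lateral(block_centroid)[None, :] * 0.7
        return blob + (target - lateral(face.mean(axis=0)))[0]

    def slide_to_ligand(blob, sign, block, other=None):
        offsets = np.arange(0.0, 25.0, 0.1)
        placements = [blob + (sign * t) * u for t in offsets]
        dmins = np.array([_min_cross_dist(lig, p) for p in placements])
        admissible = (dmins >= 2.35) & (dmins <= 2.7)
        if other is not None:  # keep clear of the already-placed protein
            admissible &= np.array(
                [_min_cross_dist(other, p) >= 3.3 for p in placements])
        valid = np.flatnonzero(admissible)
        if len(valid) == 0:
            raise GenerationError("no protein placement against the ligand")

        def score(p):
            d = np.linalg.norm(lig[:, None] - p[None, :], axis=-1).min(axis=1)
            return 3 * (d[block] < CONTACT).sum() + (d < CONTACT).sum()

        best = max(valid, key=lambda i: score(placements[i]))
        return placements[best]

    anchor = slice(0, spec.anchor_size)
    warhead = slice(n - spec.warhead_size, n)
    p1 = slide_to_ligand(
        flattened_blob(spec.n_res_p1, lig[anchor].mean(axis=0), -1.0),
        -1.0, anchor)
    p2 = slide_to_ligand(
        flattened_blob(spec.n_res_p2, lig[warhead].mean(axis=0), +1.0),
        +1.0, warhead, other=p1)

    # explicit protein-protein contact bridges away from the ligand
    bridge_gap = min(spec.interface_separation, 4.7)
    lat_clear = np.linalg.norm(
        lateral(p2)[:, None] - lateral(lig)[None, :], axis=-1).min(axis=1)
    cand = np.flatnonzero(lat_clear > 4.0)
    moved = 0
    for j in cand[np.argsort(p2[cand] @ u)]:
        i = int(np.argmin(np.linalg.norm(p1 - p2[j], axis=1)))
        new_j = p1[i] + bridge_gap * _unit(p2[j] - p1[i])
        d_other_p1 = np.delete(np.linalg.norm(p1 - new_j, axis=1), i)
        d_other_p2 = np.delete(np.linalg.norm(p2 - new_j, axis=1), j)
        if (np.min(np.linalg.norm(lig - new_j, axis=1)) >= 2.35
                and d_other_p1.min() >= 3.4 and d_other_p2.min() >= 3.0):
            p2[j] = new_j
            moved += 1
        if moved == 4:
            break

    pp = np.linalg.norm(p1[:, None] - p2[None, :], axis=-1)
    if not ((pp < 5.0).sum() >= 2 and (pp < PP_POCKET).sum() >= 6
            and pp.min() >= 3.2):
        raise GenerationError("protein interface constraints unsatisfied")

    d_l1 = np.linalg.norm(lig[:, None] - p1[None, :], axis=-1)
    d_l2 = np.linalg.norm(lig[:, None] - p2[None, :], axis=-1)
    ok = (
        (d_l1.min(axis=1) < CONTACT).sum() >= 3
        and (d_l2.min(axis=1) < CONTACT).sum() >= 3
        and (d_l1[anchor].min(axis=1) < CONTACT).sum() >= 2
        and (d_l2[warhead].min(axis=1) < CONTACT).sum() >= 2
        and d_l1.min() >= 2.05 and d_l2.min() >= 2.05
        and np.all(np.linalg.norm(np.diff(lig, axis=0), axis=1) < 3.95)
        and _spread_ok(lig[anchor], min_second_sv=0.08)
        and _spread_ok(lig[warhead], min_second_sv=0.08)
    )
    if not ok:
        raise GenerationError("ligand bridge constraints unsatisfied")

    mids1 = _interface_midpoints(lig, p1, CONTACT)
    mids2 = _interface_midpoints(p2, p1, PP_POCKET)
    if not (_spread_ok(mids1) and _spread_ok(mids2)):
        raise GenerationError("interface point sets too degenerate")
    return p1, p2, lig


def _farthest_point_subsample(points, k):
    """Deterministic farthest-point subsampling to at most k points."""
    if len(points) <= k:
        return points
    centroid = points.mean(axis=0)
    chosen = [int(np.argmin(np.linalg.norm(points - centroid, axis=1)))]
    d = np.linalg.norm(points - points[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return points[sorted(chosen)]


def _interface_midpoints(a, b, cutoff, max_points=None):
    d = np.linalg.norm(a[:, None] - b[None, :], axis=-1)
    ii, jj = np.where(d < cutoff)
    if len(ii) < 3:
        raise GenerationError("interface too sparse for pocket targets")
    mids = 0.5 * (a[ii] + b[jj])
    if max_points is not None:
        mids = _farthest_point_subsample(mids, max_points)
    return mids


def make_toy_complex(spec: Optional[ToyComplexSpec] = None,
                     max_retries: int = 50) -> ToyComplex:
    """Generate one toy ternary complex; deterministic in ``spec.seed``."""
    spec = spec or ToyComplexSpec()
    for attempt in range(max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        try:
            p1, p2, lig = _build_geometry(spec, rng)
            break
        except GenerationError:
            continue
    else:
        raise GenerationError(f"no valid geometry after {max_retries} attempts")

    aa1 = [AA3[i] for i in rng.integers(0, 20, size=spec.n_res_p1)]
    aa2 = [AA3[i] for i in rng.integers(0, 20, size=spec.n_res_p2)]
    elems = [ELEMENTS[i] for i in rng.integers(0, 3, size=spec.n_lig_atoms)]
    atomic = {"C": 6, "N": 7, "O": 8}

    lig_nodes = [
        AtomNode(atomic_number=atomic[e], total_degree=2, num_h=2,
                 hybridization="SP3", position=lig[i])
        for i, e in enumerate(elems)
    ]
    p1_nodes = [ResidueNode(a, p1[i]) for i, a in enumerate(aa1)]
    p2_nodes = [ResidueNode(a, p2[i]) for i, a in enumerate(aa2)]

    lig_graph = build_ligand_graph(lig_nodes, lig)
    p1_graph = build_protein_graph(p1_nodes, k=min(10, spec.n_res_p1 - 1), role="p1")
    p2_graph = build_protein_graph(p2_nodes, k=min(10, spec.n_res_p2 - 1), role="p2")

    native = TernaryComplex(
        p1_coords=p1, lig_coords=lig, p2_coords=p2, mode="mgd",
        p1_labels=aa1, p2_labels=aa2, lig_elements=elems,
    )

    cap = spec.max_interface_points
    t1 = _interface_midpoints(lig, p1, CONTACT, max_points=cap)
    t2 = _interface_midpoints(p2, p1, PP_POCKET, max_points=cap)
    t_l2 = _interface_midpoints(lig, p2, CONTACT, max_points=cap)

    d_l1 = np.linalg.norm(lig[:, None] - p1[None, :], axis=-1)
    d_l2 = np.linalg.norm(lig[:, None] - p2[None, :], axis=-1)
    d_pp = np.linalg.norm(p2[:, None] - p1[None, :], axis=-1)
    pocket_indices = {
        "lig_near_p1": np.flatnonzero(d_l1.min(axis=1) < CONTACT),
        "lig_near_p2": np.flatnonzero(d_l2.min(axis=1) < CONTACT),
        "p1_near_lig": np.flatnonzero(d_l1.min(axis=0) < CONTACT),
        "p2_near_lig": np.flatnonzero(d_l2.min(axis=0) < CONTACT),
        "p2_near_p1": np.flatnonzero(d_pp.min(axis=1) < PP_POCKET),
        "p1_near_p2": np.flatnonzero(d_pp.min(axis=0) < PP_POCKET),
    }

    anchor_mask = np.arange(spec.anchor_size)
    warhead_mask = np.arange(spec.n_lig_atoms - spec.warhead_size, spec.n_lig_atoms)

    # unbound protein2: native pose displaced by a known rigid motion; the
    # warhead pose travels with it, giving exact index-aligned pockets
    from .graphs import apply_random_se3

    p2_moved_graph, tf_unbound = apply_random_se3(p2_graph, seed=spec.seed + 7)
    p2_unbound = p2_moved_graph.positions()
    anchor_pocket = lig[anchor_mask].copy()
    warhead_pocket = tf_unbound.apply(lig[warhead_mask])

    # toy conformer pool: rigid copies of the native conformation
    pool_seeds = list(range(8))
    confs = []
    for s in pool_seeds:
        g, _ = apply_random_se3(lig_graph, seed=(spec.seed * 1000 + s) % (2**31))
        confs.append(g.positions())
    pool = ConformerPool(molecule_id=f"toy-{spec.seed}", conformers=confs,
                         seeds=pool_seeds)

    sequences = {
        "p1": "".join(AA1[AA3.index(a)] for a in aa1),
        "p2": "".join(AA1[AA3.index(a)] for a in aa2),
    }

    return ToyComplex(
        spec=spec, native=native,
        lig_graph=lig_graph, p1_graph=p1_graph, p2_graph=p2_graph,
        interface_points={"lig_p1": t1, "p2_p1": t2, "lig_p2": t_l2},
        pocket_indices=pocket_indices,
        anchor_mask=anchor_mask, warhead_mask=warhead_mask,
        p2_unbound=p2_unbound, p2_unbound_transform=tf_unbound,
        anchor_pocket=anchor_pocket, warhead_pocket=warhead_pocket,
        pool=pool, sequences=sequences,
        complex_id=f"TOY{spec.seed % 10000:04d} A B LIG",
    )


def _mutate(seq: str, rng, n_mut: int) -> str:
    s = list(seq)
    for _ in range(n_mut):
        s[rng.integers(0, len(s))] = AA1[rng.integers(0, 20)]
    return "".join(s)


def make_toy_dataset(n: int, seed: int = 0, cluster_size: int = 3):
    """``n`` fixtures grouped into sequence clusters.

    Each base fixture seeds a cluster; cluster mates reuse its geometry but
    carry lightly mutated sequences, so the identity clusterer groups them.
    Returns (complexes, records, clusters) where ``clusters`` maps
    cluster_id -> member complex ids (first member is the representative).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    complexes: List[ToyComplex] = []
    records: List[ComplexRecord] = []
    clusters: Dict[str, List[str]] = {}
    idx = 0
    base_seed = 0
    while idx < n:
        base = make_toy_complex(ToyComplexSpec(seed=seed * 10007 + base_seed))
        cluster_id = f"cl{base_seed}"
        clusters[cluster_id] = []
        for member in range(min(cluster_size, n - idx)):
            cid = f"TOY{idx:04d} A B LIG"
            toy = base if member == 0 else _with_mutated_sequences(base, rng, cid)
            if member == 0:
                toy = _with_id(base, cid)
            complexes.append(toy)
            records.append(ComplexRecord(
                entry_id=f"TOY{idx:04d}", chain_p1="A", chain_p2="B",
                ligand_id="LIG", method="X-RAY DIFFRACTION",
                resolution=float(rng.uniform(1.2, 2.8)),
                r_free=float(rng.uniform(0.15, 0.25)),
                lengths=(toy.spec.n_res_p1, toy.spec.n_res_p2),
                sequences=(toy.sequences["p1"], toy.sequences["p2"]),
            ))
            clusters[cluster_id].append(cid)
            idx += 1
        base_seed += 1
    return complexes, records, clusters


def _with_id(toy: ToyComplex, cid: str) -> ToyComplex:
    import copy

    t = copy.copy(toy)
    t.complex_id = cid
    return t


def _with_mutated_sequences(toy: ToyComplex, rng, cid: str) -> ToyComplex:
    import copy

    t = copy.copy(toy)
    t.sequences = {k: _mutate(v, rng, n_mut=max(1, len(v) // 5))
                   for k, v in toy.sequences.items()}
    t.complex_id = cid
    return t


def write_fixture(toy: ToyComplex, out_dir) -> None:
    """Write the fixture as PDB + SDF + a JSON ground-truth bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pdb(toy.native, out / "native.pdb")
    _write_sdf(toy, out / "ligand.sdf")
    bundle = {
        "complex_id": toy.complex_id,
        "interface_points": {k: v.tolist() for k, v in toy.interface_points.items()},
        "pocket_indices": {k: v.tolist() for k, v in toy.pocket_indices.items()},
        "anchor_mask": toy.anchor_mask.tolist(),
        "warhead_mask": toy.warhead_mask.tolist(),
        "p2_unbound": toy.p2_unbound.tolist(),
        "anchor_pocket": toy.anchor_pocket.tolist(),
        "warhead_pocket": toy.warhead_pocket.tolist(),
        "sequences": toy.sequences,
        "pae_target": toy.pae_target,
    }
    (out / "ground_truth.json").write_text(json.dumps(bundle, indent=1))


def _write_sdf(toy: ToyComplex, path) -> None:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for node in toy.lig_graph.nodes:
        a = Chem.Atom(int(node.atomic_number))
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    n = toy.lig_graph.n_nodes
    for i in range(n - 1):
        mol.AddBond(i, i + 1, Chem.BondType.SINGLE)
    conf = Chem.Conformer(n)
    for i, node in enumerate(toy.lig_graph.nodes):
        conf.SetAtomPosition(i, Point3D(*node.position))
    m = mol.GetMol()
    m.AddConformer(conf)
    with Chem.SDWriter(str(path)) as w:
        w.write(m)
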