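"""Geometric-graph featurization of ligands and proteins.

A ternary complex is handled as three entities -- protein1 (the fixed frame,
e.g. an E3 ligase), a small molecule, and protein2 (the protein of interest).
Each entity becomes an :class:`EntityGraph`: nodes carry chemical features and
3D coordinates, edges carry relative-distance descriptors.  Ligand edges
connect heavy-atom pairs closer than 4 A in the construction conformation;
protein graphs use k-nearest-neighbour connectivity over residue
representative atoms (Calpha).

The module also provides RDKit-backed conformer-pool generation (ETKDG, one
conformer per seed), seeded SE(3) perturbations used for training
augmentation, and pocket embeddings that mark interface nodes and optionally
pin their coordinates to an unbound binary pose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomNode",
    "ResidueNode",
    "EntityGraph",
    "ConformerPool",
    "RigidTransform",
    "DegenerateInputError",
    "ConformerGenerationError",
    "LIGAND_EDGE_CUTOFF",
    "build_ligand_graph",
    "build_protein_graph",
    "generate_conformer_pool",
    "apply_random_se3",
    "attach_pocket_embedding",
    "strip_pocket_embedding",
    "atoms_from_rdkit",
    "ligand_from_file",
    "ligand_from_smiles",
    "protein_residues_from_file",
    "graph_to_json",
    "graph_from_json",
]

LIGAND_EDGE_CUTOFF = 4.0  # A, strict "<"

# fixed categorical vocabularies; the final bucket is "unknown"
CHIRALITY_VOCAB = (
    "CHI_UNSPECIFIED",
    "CHI_TETRAHEDRAL_CW",
    "CHI_TETRAHEDRAL_CCW",
    "CHI_OTHER",
    "unknown",
)
HYBRIDIZATION_VOCAB = ("S", "SP", "SP2", "SP3", "SP3D", "SP3D2", "unknown")
AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "UNK",
)

N_RBF = 8  # Gaussian radial-basis centres spanning [0, cutoff]


class DegenerateInputError(ValueError):
    """Raised for inputs too small/degenerate for the requested operation."""


class ConformerGenerationError(RuntimeError):
    """Raised when 3D embedding fails for a seed after retries."""


@dataclass(frozen=True)
class AtomNode:
    """One heavy atom of the small molecule."""

    atomic_number: int
    chirality: str = "CHI_UNSPECIFIED"
    total_degree: int = 0
    formal_charge: int = 0
    implicit_h: int = 0
    num_h: int = 0
    radical_electrons: int = 0
    hybridization: str = "SP3"
    is_aromatic: bool = False
    in_ring: bool = False
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pocket_flag: bool = False

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")

    def feature_vector(self) -> np.ndarray:
        chir = _one_hot(self.chirality, CHIRALITY_VOCAB)
        hyb = _one_hot(self.hybridization, HYBRIDIZATION_VOCAB)
        scalars = np.array(
            [
                float(self.atomic_number),
                float(self.total_degree),
                float(self.formal_charge),
                float(self.implicit_h),
                float(self.num_h),
                float(self.radical_electrons),
                float(self.is_aromatic),
                float(self.in_ring),
            ]
        )
        return np.concatenate([scalars, chir, hyb])


@dataclass(frozen=True)
class ResidueNode:
    """One residue, represented by its Calpha coordinate."""

    amino_acid_type: str
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pocket_flag: bool = False

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.all(np.isfinite(self.position)):
            raise ValueError("residue position must be finite")
        aa = self.amino_acid_type.upper()
        if aa not in AMINO_ACIDS:
            aa = "UNK"
        object.__setattr__(self, "amino_acid_type", aa)

    def feature_vector(self) -> np.ndarray:
        return _one_hot(self.amino_acid_type, AMINO_ACIDS)


def _one_hot(value, vocab) -> np.ndarray:
    v = np.zeros(len(vocab))
    try:
        v[vocab.index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0  # unknown bucket
    return v


@dataclass
class EntityGraph:
    """A geometric graph for one entity of the ternary complex.

    Edges are stored directionally: both (i, j) and (j, i) are present.
    ``edge_index`` is (2, E) with row 0 = source j, row 1 = target i, so
    column e encodes the message j -> i.  ``edge_features`` holds the
    Euclidean distance in column 0 followed by a radial-basis expansion
    (and optional angular descriptors for ligand graphs).
    """

    role: str  # "lig" | "p1" | "p2"
    nodes: list
    edge_index: np.ndarray
    edge_features: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def positions(self) -> np.ndarray:
        if not self.nodes:
            return np.zeros((0, 3))
        return np.stack([n.position for n in self.nodes])

    def node_features(self) -> np.ndarray:
        return np.stack([n.feature_vector() for n in self.nodes])

    def pocket_mask(self) -> np.ndarray:
        return np.array([n.pocket_flag for n in self.nodes], dtype=bool)

    def with_positions(self, coords: np.ndarray) -> "EntityGraph":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_nodes, 3):
            raise ValueError(f"coordinate shape {coords.shape} does not match graph")
        nodes = [replace(n, position=coords[i]) for i, n in enumerate(self.nodes)]
        return EntityGraph(self.role, nodes, self.edge_index.copy(), self.edge_features.copy())

    def edge_list(self):
        """Edges as (target i, source j) pairs, matching the j->i convention."""
        return [(int(self.edge_index[1, e]), int(self.edge_index[0, e]))
                for e in range(self.n_edges)]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("R is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("R is not a proper rotation (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply ``other``, then ``self``."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class ConformerPool:
    """Pre-generated 3D conformations of one molecule, one per seed."""

    molecule_id: str
    conformers: list  # of (n_atoms, 3) arrays
    seeds: list

    def __post_init__(self):
        if len(self.conformers) != len(self.seeds):
            raise ValueError("conformer/seed count mismatch")
        shapes = {c.shape for c in self.conformers}
        if len(shapes) > 1:
            raise ValueError("conformers disagree on atom count")

    def __len__(self):
        return len(self.conformers)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def _rbf(d: np.ndarray, cutoff: float) -> np.ndarray:
    centers = np.linspace(0.0, cutoff, N_RBF)
    width = cutoff / N_RBF
    return np.exp(-((d[:, None] - centers[None, :]) ** 2) / (2.0 * width**2))


def _edge_features(coords, src, dst, cutoff, angular_ref=None):
    d = np.linalg.norm(coords[dst] - coords[src], axis=1)
    feats = [d[:, None], _rbf(d, cutoff)]
    if angular_ref is not None:
        # optional angular descriptor: cosine of the angle between the edge
        # vector and the direction from the source atom to the molecular
        # centroid of the construction conformation
        vec = coords[dst] - coords[src]
        ref = angular_ref - coords[src]
        num = np.einsum("ij,ij->i", vec, ref)
        den = np.linalg.norm(vec, axis=1) * np.linalg.norm(ref, axis=1) + 1e-12
        feats.append((num / den)[:, None])
    return np.concatenate(feats, axis=1)


def build_ligand_graph(
    atoms: Sequence[AtomNode],
    conformation: np.ndarray,
    cutoff: float = LIGAND_EDGE_CUTOFF,
    angular: bool = False,
) -> EntityGraph:
    """Distance-thresholded ligand graph: edges strictly below ``cutoff`` A.

    ``conformation`` overrides the atoms' stored positions and defines edge
    topology.  Both edge directions are stored.
    """
    if len(atoms) < 2:
        raise DegenerateInputError("ligand graph needs at least 2 atoms")
    coords = np.asarray(conformation, dtype=float)
    if coords.shape != (len(atoms), 3):
        raise ValueError(f"conformation shape {coords.shape} != ({len(atoms)}, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("conformation must be finite")

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    n = len(atoms)
    src, dst = [], []
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] < cutoff:
                src.append(j)  # message j -> i
                dst.append(i)
    edge_index = np.array([src, dst], dtype=int).reshape(2, -1)
    angular_ref = coords.mean(axis=0) if angular else None
    if edge_index.shape[1]:
        ef = _edge_features(coords, edge_index[0], edge_index[1], cutoff, angular_ref)
    else:
        ef = np.zeros((0, 1 + N_RBF + (1 if angular else 0)))
    nodes = [replace(a, position=coords[i]) for i, a in enumerate(atoms)]
    return EntityGraph("lig", nodes, edge_index, ef)


def build_protein_graph(
    residues: Sequence[ResidueNode],
    k: int = 10,
    role: str = "p1",
) -> EntityGraph:
    """k-nearest-neighbour residue graph; ties broken by ascending index.

    Each node i receives a directed edge from each of its k nearest other
    nodes (fewer when the chain has < k+1 residues).
    """
    if len(residues) == 0:
        raise DegenerateInputError("empty residue list")
    if len(residues) < 2:
        raise DegenerateInputError("protein graph needs at least 2 residues")
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = np.stack([r.position for r in residues])
    n = len(residues)
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    src, dst = [], []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        # lexicographic (distance, index) ordering makes ties deterministic
        order = sorted(others, key=lambda j: (dist[i, j], j))
        for j in order[: min(k, n - 1)]:
            src.append(j)
            dst.append(i)
    edge_index = np.array([src, dst], dtype=int).reshape(2, -1)
    cutoff = max(float(dist.max()), 1e-6)
    ef = _edge_features(coords, edge_index[0], edge_index[1], cutoff)
    return EntityGraph(role, list(residues), edge_index, ef)


# ---------------------------------------------------------------------------
# conformer pools (RDKit / ETKDG)
# ---------------------------------------------------------------------------

def _embed_one(mol, seed: int) -> np.ndarray:
    from rdkit.Chem import AllChem

    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    m = AllChem.AddHs(mol)
    ok = AllChem.EmbedMolecule(m, params)
    if ok != 0:
        params.useRandomCoords = True
        ok = AllChem.EmbedMolecule(m, params)
    if ok != 0:
        raise ConformerGenerationError(f"3D embedding failed for seed {seed}")
    from rdkit.Chem import RemoveHs

    m = RemoveHs(m)
    return np.array(m.GetConformer().GetPositions(), dtype=float)


def generate_conformer_pool(
    smiles: str, n: int, seeds: Sequence[int]
) -> ConformerPool:
    """Embed ``n`` random conformations, one per seed (ETKDGv3).

    The same seed always yields bitwise-identical coordinates.  Training
    pools use n = 50 by convention.
    """
    from rdkit import Chem

    if n != len(seeds):
        raise ValueError("n must equal len(seeds)")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    confs = [_embed_one(mol, s) for s in seeds]
    return ConformerPool(smiles, confs, list(seeds))


def atoms_from_rdkit(mol, conf_id: int = -1) -> list:
    """Heavy-atom :class:`AtomNode` list from an RDKit molecule."""
    from rdkit import Chem

    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer(conf_id) if mol.GetNumConformers() else None
    nodes = []
    for a in mol.GetAtoms():
        pos = (
            np.array(conf.GetAtomPosition(a.GetIdx()))
            if conf is not None
            else np.zeros(3)
        )
        nodes.append(
            AtomNode(
                atomic_number=a.GetAtomicNum(),
                chirality=str(a.GetChiralTag()),
                total_degree=a.GetTotalDegree(),
                formal_charge=a.GetFormalCharge(),
                implicit_h=a.GetNumImplicitHs(),
                num_h=a.GetTotalNumHs(),
                radical_electrons=a.GetNumRadicalElectrons(),
                hybridization=str(a.GetHybridization()),
                is_aromatic=a.GetIsAromatic(),
                in_ring=a.IsInRing(),
                position=pos,
            )
        )
    return nodes


def ligand_from_smiles(smiles: str, seed: int = 0):
    """(AtomNode list, conformation) for a SMILES string, ETKDG-embedded."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    coords = _embed_one(mol, seed)
    atoms = atoms_from_rdkit(mol)
    atoms = [replace(a, position=coords[i]) for i, a in enumerate(atoms)]
    return atoms, coords


def ligand_from_file(path: str):
    """Load a ligand from SDF / MOL2 / PDB; returns (AtomNode list, coords)."""
    from rdkit import Chem

    p = str(path)
    if p.endswith(".sdf"):
        supp = Chem.SDMolSupplier(p, removeHs=True, sanitize=False)
        mol = next(iter(supp))
    elif p.endswith(".mol2"):
        mol = Chem.MolFromMol2File(p, removeHs=True, sanitize=False)
    else:
        mol = Chem.MolFromPDBFile(p, removeHs=True, sanitize=False)
    if mol is None:
        raise ValueError(f"could not parse ligand file {path}")
    atoms = atoms_from_rdkit(mol)
    coords = np.stack([a.position for a in atoms])
    return atoms, coords


def protein_residues_from_file(path: str, chain: Optional[str] = None) -> list:
    """Residue nodes (Calpha) from a PDB or mmCIF file.

    Altloc handling keeps the highest-occupancy location (first on tie),
    which is biotite's ``altloc="occupancy"`` behaviour.
    """
    import biotite.structure as struc

    p = str(path)
    if p.endswith(".cif") or p.endswith(".mmcif"):
        import biotite.structure.io.pdbx as pdbx

        f = pdbx.CIFFile.read(p)
        arr = pdbx.get_structure(f, model=1, altloc="occupancy")
    else:
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile.read(p)
        arr = f.get_structure(model=1, altloc="occupancy")
    arr = arr[struc.filter_amino_acids(arr)]
    if chain is not None:
        arr = arr[arr.chain_id == chain]
    ca = arr[arr.atom_name == "CA"]
    return [
        ResidueNode(amino_acid_type=str(res), position=np.array(pos))
        for res, pos in zip(ca.res_name, ca.coord)
    ]


# ---------------------------------------------------------------------------
# SE(3) augmentation
# ---------------------------------------------------------------------------

def apply_random_se3(
    graph: EntityGraph, seed: int, translation_radius: float = 10.0
):
    """Seeded uniform rotation + translation uniform in a ball.

    Features and edge topology are untouched; the applied transform is
    returned so it can be inverted or logged.
    """
    if graph.n_nodes == 0:
        raise DegenerateInputError("cannot transform an empty graph")
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    # uniform in a ball via radius ~ U^(1/3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = translation_radius * rng.uniform() ** (1.0 / 3.0)
    t = direction * radius
    tf = RigidTransform(R, t)
    return graph.with_positions(tf.apply(graph.positions())), tf


# ---------------------------------------------------------------------------
# pocket embeddings
# ---------------------------------------------------------------------------

def attach_pocket_embedding(
    graph: EntityGraph,
    pocket_indices: Sequence[int],
    pocket_coords: Optional[np.ndarray] = None,
) -> EntityGraph:
    """Flag pocket nodes; optionally pin their coordinates.

    At inference (unbound-pocket protocol) ``pocket_coords`` carries the
    coordinates from the binary pose and replaces the flagged nodes'
    positions.  During training it is None and positions are already the
    ground-truth (post-augmentation) values, so only flags are set.  The
    learnable pocket embedding itself is added to flagged nodes' latent
    features inside the encoder.
    """
    idx = list(pocket_indices)
    for i in idx:
        if not (0 <= i < graph.n_nodes):
            raise IndexError(f"pocket index {i} out of range for graph of size {graph.n_nodes}")
    if pocket_coords is not None:
        pocket_coords = np.asarray(pocket_coords, dtype=float)
        if pocket_coords.shape != (len(idx), 3):
            raise ValueError("pocket_coords shape must be (len(indices), 3)")
    nodes = list(graph.nodes)
    for rank, i in enumerate(idx):
        kw = {"pocket_flag": True}
        if pocket_coords is not None:
            kw["position"] = pocket_coords[rank]
        nodes[i] = replace(nodes[i], **kw)
    return EntityGraph(graph.role, nodes, graph.edge_index.copy(), graph.edge_features.copy())


def strip_pocket_embedding(graph: EntityGraph) -> EntityGraph:
    """Clear all pocket flags (positions are left as they are)."""
    nodes = [replace(n, pocket_flag=False) for n in graph.nodes]
    return EntityGraph(graph.role, nodes, graph.edge_index.copy(), graph.edge_features.copy())


# ---------------------------------------------------------------------------
# JSON fixture format
# ---------------------------------------------------------------------------

def graph_to_json(graph: EntityGraph) -> str:
    """Serialize a graph to the documented JSON fixture format."""
    payload = {
        "role": graph.role,
        "node_kind": "atom" if graph.role == "lig" else "residue",
        "nodes": [],
        "edge_index": graph.edge_index.tolist(),
        "edge_features": graph.edge_features.tolist(),
    }
    for n in graph.nodes:
        d = {k: v for k, v in n.__dict__.items() if k != "position"}
        d["position"] = n.position.tolist()
        payload["nodes"].append(d)
    return json.dumps(payload)


def graph_from_json(text: str) -> EntityGraph:
    payload = json.loads(text)
    cls = AtomNode if payload["node_kind"] == "atom" else ResidueNode
    nodes = [cls(**d) for d in payload["nodes"]]
    return EntityGraph(
        payload["role"],
        nodes,
        np.array(payload["edge_index"], dtype=int).reshape(2, -1),
        np.array(payload["edge_features"], dtype=float),
    )
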