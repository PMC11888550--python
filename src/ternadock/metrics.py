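"""Interface-quality metrics: DockQ, CAPRI classes, acceptable rank, Calpha
RMSD, and buried surface area.

DockQ combines three ingredients computed on the protein1-protein2 interface:
Fnat (fraction of native residue-residue contacts preserved; 5 A heavy-atom
contact cutoff), LRMS (backbone RMSD of the mobile chain after superposing
the receptor) and iRMS (backbone RMSD over interface residues, defined with
the 10 A cutoff), blended as

    DockQ = ( Fnat + 1/(1 + (iRMS/1.5)^2) + 1/(1 + (LRMS/8.5)^2) ) / 3.

In this package's frame convention protein1 is the receptor.  The toy and
engine structures represent protein backbones by Calpha atoms, so "backbone"
and "heavy atom" reduce to Calpha for proteins.

CAPRI classes are assigned from DockQ bands (>= 0.80 High, > 0.49 Medium,
> 0.23 Acceptable, else Incorrect) — an approximation to the original CAPRI
decision tree, consistent with how the bands are reported alongside DockQ.

Buried surface area uses Shrake-Rupley SASA (probe 1.4 A, golden-spiral
sphere points): for each entity pair, BSA = SASA(A) + SASA(B) - SASA(A+B),
and the total sums the protein-protein and the two protein-ligand pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .assembly import TernaryComplex, kabsch

__all__ = [
    "DockQResult",
    "BSAResult",
    "UndefinedMetricError",
    "dockq",
    "capri_class",
    "acceptable_rank",
    "ca_rmsd",
    "ca_rmsd_acceptable",
    "shrake_rupley_sasa",
    "buried_surface_area",
    "top5_mean_bsa",
    "CONTACT_CUTOFF",
    "INTERFACE_CUTOFF",
]

CONTACT_CUTOFF = 5.0  # A, Fnat contact definition
INTERFACE_CUTOFF = 10.0  # A, interface-residue definition
PROBE_RADIUS = 1.4  # A, water probe

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


class UndefinedMetricError(ValueError):
    pass


@dataclass
class DockQResult:
    fnat: float
    lrms: float
    irms: float
    dockq: float
    capri_class: str


@dataclass
class BSAResult:
    per_pair: Dict[str, float]
    total: float


def _contact_pairs(a: np.ndarray, b: np.ndarray, cutoff: float):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return set(zip(*np.where(d < cutoff)))


def dockq(pred: TernaryComplex, native: TernaryComplex) -> DockQResult:
    """DockQ of the p1-p2 protein interface, pred vs native.

    Residue correspondence is by index within each chain.  Raises
    :class:`UndefinedMetricError` when the native interface has no contacts.
    """
    n1, n2 = native.p1_coords, native.p2_coords
    q1, q2 = pred.p1_coords, pred.p2_coords
    if n1.shape != q1.shape or n2.shape != q2.shape:
        raise ValueError("pred/native chain sizes differ")

    native_contacts = _contact_pairs(n1, n2, CONTACT_CUTOFF)
    if not native_contacts:
        raise UndefinedMetricError("native p1-p2 interface has no contacts")
    pred_contacts = _contact_pairs(q1, q2, CONTACT_CUTOFF)
    fnat = len(native_contacts & pred_contacts) / len(native_contacts)

    # receptor (p1) superposition, then RMSD of the mobile chain
    tf_rec = kabsch(q1, n1, allow_degenerate=True)
    lrms = float(np.sqrt(np.mean(np.sum((tf_rec.apply(q2) - n2) ** 2, axis=1))))

    # interface residues from the 10 A native contact map
    iface = _contact_pairs(n1, n2, INTERFACE_CUTOFF)
    res1 = sorted({i for i, _ in iface})
    res2 = sorted({j for _, j in iface})
    nat_iface = np.concatenate([n1[res1], n2[res2]])
    pred_iface = np.concatenate([q1[res1], q2[res2]])
    tf_i = kabsch(pred_iface, nat_iface, allow_degenerate=True)
    irms = float(np.sqrt(np.mean(np.sum((tf_i.apply(pred_iface) - nat_iface) ** 2, axis=1))))

    score = (fnat + 1.0 / (1.0 + (irms / 1.5) ** 2)
             + 1.0 / (1.0 + (lrms / 8.5) ** 2)) / 3.0
    return DockQResult(fnat=fnat, lrms=lrms, irms=irms, dockq=float(score),
                       capri_class=capri_class(float(score)))


def capri_class(score) -> str:
    """CAPRI quality band from a DockQ value (0.23/0.49/0.80 edges)."""
    s = float(getattr(score, "dockq", score))
    if s >= 0.80:
        return "High"
    if s > 0.49:
        return "Medium"
    if s > 0.23:
        return "Acceptable"
    return "Incorrect"


def acceptable_rank(records: Sequence, natives) -> int:
    """1-based rank of the first PAE-ranked prediction with DockQ > 0.23.

    ``records`` must already be ranked (ascending PAE).  ``natives`` is one
    native complex or a sequence matching ``records``.  When no prediction
    qualifies the convention value len(records) + 1 is returned (41 for the
    standard 40-seed protocol).
    """
    if len(records) == 0:
        raise ValueError("empty prediction sequence")
    for rank, rec in enumerate(records, start=1):
        native = natives[rank - 1] if isinstance(natives, (list, tuple)) else natives
        pred = getattr(rec, "complex", rec)
        if dockq(pred, native).dockq > 0.23:
            return rank
    return len(records) + 1


def ca_rmsd(pred: TernaryComplex, native: TernaryComplex) -> float:
    """Calpha RMSD of protein2 after receptor (protein1) superposition."""
    if pred.p2_coords.shape != native.p2_coords.shape:
        raise ValueError("Calpha sets differ in size")
    tf = kabsch(pred.p1_coords, native.p1_coords, allow_degenerate=True)
    return float(np.sqrt(np.mean(np.sum(
        (tf.apply(pred.p2_coords) - native.p2_coords) ** 2, axis=1))))


def ca_rmsd_acceptable(pred: TernaryComplex, native: TernaryComplex) -> bool:
    """True iff the Calpha RMSD is strictly below 10 A."""
    return ca_rmsd(pred, native) < 10.0


# ---------------------------------------------------------------------------
# solvent-accessible / buried surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral quasi-uniform points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5**0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def _radii(elements: Optional[Sequence[str]], n: int) -> np.ndarray:
    if elements is None:
        return np.full(n, VDW_RADII["C"])
    out = np.empty(n)
    for i, e in enumerate(elements):
        key = str(e).upper()
        if key not in VDW_RADII:
            warnings.warn(f"no van-der-Waals radius for element {e!r}; using default")
        out[i] = VDW_RADII.get(key, DEFAULT_RADIUS)
    return out


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = PROBE_RADIUS,
                       n_sphere_points: int = 960) -> float:
    """Total solvent-accessible surface area (A^2) of one atom set."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sphere = _sphere_points(n_sphere_points)
    expanded = radii + probe
    total = 0.0
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) > expanded[i] + expanded[j]:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d > expanded[j]
        total += 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return float(total)


def buried_surface_area(complex: TernaryComplex,
                        n_sphere_points: int = 960) -> BSAResult:
    """Per-pair and total buried surface area of the assembled complex.

    For each pair, buried = SASA(A alone) + SASA(B alone) - SASA(A and B
    together); the total sums the p1-p2, p1-lig and p2-lig pairs (no
    division by two — the summation convention).
    """
    n_p1, n_p2, n_lig = (len(complex.p1_coords), len(complex.p2_coords),
                         len(complex.lig_coords))
    ents = {
        "p1": (complex.p1_coords, _radii(None, n_p1)),
        "p2": (complex.p2_coords, _radii(None, n_p2)),
        "lig": (complex.lig_coords, _radii(complex.lig_elements, n_lig)),
    }
    solo = {k: shrake_rupley_sasa(c, r, n_sphere_points=n_sphere_points)
            for k, (c, r) in ents.items()}
    per_pair = {}
    for a, b in (("p1", "p2"), ("p1", "lig"), ("p2", "lig")):
        coords = np.concatenate([ents[a][0], ents[b][0]])
        radii = np.concatenate([ents[a][1], ents[b][1]])
        both = shrake_rupley_sasa(coords, radii, n_sphere_points=n_sphere_points)
        per_pair[f"{a}-{b}"] = max(solo[a] + solo[b] - both, 0.0)
    return BSAResult(per_pair=per_pair, total=float(sum(per_pair.values())))


def top5_mean_bsa(records: Sequence, n_sphere_points: int = 960) -> float:
    """Mean total BSA over the (at most) five lowest-PAE predictions."""
    if len(records) == 0:
        raise ValueError("no prediction records")
    def pae_of(r):
        p = getattr(r, "pae", r)
        return float(getattr(p, "value", p))
    top = sorted(records, key=pae_of)[:5]
    values = [buried_surface_area(r.complex, n_sphere_points=n_sphere_points).total
              for r in top]
    return float(np.mean(values))
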