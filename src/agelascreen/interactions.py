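"""Geometric ligand-RNA interaction fingerprints from complex coordinates.

Given a ligand-receptor complex (PDB), detects hydrogen bonds, halogen-pi
and halogen-bond contacts, aromatic stacking, van der Waals contact shells,
and the ligand's buried surface fraction. Detection is purely geometric;
every threshold is an explicit parameter. Nucleobase donors, acceptors and
pi systems come from residue-name templates (A/U/G/C), with a ring-detection
fallback for modified bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "LigandStructure",
    "ReceptorModel",
    "Residue",
    "InteractionRecord",
    "FingerprintReport",
    "load_complex",
    "detect_hbonds",
    "detect_halogen_pi",
    "detect_stacking",
    "contact_shell",
    "buried_fraction",
    "fingerprint",
    "build_map",
]

HALOGENS = {"F", "CL", "BR", "I"}
VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "CL": 1.75, "BR": 1.85,
       "I": 1.98, "S": 1.80, "P": 1.80, "H": 1.20}
PROBE_RADIUS = 1.4

# nucleobase templates: polar atoms and aromatic ring atom names
NUC_DONOR_ATOMS = {"A": {"N6"}, "G": {"N1", "N2"}, "C": {"N4"}, "U": {"N3"}}
NUC_ACCEPTOR_ATOMS = {
    "A": {"N1", "N3", "N7"}, "G": {"O6", "N3", "N7"},
    "C": {"O2", "N3"}, "U": {"O2", "O4"},
}
BACKBONE_ACCEPTORS = {"OP1", "OP2", "O2'", "O3'", "O4'", "O5'"}
NUC_RINGS = {
    "U": ({"N1", "C2", "N3", "C4", "C5", "C6"},),
    "C": ({"N1", "C2", "N3", "C4", "C5", "C6"},),
    "A": ({"N9", "C8", "N7", "C5", "C4"}, {"C4", "C5", "C6", "N1", "C2", "N3"}),
    "G": ({"N9", "C8", "N7", "C5", "C4"}, {"C4", "C5", "C6", "N1", "C2", "N3"}),
}


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray

    @property
    def rid(self) -> str:
        return f"{self.name}{self.number}"

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])


@dataclass
class ReceptorModel:
    residues: list[Residue]

    def __iter__(self):
        return iter(self.residues)


@dataclass
class LigandStructure:
    """Ligand atoms split out of a complex, with distance-based connectivity."""

    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self._bonds = _infer_bonds(self.elements, self.coords)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.elements) if e != "H"]

    def neighbors(self, i: int) -> list[int]:
        return self._bonds[i]

    def rings(self) -> list[list[int]]:
        """5/6-membered rings from the connectivity graph."""
        from rdkit import Chem

        rw = Chem.RWMol()
        heavy = self.heavy_indices
        remap = {}
        for i in heavy:
            a = Chem.Atom(self.elements[i].capitalize())
            a.SetNoImplicit(True)
            remap[i] = rw.AddAtom(a)
        for i in heavy:
            for j in self._bonds[i]:
                if j in remap and remap[i] < remap[j]:
                    rw.AddBond(remap[i], remap[j], Chem.BondType.SINGLE)
        m = rw.GetMol()
        Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
        back = {v: k for k, v in remap.items()}
        return [[back[i] for i in ring] for ring in m.GetRingInfo().AtomRings()
                if len(ring) in (5, 6)]


def _infer_bonds(elements, coords) -> dict[int, list[int]]:
    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    bonds: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            lim = 1.3 if ("H" in (elements[i], elements[j])) else 1.85
            if d < lim:
                bonds[i].append(j)
                bonds[j].append(i)
    return bonds


def _ring_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit normal) of a best-fit plane."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    return c, vt[2]


def load_complex(pdb_file, ligand_selector: str) -> tuple[LigandStructure, ReceptorModel]:
    """Split one ligand (by residue name or chain id) out of a PDB complex.

    Residue numbering is preserved verbatim from the file. Exactly one
    matching ligand residue group is required.
    """
    st = gemmi.read_structure(str(pdb_file))
    st.setup_entities()
    lig_residues, rec_residues = [], []
    for model in st:
        for chain in model:
            for res in chain:
                is_lig = (res.name == ligand_selector or chain.name == ligand_selector)
                rec = Residue(
                    chain=chain.name, number=res.seqid.num, name=res.name,
                    atom_names=[a.name for a in res],
                    elements=[a.element.name.upper() for a in res],
                    coords=np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res]),
                )
                (lig_residues if is_lig else rec_residues).append(rec)
        break  # first model only
    if len(lig_residues) == 0:
        raise ValueError(f"ligand selector {ligand_selector!r} matched nothing")
    if len(lig_residues) > 1:
        ids = [f"{r.chain}/{r.rid}" for r in lig_residues]
        raise ValueError(f"ligand selector {ligand_selector!r} matched several: {ids}")
    lr = lig_residues[0]
    ligand = LigandStructure(name=lr.name, atom_names=lr.atom_names,
                             elements=lr.elements, coords=lr.coords)
    return ligand, ReceptorModel(residues=rec_residues)


@dataclass
class InteractionRecord:
    type: str
    ligand_atom: str
    residue: str
    distance: float
    angle: float | None = None
    detail: str = ""

    def key(self):
        return (self.type, self.ligand_atom, self.residue)


@dataclass
class FingerprintReport:
    ligand: str
    records: list[InteractionRecord] = field(default_factory=list)
    shell: list[str] = field(default_factory=list)
    buried: float = 0.0

    def residues_in_records(self) -> set[str]:
        return {r.residue for r in self.records}


def _ligand_donors(lig: LigandStructure):
    """(donor heavy index, H position) pairs.

    Explicit hydrogens are trusted when the ligand has any; otherwise an
    idealized H is placed on plausible donors (under-coordinated N; O bound
    by a long single bond — a short C-O marks a carbonyl, not a hydroxyl).
    """
    out = []
    has_explicit_h = any(e == "H" for e in lig.elements)
    for i, e in enumerate(lig.elements):
        if e not in ("N", "O"):
            continue
        h_nbrs = [j for j in lig.neighbors(i) if lig.elements[j] == "H"]
        if h_nbrs:
            for j in h_nbrs:
                out.append((i, lig.coords[j]))
        elif not has_explicit_h:
            heavy_nbrs = [j for j in lig.neighbors(i) if lig.elements[j] != "H"]
            if not heavy_nbrs or len(heavy_nbrs) > 2:
                continue
            if e == "O":
                d = min(np.linalg.norm(lig.coords[i] - lig.coords[j])
                        for j in heavy_nbrs)
                if d < 1.32:  # double-bond-like: carbonyl O, no H
                    continue
            u = lig.coords[i] - lig.coords[heavy_nbrs].mean(axis=0)
            nu = np.linalg.norm(u)
            if nu > 1e-8:
                out.append((i, lig.coords[i] + u / nu * 1.0))
    return out


def _ligand_acceptors(lig: LigandStructure) -> list[int]:
    return [i for i, e in enumerate(lig.elements) if e in ("N", "O")]


def _receptor_donors(res: Residue):
    """(donor atom index, H position) pairs for one residue."""
    names = NUC_DONOR_ATOMS.get(res.name, set())
    out = []
    for i, an in enumerate(res.atom_names):
        base = an in names or (res.name not in NUC_DONOR_ATOMS and
                               res.elements[i] in ("N", "O"))
        if not base:
            continue
        h_idx = [j for j, hn in enumerate(res.atom_names)
                 if res.elements[j] == "H"
                 and np.linalg.norm(res.coords[j] - res.coords[i]) < 1.3]
        if h_idx:
            for j in h_idx:
                out.append((i, res.coords[j]))
        else:
            nbrs = [j for j in range(len(res.atom_names))
                    if j != i and res.elements[j] != "H"
                    and np.linalg.norm(res.coords[j] - res.coords[i]) < 1.8]
            if nbrs:
                u = res.coords[i] - res.coords[nbrs].mean(axis=0)
                nu = np.linalg.norm(u)
                if nu > 1e-8:
                    out.append((i, res.coords[i] + u / nu * 1.0))
    return out


def _receptor_acceptors(res: Residue) -> list[int]:
    names = NUC_ACCEPTOR_ATOMS.get(res.name, set()) | BACKBONE_ACCEPTORS
    out = []
    for i, an in enumerate(res.atom_names):
        if an in names:
            out.append(i)
        elif res.name not in NUC_ACCEPTOR_ATOMS and res.elements[i] in ("N", "O"):
            out.append(i)
    return out


def _angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v) + 1e-12)
    return math.degrees(math.acos(np.clip(cosv, -1.0, 1.0)))


def detect_hbonds(lig: LigandStructure, receptor: ReceptorModel,
                  d_max: float = 3.5, angle_min: float = 120.0) -> list[InteractionRecord]:
    """Donor-acceptor pairs with heavy-atom distance <= d_max and
    D-H...A angle >= angle_min, in both directions."""
    records = []
    # ligand donor -> receptor acceptor
    donors = _ligand_donors(lig)
    for res in receptor:
        for ai in _receptor_acceptors(res):
            a_pos = res.coords[ai]
            for di, h_pos in donors:
                d_pos = lig.coords[di]
                dist = float(np.linalg.norm(d_pos - a_pos))
                if dist > d_max:
                    continue
                ang = _angle(d_pos, h_pos, a_pos)
                if ang >= angle_min:
                    records.append(InteractionRecord(
                        "hbond", lig.atom_names[di], res.rid, round(dist, 3),
                        round(ang, 1), detail=f"ligand-donor->{res.atom_names[ai]}"))
    # receptor donor -> ligand acceptor
    acceptors = _ligand_acceptors(lig)
    for res in receptor:
        for di, h_pos in _receptor_donors(res):
            d_pos = res.coords[di]
            for ai in acceptors:
                a_pos = lig.coords[ai]
                dist = float(np.linalg.norm(d_pos - a_pos))
                if dist > d_max:
                    continue
                ang = _angle(d_pos, h_pos, a_pos)
                if ang >= angle_min:
                    records.append(InteractionRecord(
                        "hbond", lig.atom_names[ai], res.rid, round(dist, 3),
                        round(ang, 1), detail=f"receptor-donor:{res.atom_names[di]}"))
    return _dedup_records(records)


def _residue_rings(res: Residue) -> list[np.ndarray]:
    """Aromatic-ring coordinate blocks for one residue (template or fallback)."""
    blocks = []
    if res.name in NUC_RINGS:
        for names in NUC_RINGS[res.name]:
            idx = [i for i, an in enumerate(res.atom_names) if an in names]
            if len(idx) >= 4:
                blocks.append(res.coords[idx])
    else:
        lig_like = LigandStructure("tmp", res.atom_names, res.elements, res.coords)
        for ring in lig_like.rings():
            blocks.append(res.coords[ring])
    return blocks


def detect_halogen_pi(lig: LigandStructure, receptor: ReceptorModel,
                      d_max: float = 4.0, normal_max: float = 45.0,
                      xb_d_max: float = 3.6, xb_angle_min: float = 150.0
                      ) -> list[InteractionRecord]:
    """Halogen-pi contacts (X over a ring face) and linear halogen bonds.

    Halogen-pi: ligand halogen within ``d_max`` of an aromatic-ring centroid
    and within ``normal_max`` degrees of the ring normal. Halogen bond:
    C-X...acceptor with angle >= ``xb_angle_min`` and X...A <= ``xb_d_max``.
    """
    records = []
    halos = [i for i, e in enumerate(lig.elements) if e.upper() in HALOGENS]
    for res in receptor:
        rings = _residue_rings(res)
        for xi in halos:
            x = lig.coords[xi]
            for ring_pts in rings:
                centroid, normal = _ring_plane(ring_pts)
                v = x - centroid
                dist = float(np.linalg.norm(v))
                if dist > d_max or dist < 1e-6:
                    continue
                tilt = math.degrees(math.acos(np.clip(
                    abs(np.dot(v / dist, normal)), -1.0, 1.0)))
                if tilt <= normal_max:
                    records.append(InteractionRecord(
                        "halogen_pi", lig.atom_names[xi], res.rid,
                        round(dist, 3), round(tilt, 1)))
        for xi in halos:
            x = lig.coords[xi]
            c_nbrs = [j for j in lig.neighbors(xi) if lig.elements[j] == "C"]
            if not c_nbrs:
                continue
            c = lig.coords[c_nbrs[0]]
            for ai in _receptor_acceptors(res):
                a = res.coords[ai]
                dist = float(np.linalg.norm(x - a))
                if dist > xb_d_max:
                    continue
                ang = _angle(c, x, a)
                if ang >= xb_angle_min:
                    records.append(InteractionRecord(
                        "halogen_bond", lig.atom_names[xi], res.rid,
                        round(dist, 3), round(ang, 1),
                        detail=f"acceptor:{res.atom_names[ai]}"))
    return _dedup_records(records)


def detect_stacking(lig: LigandStructure, receptor: ReceptorModel,
                    parallel_d_max: float = 4.5, parallel_angle_max: float = 30.0,
                    t_d_max: float = 5.0) -> list[InteractionRecord]:
    """Aromatic stacking: parallel (centroids <= 4.5 Å, planes within 30°)
    or T-shaped (60-90°, centroids <= 5.0 Å)."""
    records = []
    lig_rings = lig.rings()
    for ring in lig_rings:
        lc, ln = _ring_plane(lig.coords[ring])
        label = lig.atom_names[ring[0]]
        for res in receptor:
            for ring_pts in _residue_rings(res):
                rc, rn = _ring_plane(ring_pts)
                dist = float(np.linalg.norm(lc - rc))
                if dist > t_d_max:
                    continue
                ang = math.degrees(math.acos(np.clip(abs(np.dot(ln, rn)), -1.0, 1.0)))
                if dist <= parallel_d_max and ang <= parallel_angle_max:
                    records.append(InteractionRecord(
                        "pi_stack", label, res.rid, round(dist, 3), round(ang, 1),
                        detail="parallel"))
                elif 60.0 <= ang <= 90.0 and dist <= t_d_max:
                    records.append(InteractionRecord(
                        "pi_stack", label, res.rid, round(dist, 3), round(ang, 1),
                        detail="t-shaped"))
    return _dedup_records(records)


def contact_shell(lig: LigandStructure, receptor: ReceptorModel,
                  d_max: float = 4.5) -> list[str]:
    """Residues with >=1 heavy atom within d_max of any ligand heavy atom,
    sorted by residue number."""
    lh = lig.coords[lig.heavy_indices]
    hits = []
    for res in receptor:
        mask = res.heavy_mask()
        if not mask.any():
            continue
        rc = res.coords[mask]
        d = np.sqrt(((rc[:, None, :] - lh[None, :, :]) ** 2).sum(-1))
        if d.min() <= d_max:
            hits.append(res)
    hits.sort(key=lambda r: (r.number, r.chain))
    return [r.rid for r in hits]


def _sphere_points(n: int = 256) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _sasa(coords: np.ndarray, radii: np.ndarray, context: np.ndarray,
          context_radii: np.ndarray, n_points: int = 256) -> float:
    """Shrake-Rupley solvent-accessible surface area of the first atom set,
    with ``context`` atoms also blocking the probe."""
    pts = _sphere_points(n_points)
    all_c = np.vstack([coords, context]) if len(context) else coords
    all_r = np.concatenate([radii, context_radii]) if len(context) else radii
    area = 0.0
    for i, (c, r) in enumerate(zip(coords, radii)):
        rr = r + PROBE_RADIUS
        surf = c + pts * rr
        d2 = ((surf[:, None, :] - all_c[None, :, :]) ** 2).sum(-1)
        lim2 = (all_r + PROBE_RADIUS) ** 2
        # a surface point is accessible if outside every other inflated sphere
        accessible = (d2 >= lim2[None, :] - 1e-9)
        accessible[:, i] = True  # the atom's own sphere never blocks it
        frac = accessible.all(axis=1).mean()
        area += 4.0 * np.pi * rr * rr * frac
    return area


def buried_fraction(lig: LigandStructure, receptor: ReceptorModel,
                    n_points: int = 256) -> float:
    """1 - SASA(ligand in complex) / SASA(ligand alone), probe 1.4 Å."""
    hi = lig.heavy_indices
    coords = lig.coords[hi]
    radii = np.array([VDW.get(lig.elements[i].upper(), 1.7) for i in hi])
    ctx_coords, ctx_radii = [], []
    for res in receptor:
        mask = res.heavy_mask()
        ctx_coords.append(res.coords[mask])
        ctx_radii.extend(VDW.get(e.upper(), 1.7)
                         for e, m in zip(res.elements, mask) if m)
    ctx = np.vstack(ctx_coords) if ctx_coords else np.zeros((0, 3))
    free = _sasa(coords, radii, np.zeros((0, 3)), np.zeros(0), n_points)
    if free <= 0:
        return 0.0
    bound = _sasa(coords, radii, ctx, np.array(ctx_radii), n_points)
    return float(np.clip(1.0 - bound / free, 0.0, 1.0))


def _dedup_records(records: list[InteractionRecord]) -> list[InteractionRecord]:
    best: dict = {}
    for r in records:
        k = r.key()
        if k not in best or r.distance < best[k].distance:
            best[k] = r
    return sorted(best.values(), key=lambda r: (r.residue, r.type, r.ligand_atom))


def fingerprint(lig: LigandStructure, receptor: ReceptorModel,
                hbond_d_max: float = 3.5, hbond_angle_min: float = 120.0,
                halogen_pi_d_max: float = 4.0, shell_d_max: float = 4.5
                ) -> FingerprintReport:
    """Run every detector and assemble one report for a ligand."""
    records = (detect_hbonds(lig, receptor, hbond_d_max, hbond_angle_min)
               + detect_halogen_pi(lig, receptor, halogen_pi_d_max)
               + detect_stacking(lig, receptor))
    return FingerprintReport(
        ligand=lig.name,
        records=records,
        shell=contact_shell(lig, receptor, shell_d_max),
        buried=round(buried_fraction(lig, receptor), 4),
    )


def build_map(reports: list[FingerprintReport]):
    """Cross-ligand interaction matrix (ligand x residue x type).

    Returns (matrix DataFrame with one row per ligand and one column per
    (residue, type) pair, JSON-serializable dict). Deterministic ordering.
    """
    import pandas as pd

    if not reports:
        raise ValueError("need at least one fingerprint report")
    cols = sorted({(r.residue, r.type) for rep in reports for r in rep.records})
    rows = {}
    for rep in reports:
        row = {f"{res}:{typ}": 0 for res, typ in cols}
        for r in rep.records:
            row[f"{r.residue}:{r.type}"] += 1
        rows[rep.ligand] = row
    matrix = pd.DataFrame(list(rows.values()),
                          index=list(rows.keys())).fillna(0).astype(int)
    payload = {
        rep.ligand: {
            "records": [vars(r) for r in rep.records],
            "shell": rep.shell,
            "buried_fraction": rep.buried,
        }
        for rep in reports
    }
    return matrix, payload
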