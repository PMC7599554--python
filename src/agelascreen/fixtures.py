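"""Synthetic ligand-RNA pose fixtures with planted interaction geometry.

Real docked poses require a docking engine and a ribosome structure, both
outside this package's scope; the detectors are therefore validated on
synthetic complexes in which every interaction is planted at an exactly
specified geometry (within PDB coordinate precision, 0.001 Å). The builder
places idealized uracil-like nucleotides (or single-carbon contact markers)
around a rigid template ligand so that each requested interaction — and no
other — falls inside the detector envelopes.

All files written here are synthetic; they model the geometry of an
interaction, not any particular crystal structure.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["make_fixture_complex", "TEMPLATE_LIGAND_ATOMS"]

# Rigid template ligand: a 4-chloro-benzamide-like fragment laid out in the
# z=0 plane with idealized geometry. Anchors: amide N-H donor (N1/H1),
# carbonyl O acceptor (O1), aromatic ring (C2..C7), ring chlorine (CL1).
_R = 1.39  # aromatic C-C
TEMPLATE_LIGAND_ATOMS = [
    # (name, element, x, y, z)
    ("C2", "C", 0.000, 0.000, 0.000),
    ("C3", "C", 1.204, 0.695, 0.000),
    ("C4", "C", 1.204, 2.085, 0.000),
    ("C5", "C", 0.000, 2.780, 0.000),
    ("C6", "C", -1.204, 2.085, 0.000),
    ("C7", "C", -1.204, 0.695, 0.000),
    ("CL1", "CL", 0.000, 4.520, 0.000),          # para chlorine on C5
    ("C1", "C", 0.000, -1.490, 0.000),           # carbonyl carbon on C2
    ("O1", "O", 1.050, -2.110, 0.000),           # carbonyl oxygen
    ("N1", "N", -1.180, -2.110, 0.000),          # amide nitrogen
    ("H1", "H", -1.180, -3.110, 0.000),          # amide H, along -y
    ("C8", "C", -2.450, -1.450, 0.000),          # N-methyl
]

# Idealized planar uracil-like base (ring in its local xy plane).
# N3-H3 is the donor; O2/O4 are acceptors.
_URACIL = [
    ("N1", "N", 0.000, 0.000, 0.000),
    ("C2", "C", 1.380, 0.000, 0.000),
    ("O2", "O", 2.000, -1.070, 0.000),
    ("N3", "N", 2.070, 1.195, 0.000),
    ("H3", "H", 3.080, 1.195, 0.000),
    ("C4", "C", 1.380, 2.390, 0.000),
    ("O4", "O", 2.000, 3.460, 0.000),
    ("C5", "C", 0.000, 2.390, 0.000),
    ("C6", "C", -0.690, 1.195, 0.000),
]
_U_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length direction")
    return np.asarray(v, dtype=float) / n


def _rotation_between(a, b):
    """Rotation matrix taking unit vector a to unit vector b."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any perpendicular axis
        axis = _unit(np.cross(a, [1.0, 0.3, 0.2]))
        return 2 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (np.linalg.norm(v) ** 2))


class _Builder:
    def __init__(self):
        self.lig_atoms = [(n, e, np.array([x, y, z]))
                          for n, e, x, y, z in TEMPLATE_LIGAND_ATOMS]
        self.residues = []  # (chain, number, name, [(atom, element, xyz)])
        self._auto_number = 9000

    def lig(self, name):
        for n, e, xyz in self.lig_atoms:
            if n == name:
                return xyz
        raise KeyError(name)

    def _place_uracil(self, anchor_atom: str, target_xyz: np.ndarray,
                      away_from: np.ndarray, residue, plane_normal=None):
        """Place a uracil so ``anchor_atom`` lands on ``target_xyz`` with the
        rest of the base pointing away from ``away_from``."""
        local = {n: np.array([x, y, z]) for n, _, x, y, z in _URACIL}
        centroid = np.mean([local[n] for n in _U_RING], axis=0)
        a_local = local[anchor_atom]
        out_dir_local = _unit(a_local - centroid) if np.linalg.norm(
            a_local - centroid) > 1e-9 else np.array([1.0, 0, 0])
        want = _unit(target_xyz - away_from)
        # anchor->centroid must continue along ``want`` so the base body
        # extends away from the ligand, not back over it
        rot = _rotation_between(-out_dir_local, want)
        if plane_normal is not None:
            # additionally align the base plane normal (local z) to plane_normal
            rot = _rotation_between(rot @ np.array([0.0, 0.0, 1.0]),
                                    _unit(plane_normal)) @ rot
        shift = target_xyz - rot @ a_local
        atoms = [(n, e, rot @ np.array([x, y, z]) + shift)
                 for n, e, x, y, z in _URACIL]
        chain, number, name = residue
        self.residues.append((chain, number, name, atoms))

    def plant_hbond_ligand_donor(self, distance, angle, residue):
        """Receptor O4 acceptor placed so N1-H1...O4 has the given heavy-atom
        distance (Å) and D-H-A angle (degrees)."""
        d_pos, h_pos = self.lig("N1"), self.lig("H1")
        u = _unit(d_pos - h_pos)
        # in-plane perpendicular to u
        v = _unit(np.cross(np.cross(u, [0, 0, 1.0]), u))
        theta = math.radians(angle)
        dh = float(np.linalg.norm(d_pos - h_pos))
        # law of cosines for |H-A| given |D-A| and the D-H-A angle at H
        x = dh * math.cos(theta) + math.sqrt(
            (dh * math.cos(theta)) ** 2 - dh * dh + distance * distance)
        a_pos = h_pos + x * (math.cos(theta) * u + math.sin(theta) * v)
        self._place_uracil("O4", a_pos, away_from=h_pos, residue=residue)

    def plant_hbond_ligand_acceptor(self, distance, angle, residue):
        """Receptor N3-H3 donor aimed at the carbonyl O1; the donor N sits at
        ``distance`` from O1 and the N-H points at O1 (angle ~= requested)."""
        a_pos = self.lig("O1")
        c_pos = self.lig("C1")
        direction = _unit(a_pos - c_pos)
        d_pos = a_pos + direction * distance
        # place with N3 at d_pos, base away from the ligand; H3 will sit on
        # the N3->O1 line because the base's outward axis points back at O1
        self._place_uracil("N3", d_pos, away_from=a_pos, residue=residue)
        # rotate the placed residue about N3 so H3 points exactly at O1 with
        # the requested D-H...A angle (180 keeps it collinear)
        chain, number, name, atoms = self.residues[-1]
        local = {n: xyz for n, _, xyz in atoms}
        h = local["H3"]
        want_h = d_pos + _unit(a_pos - d_pos) * np.linalg.norm(h - d_pos)
        rot = _rotation_between(h - d_pos, want_h - d_pos)
        atoms = [(n, e, rot @ (xyz - d_pos) + d_pos) for n, e, xyz in atoms]
        if abs(angle - 180.0) > 1e-6:
            # rotate the residue about N3 (in the base plane) until the
            # D-H...A angle at H equals the request; solve the triangle
            # (|N3-H| fixed, |N3-O1| fixed) for the rotation at N3
            nh = float(np.linalg.norm(h - d_pos))
            na = float(np.linalg.norm(a_pos - d_pos))

            def angle_at_h(phi):
                ha2 = nh * nh + na * na - 2 * nh * na * math.cos(phi)
                ha = math.sqrt(ha2)
                cos_h = (nh * nh + ha2 - na * na) / (2 * nh * ha)
                return math.degrees(math.acos(np.clip(cos_h, -1, 1)))

            lo_phi, hi_phi = 0.0, math.radians(60.0)
            for _ in range(60):
                mid = (lo_phi + hi_phi) / 2
                if angle_at_h(mid) > angle:
                    lo_phi = mid
                else:
                    hi_phi = mid
            _, _, vt = np.linalg.svd(np.array([xyz for _, _, xyz in atoms])
                                     - d_pos)
            axis = vt[2]
            tilt = (lo_phi + hi_phi) / 2
            k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot2 = np.eye(3) + math.sin(tilt) * k + (1 - math.cos(tilt)) * (k @ k)
            atoms = [(n, e, rot2 @ (xyz - d_pos) + d_pos) for n, e, xyz in atoms]
        self.residues[-1] = (chain, number, name, atoms)

    def plant_halogen_pi(self, distance, residue, off_normal_deg: float = 0.0):
        """Uracil ring centroid at ``distance`` from CL1 along the C5-CL1 axis,
        ring plane perpendicular to that axis (so CL sits on the ring normal,
        tilted by ``off_normal_deg`` if requested)."""
        x_pos = self.lig("CL1")
        axis = _unit(x_pos - self.lig("C5"))
        tilt = math.radians(off_normal_deg)
        v = _unit(np.cross(axis, [0.0, 0.0, 1.0]))
        direction = math.cos(tilt) * axis + math.sin(tilt) * v
        centroid_target = x_pos + direction * distance
        local = {n: np.array([x, y, z]) for n, _, x, y, z in _URACIL}
        centroid_local = np.mean([local[n] for n in _U_RING], axis=0)
        rot = _rotation_between(np.array([0.0, 0.0, 1.0]), axis)
        shift = centroid_target - rot @ centroid_local
        atoms = [(n, e, rot @ np.array([x, y, z]) + shift)
                 for n, e, x, y, z in _URACIL if e != "H"]
        chain, number, name = residue
        self.residues.append((chain, number, name, atoms))

    def plant_stack(self, distance, residue, geometry="parallel"):
        """Uracil ring stacked over the ligand benzene ring."""
        ring = [self.lig(n) for n in ("C2", "C3", "C4", "C5", "C6", "C7")]
        centroid = np.mean(ring, axis=0)
        normal = np.array([0.0, 0.0, 1.0])
        target = centroid + normal * distance
        local = {n: np.array([x, y, z]) for n, _, x, y, z in _URACIL}
        centroid_local = np.mean([local[n] for n in _U_RING], axis=0)
        if geometry == "parallel":
            rot = np.eye(3)
        elif geometry == "t":
            rot = _rotation_between(np.array([0.0, 0.0, 1.0]),
                                    np.array([1.0, 0.0, 0.0]))
        else:
            raise ValueError(f"unknown stack geometry {geometry!r}")
        shift = target - rot @ centroid_local
        atoms = [(n, e, rot @ np.array([x, y, z]) + shift)
                 for n, e, x, y, z in _URACIL if e != "H"]
        chain, number, name = residue
        self.residues.append((chain, number, name, atoms))

    def plant_contact(self, distance, residue, direction):
        """Single-carbon marker residue with nearest-atom distance
        ``distance`` from the ligand (no polar/aromatic content, so it
        triggers only the contact-shell detector)."""
        direction = _unit(direction)
        lig_heavy = np.array([xyz for _, e, xyz in self.lig_atoms if e != "H"])
        # walk outward until the nearest-atom distance equals the target
        center = lig_heavy.mean(axis=0)
        pos = center + direction * 1.0
        for _ in range(200):
            dmin = np.min(np.linalg.norm(lig_heavy - pos, axis=1))
            if abs(dmin - distance) < 1e-6:
                break
            pos = pos + direction * (distance - dmin)
        chain, number, name = residue
        self.residues.append((chain, number, name, [("C1'", "C", pos)]))

    def plant_cage(self, radius: float = 7.5, spacing: float = 1.2):
        """Concentric shells of carbons enclosing the ligand (buried fixture).

        Two shells are needed because solvent accessibility is a local test:
        the inner shell's inflated spheres must cover the ligand surface
        points near the molecular center, the outer shell those farther out.
        """
        lig_heavy = np.array([xyz for _, e, xyz in self.lig_atoms if e != "H"])
        center = lig_heavy.mean(axis=0)
        atoms = []
        for r in (radius - 2.5, radius):
            n = max(64, int(4 * np.pi * r ** 2 / spacing ** 2))
            i = np.arange(n) + 0.5
            phi = np.arccos(1 - 2 * i / n)
            theta = np.pi * (1 + 5 ** 0.5) * i
            pts = center + r * np.column_stack(
                [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi),
                 np.cos(phi)])
            atoms.extend(("C1'", "C", p) for p in pts)
        self.residues.append(("Z", self._auto_number, "CGE", atoms))
        self._auto_number += 1

    def plant_wall(self, distance: float = 3.5, spacing: float = 1.5,
                   extent: float = 12.0):
        """Planar wall of carbons below the ligand plane (half-buried fixture)."""
        lig_heavy = np.array([xyz for _, e, xyz in self.lig_atoms if e != "H"])
        center = lig_heavy.mean(axis=0)
        zs = center[2] - distance
        g = np.arange(-extent, extent + spacing, spacing)
        atoms = []
        for x in g:
            for y in g:
                atoms.append(("C1'", "C",
                              np.array([center[0] + x, center[1] + y, zs])))
        self.residues.append(("Z", self._auto_number, "WAL", atoms))
        self._auto_number += 1

    def write(self, path):
        lines = []
        serial = 1
        for n, e, xyz in self.lig_atoms:
            lines.append(_pdb_line("HETATM", serial, n, "LIG", "X", 1, xyz, e))
            serial += 1
        for chain, number, name, atoms in self.residues:
            for an, ae, xyz in atoms:
                lines.append(_pdb_line("ATOM", serial, an, name, chain,
                                       number, xyz, ae))
                serial += 1
        lines.append("END")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _pdb_line(record, serial, name, resname, chain, resnum, xyz, element):
    name_f = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (f"{record:<6s}{serial:>5d} {name_f}{'':1s}{resname:>3s} {chain:1s}"
            f"{resnum:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element.upper():>2s}")


def make_fixture_complex(spec: list[dict], path, second_ligand: bool = False):
    """Write a synthetic complex PDB realizing each planted interaction.

    ``spec`` entries (type-dispatched):
      {"type": "hbond", "role": "ligand_donor"|"ligand_acceptor",
       "distance": Å, "angle": deg, "residue": (chain, number, resname)}
      {"type": "halogen_pi", "distance": Å, "off_normal": deg,
       "residue": (...)}
      {"type": "pi_stack", "distance": Å, "geometry": "parallel"|"t",
       "residue": (...)}
      {"type": "contact", "distance": Å, "residue": (...),
       "direction": 3-vector}
      {"type": "cage", "radius": Å} / {"type": "wall", "distance": Å}

    An empty spec writes the ligand alone. ``second_ligand`` duplicates the
    ligand residue (for selector-error tests).
    """
    b = _Builder()
    for item in spec:
        kind = item["type"]
        if kind == "hbond":
            if item.get("role", "ligand_donor") == "ligand_donor":
                b.plant_hbond_ligand_donor(item["distance"], item["angle"],
                                           item["residue"])
            else:
                b.plant_hbond_ligand_acceptor(item["distance"], item["angle"],
                                              item["residue"])
        elif kind == "halogen_pi":
            b.plant_halogen_pi(item["distance"], item["residue"],
                               off_normal_deg=item.get("off_normal", 0.0))
        elif kind == "pi_stack":
            b.plant_stack(item["distance"], item["residue"],
                          geometry=item.get("geometry", "parallel"))
        elif kind == "contact":
            b.plant_contact(item["distance"], item["residue"],
                            item.get("direction", (1.0, 0.3, 0.2)))
        elif kind == "cage":
            b.plant_cage(radius=item.get("radius", 8.0))
        elif kind == "wall":
            b.plant_wall(distance=item.get("distance", 3.5))
        else:
            raise ValueError(f"unknown planted interaction type {kind!r}")
    if second_ligand:
        shift = np.array([30.0, 0.0, 0.0])
        for n, e, xyz in list(b.lig_atoms):
            b.residues.append(("Y", 2, "LIG", [(n, e, xyz + shift)]))
    b.write(path)
    return path
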