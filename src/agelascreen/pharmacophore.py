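"""Pharmacophore atom typing, feature perception, and common hypotheses.

Feature kinds follow the usual closed vocabulary: hydrogen-bond donor,
hydrogen-bond acceptor, hydrophobic, aromatic, halogen, positive, negative.
Typing is rule-based (SMARTS); aromatic features sit at ring centroids,
hydrophobic features at centroids of connected nonpolar-carbon clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import Molecule

__all__ = [
    "PharmacophoreFeature",
    "Hypothesis",
    "FEATURE_KINDS",
    "atom_classes",
    "perceive_features",
    "common_hypothesis",
]

FEATURE_KINDS = ("donor", "acceptor", "hydrophobic", "aromatic", "halogen",
                 "positive", "negative")

# SMARTS operate on the implicit-H graph; donors are N/O carrying >=1 H.
_SMARTS = {
    "donor": "[$([N;!H0;+0,+1]),$([O;H1,H2;+0]),$([n;H1])]",
    "acceptor": "[$([O;X1,X2;+0]),$([O-]),$([N;X3;v3;!$([N]a);!$([NX3][CX3]=[O,N,S])]),$([n;X2;H0])]",
    "halogen": "[F,Cl,Br,I]",
    "positive": "[+1,+2,$([NX4])]",
    "negative": "[-1,-2]",
    "hydrophobic_atom": "[#6;!$([#6]~[#7,#8,#15,#16]);!$([#6]~[F,Cl,Br,I])]",
}


@dataclass
class PharmacophoreFeature:
    """One perceived chemical feature at a 3D position."""

    kind: str
    position: np.ndarray
    radius: float = 1.0
    source_atoms: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Hypothesis:
    """A rigid frame of features shared by a set of aligned molecules."""

    features: list[PharmacophoreFeature]
    tolerance: float
    source: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.features) < 3:
            raise ValueError("a hypothesis needs at least 3 features")

    def pairwise_distances(self) -> np.ndarray:
        pos = np.array([f.position for f in self.features])
        d = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((d ** 2).sum(axis=-1))

    def kinds(self) -> list[str]:
        return [f.kind for f in self.features]


def atom_classes(mol: Molecule) -> dict[str, list[int]]:
    """Heavy-atom index lists per pharmacophore class.

    Indices are positions within the heavy-atom ordering (the ordering used
    by ConformerSet.heavy_coords), so they can index conformer coordinates
    directly. Classes with no member are omitted.
    """
    m = mol.rdmol
    heavy = [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() > 1]
    remap = {idx: i for i, idx in enumerate(heavy)}
    out: dict[str, list[int]] = {}

    def matches(smarts):
        patt = Chem.MolFromSmarts(smarts)
        return sorted({t[0] for t in m.GetSubstructMatches(patt)})

    for cls, key in [("donor", "donor"), ("acceptor", "acceptor"),
                     ("halogen", "halogen")]:
        idx = [remap[i] for i in matches(_SMARTS[key]) if i in remap]
        if idx:
            out[cls] = idx
    arom = [remap[a.GetIdx()] for a in m.GetAtoms()
            if a.GetIsAromatic() and a.GetIdx() in remap]
    if arom:
        out["aromatic"] = arom
    hyd = [remap[i] for i in matches(_SMARTS["hydrophobic_atom"]) if i in remap]
    if hyd:
        out["hydrophobic"] = hyd
    return out


def _clusters(indices: list[int], mol: Chem.Mol, heavy: list[int]) -> list[list[int]]:
    """Connected components of a heavy-atom index subset (graph adjacency)."""
    idx_set = set(indices)
    back = {i: heavy[i] for i in indices}
    seen, comps = set(), []
    for start in indices:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            atom = mol.GetAtomWithIdx(back[i])
            for nb in atom.GetNeighbors():
                j = heavy.index(nb.GetIdx()) if nb.GetIdx() in heavy else None
                if j is not None and j in idx_set and j not in seen:
                    seen.add(j)
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def perceive_features(mol: Molecule, conformer: np.ndarray) -> list[PharmacophoreFeature]:
    """Perceive pharmacophore features on one conformer.

    Donor / acceptor / halogen / charged features sit on their atoms;
    aromatic features at ring centroids; hydrophobic features at centroids
    of connected nonpolar-carbon clusters.
    """
    conformer = np.asarray(conformer, dtype=float)
    if conformer.ndim != 2 or conformer.shape[1] != 3:
        raise ValueError("conformer must be an (n_heavy, 3) coordinate array")
    m = mol.rdmol
    heavy = [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() > 1]
    if conformer.shape[0] != len(heavy):
        raise ValueError("conformer does not match the molecule's heavy-atom count")
    remap = {idx: i for i, idx in enumerate(heavy)}
    classes = atom_classes(mol)
    feats: list[PharmacophoreFeature] = []

    for kind in ("donor", "acceptor", "halogen"):
        for i in classes.get(kind, []):
            feats.append(PharmacophoreFeature(kind, conformer[i], 1.0, [i]))

    patt = Chem.MolFromSmarts(_SMARTS["positive"])
    for t in m.GetSubstructMatches(patt):
        if t[0] in remap:
            feats.append(PharmacophoreFeature("positive", conformer[remap[t[0]]], 1.0,
                                              [remap[t[0]]]))
    patt = Chem.MolFromSmarts(_SMARTS["negative"])
    for t in m.GetSubstructMatches(patt):
        if t[0] in remap:
            feats.append(PharmacophoreFeature("negative", conformer[remap[t[0]]], 1.0,
                                              [remap[t[0]]]))

    for ring in m.GetRingInfo().AtomRings():
        if all(m.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            idx = [remap[i] for i in ring if i in remap]
            feats.append(PharmacophoreFeature("aromatic", conformer[idx].mean(axis=0),
                                              1.4, idx))

    for comp in _clusters(classes.get("hydrophobic", []), m, heavy):
        feats.append(PharmacophoreFeature("hydrophobic", conformer[comp].mean(axis=0),
                                          1.5, comp))
    return feats


def common_hypothesis(mols_with_feats: list[tuple[str, list[PharmacophoreFeature]]],
                      tolerance: float = 1.5) -> Hypothesis:
    """Cluster features across pre-aligned molecules; keep clusters present
    in every molecule within ``tolerance`` (Å) and the same kind.

    Each retained cluster's centroid becomes one hypothesis feature. Raises
    if fewer than 3 clusters survive.
    """
    if len(mols_with_feats) < 2:
        raise ValueError("need at least 2 molecules for a common hypothesis")
    names = [n for n, _ in mols_with_feats]
    ref_name, ref_feats = mols_with_feats[0]
    survivors: list[PharmacophoreFeature] = []
    for f in ref_feats:
        members = [f.position]
        present_everywhere = True
        for _, other in mols_with_feats[1:]:
            cands = [g for g in other if g.kind == f.kind
                     and np.linalg.norm(g.position - f.position) <= tolerance]
            if not cands:
                present_everywhere = False
                break
            best = min(cands, key=lambda g: np.linalg.norm(g.position - f.position))
            members.append(best.position)
        if present_everywhere:
            survivors.append(PharmacophoreFeature(
                f.kind, np.mean(members, axis=0), f.radius, list(f.source_atoms)))
    if len(survivors) < 3:
        raise ValueError(
            f"only {len(survivors)} common feature clusters across {names}; need >= 3")
    return Hypothesis(features=survivors, tolerance=tolerance, source=names)
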