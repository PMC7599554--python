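"""Scaffold-based de novo candidate generation.

The generator separates a parent ligand into its ring-system core and
exocyclic substituents, recombines fragments from a library into the open
core slots exhaustively, and then reduces the pool through a filter
cascade: chemical sanitization + 3D embedding, tautomer/ionization state
enumeration over a pH window, a reactive-functional-group blocklist, and a
physicochemical Z-score filter against a set of known actives.
"""

from __future__ import annotations

import importlib.resources
import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

from .chem import Molecule

__all__ = [
    "CoreScaffold",
    "CandidatePool",
    "ScaffoldError",
    "separate_core",
    "reassemble",
    "enumerate_candidates",
    "chemical_filter",
    "enumerate_states",
    "reactive_screen",
    "zscore_filter",
    "descriptor_vector",
    "DESCRIPTOR_NAMES",
    "REACTIVE_BLOCKLIST",
]


class ScaffoldError(ValueError):
    """Raised when core separation is impossible (e.g. acyclic input)."""


@dataclass
class CoreScaffold:
    """A ring-system core with labeled open attachment slots.

    The core keeps dummy atoms (atom map numbers 1..n) where substituents
    were severed; ``slots`` records (core attachment-atom index, slot label).
    """

    core: Chem.Mol
    slots: list[tuple[int, str]]
    provenance: str = ""
    slot_map_numbers: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.slot_map_numbers:
            self.slot_map_numbers = list(range(1, len(self.slots) + 1))

    @property
    def n_slots(self) -> int:
        return len(self.slots)


@dataclass
class CandidatePool:
    """A deduplicated set of candidate molecules with an audit trail."""

    members: list[Molecule] = field(default_factory=list)
    pool_id: str = "pool1"
    audit: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def smiles(self) -> list[str]:
        return [m.canonical_smiles for m in self.members]

    def manifest(self) -> str:
        """Deterministic JSON manifest of the pool contents."""
        rows = [{"name": m.name, "smiles": m.canonical_smiles} for m in self.members]
        return json.dumps({"pool_id": self.pool_id, "members": rows,
                           "audit": self.audit}, indent=1, sort_keys=True)


# Reactive / electrophilic groups excluded from candidate pools. Aryl
# halides (as in the parent bromopyrrole) are deliberately NOT listed.
REACTIVE_BLOCKLIST = {
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "michael_acrylate": "[CX3]=[CX3]-[CX3](=O)[OX2]",
    "epoxide": "C1OC1",
    "aldehyde": "[CX3H1](=O)[#6]",
    # sp3 C-halide activated by an adjacent carbonyl or heteroatom
    "activated_alkyl_halide":
        "[F,Cl,Br,I][CX4;$([CX4][CX3]=[O,N,S]),$([CX4][O,N,S])]",
    "heteroatom_halide": "[N,O,S][F,Cl,Br,I]",
    "azide": "[NX2]=[NX2+]=[NX1-]",
    "peroxide": "[OX2][OX2]",
}

DESCRIPTOR_NAMES = ("mol_weight", "heavy_atoms", "hbd", "hba", "rings",
                    "halogens", "clogp")


def separate_core(mol: Molecule) -> tuple[CoreScaffold, list[Chem.Mol]]:
    """Cut every exocyclic single bond from a ring atom to a non-ring
    substituent; return the core (with labeled slots) and the fragments.

    Reattaching every fragment into its slot reproduces the input graph
    (see :func:`reassemble`).
    """
    m = Chem.Mol(mol.rdmol)
    if rdMolDescriptors.CalcNumRings(m) == 0:
        raise ScaffoldError(f"{mol.name or 'molecule'} has no ring system")
    cuts = []
    for bond in m.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.IsInRing() and not b.IsInRing():
            cuts.append(bond.GetIdx())
        elif b.IsInRing() and not a.IsInRing():
            cuts.append(bond.GetIdx())
    if not cuts:
        # bare ring system: open one labeled H-slot on the first ring atom
        core = Chem.RWMol(m)
        ring_atom = next(a.GetIdx() for a in m.GetAtoms() if a.IsInRing())
        dummy = core.AddAtom(Chem.Atom(0))
        core.GetAtomWithIdx(dummy).SetAtomMapNum(1)
        core.AddBond(ring_atom, dummy, Chem.BondType.SINGLE)
        out = core.GetMol()
        Chem.SanitizeMol(out)
        return CoreScaffold(core=out, slots=[(ring_atom, "Core1")],
                            provenance=mol.name), []

    frag_mol = Chem.FragmentOnBonds(m, cuts, addDummies=True,
                                    dummyLabels=[(i + 1, i + 1) for i in range(len(cuts))])
    pieces = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=True)
    # the core is the piece containing ring atoms connected to every cut;
    # with exocyclic-only cuts the largest ring-bearing piece is the core
    core_piece = None
    for p in pieces:
        if rdMolDescriptors.CalcNumRings(p) > 0 and (
                core_piece is None
                or p.GetNumHeavyAtoms() > core_piece.GetNumHeavyAtoms()):
            core_piece = p
    fragments = [p for p in pieces if p is not core_piece]

    slots, slot_maps = [], []
    for atom in core_piece.GetAtoms():
        if atom.GetAtomicNum() == 0:
            nb = atom.GetNeighbors()[0]
            label = f"Core{(len(slots) % 3) + 1}"
            atom.SetAtomMapNum(atom.GetIsotope())
            slot_maps.append(atom.GetIsotope())
            atom.SetIsotope(0)
            slots.append((nb.GetIdx(), label))
    for frag in fragments:
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(atom.GetIsotope())
                atom.SetIsotope(0)
    return CoreScaffold(core=core_piece, slots=slots, provenance=mol.name,
                        slot_map_numbers=slot_maps), fragments


def _attach(core: Chem.Mol, assignments: dict[int, Chem.Mol]) -> Chem.Mol:
    """Replace each mapped dummy in ``core`` with the fragment of the same
    map number (fragment dummies carry matching map numbers); hydrogen
    fills a slot when the fragment is None."""
    combined = Chem.RWMol(core)
    for map_num, frag in assignments.items():
        if frag is None:
            continue
        offset = combined.GetNumAtoms()
        combined.InsertMol(frag)
        core_dummy = core_nb = frag_dummy = frag_nb = None
        for atom in combined.GetAtoms():
            if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == map_num:
                if atom.GetIdx() < offset:
                    core_dummy, core_nb = atom.GetIdx(), atom.GetNeighbors()[0].GetIdx()
                else:
                    frag_dummy, frag_nb = atom.GetIdx(), atom.GetNeighbors()[0].GetIdx()
        if core_dummy is None or frag_dummy is None:
            raise ValueError(f"no matching attachment point for slot {map_num}")
        combined.AddBond(core_nb, frag_nb, Chem.BondType.SINGLE)
        for idx in sorted((core_dummy, frag_dummy), reverse=True):
            combined.RemoveAtom(idx)
    out = combined.GetMol()
    # drop any dummies left unassigned (H fill)
    out = Chem.RemoveHs(Chem.RWMol(Chem.DeleteSubstructs(
        out, Chem.MolFromSmarts("[#0]"))).GetMol())
    Chem.SanitizeMol(out)
    return out


def reassemble(core: CoreScaffold, fragments: list[Chem.Mol]) -> Molecule:
    """Inverse of :func:`separate_core`: put every fragment back in its slot."""
    by_map: dict[int, Chem.Mol] = {}
    for frag in fragments:
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                by_map[atom.GetAtomMapNum()] = frag
    return Molecule(rdmol=_attach(core.core, by_map),
                    name=f"{core.provenance}_reassembled")


def parse_fragment(smiles: str) -> Chem.Mol | None:
    """Parse a fragment in ``[*:1]``-attachment notation; None denotes
    hydrogen (leave the slot bare)."""
    if smiles in ("", "H", "[H]"):
        return None
    frag = Chem.MolFromSmiles(smiles)
    if frag is None:
        raise ValueError(f"unparsable fragment SMILES {smiles!r}")
    if not any(a.GetAtomicNum() == 0 for a in frag.GetAtoms()):
        raise ValueError(f"fragment {smiles!r} lacks an attachment point [*:n]")
    return frag


def enumerate_candidates(core: CoreScaffold,
                         fragment_sets: dict[str, list[str]],
                         pool_id: str = "pool1") -> CandidatePool:
    """Cartesian product of fragment choices over core slots.

    ``fragment_sets`` maps slot label -> fragment SMILES list ("H" for a
    bare slot). The pre-filtration pool size equals the product of the
    per-slot cardinalities; duplicate structures are kept distinct in the
    audit but deduplicated in the member list only later, by the filters.
    """
    for label in {lab for _, lab in core.slots}:
        if not fragment_sets.get(label):
            raise ValueError(f"slot {label} has an empty fragment set")
    slot_maps = [(m, label) for m, (_, label) in
                 zip(core.slot_map_numbers, core.slots)]

    members, audit = [], []
    choice_lists = [fragment_sets[label] for _, label in slot_maps]
    for k, combo in enumerate(itertools.product(*choice_lists)):
        assignments = {}
        for (map_num, _), frag_smi in zip(slot_maps, combo):
            frag = parse_fragment(frag_smi)
            if frag is not None:
                frag = Chem.Mol(frag)
                for atom in frag.GetAtoms():
                    if atom.GetAtomicNum() == 0:
                        atom.SetAtomMapNum(map_num)
            assignments[map_num] = frag
        try:
            mol = _attach(core.core, assignments)
        except Exception as exc:
            audit.append({"index": k, "fragments": list(combo), "error": str(exc)})
            continue
        name = f"{core.provenance or 'core'}_cand{k}"
        members.append(Molecule(rdmol=mol, name=name))
        audit.append({"index": k, "name": name, "fragments": list(combo)})
    return CandidatePool(members=members, pool_id=pool_id, audit=audit)


def chemical_filter(pool: CandidatePool, seed: int = 2020) -> CandidatePool:
    """Drop members failing sanitization or 3D embedding; survivors get one
    MMFF-minimized conformer attached. Idempotent."""
    survivors, audit = [], []
    for m in pool.members:
        try:
            rd = Chem.Mol(m.rdmol)
            Chem.SanitizeMol(rd)
            if rd.GetNumConformers() == 0:
                rdH = Chem.AddHs(rd)
                params = AllChem.ETKDGv3()
                params.randomSeed = seed & 0x7FFFFFFF
                if AllChem.EmbedMolecule(rdH, params) != 0:
                    raise ValueError("embedding failed")
                AllChem.MMFFOptimizeMolecule(rdH, maxIters=300)
                rd = Chem.RemoveHs(rdH)
            survivors.append(Molecule(rdmol=rd, name=m.name))
            audit.append({"name": m.name, "kept": True})
        except Exception as exc:
            audit.append({"name": m.name, "kept": False, "reason": str(exc)})
    return CandidatePool(members=_dedup(survivors), pool_id=pool.pool_id, audit=audit)


def _dedup(members: list[Molecule]) -> list[Molecule]:
    seen, out = set(), []
    for m in members:
        key = m.canonical_smiles
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def write_pool_sdf(pool: CandidatePool, path) -> None:
    """Write the pool as a V2000 SDF (one record per member; members that
    passed chemical filtration carry their minimized conformer)."""
    from rdkit.Chem import rdDepictor

    writer = Chem.SDWriter(str(path))
    for m in pool.members:
        rd = Chem.Mol(m.rdmol)
        if rd.GetNumConformers() == 0:
            rdDepictor.Compute2DCoords(rd)
        rd.SetProp("_Name", m.name or m.canonical_smiles)
        writer.write(rd)
    writer.close()


def _load_rules():
    text = importlib.resources.files("agelascreen.data").joinpath("ph_rules.yaml").read_text()
    return yaml.safe_load(text)


def enumerate_states(pool: CandidatePool, ph_range: tuple[float, float] = (5.0, 9.0),
                     rules: dict | None = None) -> CandidatePool:
    """Expand each member into rule-based ionization states and tautomers.

    The rule table (packaged YAML) lists pKa-annotated ionization transforms
    and tautomer transforms; the parent is always retained and duplicates
    are canonicalized away. Idempotent: applying twice adds nothing new.
    """
    lo, hi = ph_range
    if not (0.0 <= lo <= hi <= 14.0):
        raise ValueError("pH range must lie within [0, 14]")
    rules = rules or _load_rules()
    out, audit = [], []
    for m in pool.members:
        states = [m]
        for rule in rules.get("ionization", []):
            fires = (rule["direction"] == "acid" and hi > rule["pka"]) or \
                    (rule["direction"] == "base" and lo < rule["pka"])
            if not fires:
                continue
            states.extend(_apply_transform(m, rule["transform"], rule["name"]))
        for rule in rules.get("tautomers", []):
            states.extend(_apply_transform(m, rule["transform"], rule["name"]))
        for s in states:
            out.append(s)
        audit.append({"name": m.name, "n_states": len(states)})
    return CandidatePool(members=_dedup(out), pool_id=pool.pool_id, audit=audit)


def _apply_transform(m: Molecule, rxn_smarts: str, rule_name: str) -> list[Molecule]:
    rxn = AllChem.ReactionFromSmarts(rxn_smarts)
    # transforms are written against the kekulized graph so aromatic
    # tautomer shifts produce kekulizable products
    mk = Chem.Mol(m.rdmol)
    Chem.Kekulize(mk, clearAromaticFlags=True)
    products = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for prods in rxn.RunReactants((mk,)):
            try:
                p = prods[0]
                Chem.SanitizeMol(p)
                products.append(Molecule(rdmol=p, name=f"{m.name}_{rule_name}"))
            except Exception:
                continue
    return products


def reactive_screen(pool: CandidatePool,
                    blocklist: dict[str, str] | None = None) -> CandidatePool:
    """Remove members matching any reactive-group SMARTS. Idempotent."""
    blocklist = blocklist or REACTIVE_BLOCKLIST
    patterns = {name: Chem.MolFromSmarts(s) for name, s in blocklist.items()}
    survivors, audit = [], []
    for m in pool.members:
        hit = next((name for name, patt in patterns.items()
                    if m.rdmol.HasSubstructMatch(patt)), None)
        if hit is None:
            survivors.append(m)
            audit.append({"name": m.name, "kept": True})
        else:
            audit.append({"name": m.name, "kept": False, "reactive_group": hit})
    return CandidatePool(members=survivors, pool_id=pool.pool_id, audit=audit)


def descriptor_vector(mol: Molecule) -> np.ndarray:
    """7-descriptor physicochemical vector (see DESCRIPTOR_NAMES)."""
    m = mol.rdmol
    halogens = sum(1 for a in m.GetAtoms() if a.GetSymbol() in ("F", "Cl", "Br", "I"))
    return np.array([
        Descriptors.MolWt(m),
        m.GetNumHeavyAtoms(),
        rdMolDescriptors.CalcNumHBD(m),
        rdMolDescriptors.CalcNumHBA(m),
        rdMolDescriptors.CalcNumRings(m),
        halogens,
        Crippen.MolLogP(m),
    ], dtype=float)


def zscore_filter(pool: CandidatePool, actives: list[Molecule],
                  z_min: float = 3.0) -> CandidatePool:
    """Keep candidates physicochemically within ``z_min`` SDs of the actives.

    Each candidate's descriptor vector is z-scored against the active-set
    mean/SD per descriptor; candidates whose maximum |z| exceeds ``z_min``
    are dropped. Zero-variance descriptors are excluded with a warning.
    Idempotent.
    """
    if len(actives) < 2:
        raise ValueError("need at least 2 actives to define the z-score frame")
    A = np.vstack([descriptor_vector(a) for a in actives])
    mean, sd = A.mean(axis=0), A.std(axis=0, ddof=1)
    usable = sd > 1e-12
    if not usable.all():
        dropped = [DESCRIPTOR_NAMES[i] for i in np.where(~usable)[0]]
        warnings.warn(f"zero-variance descriptors excluded: {dropped}")
    survivors, audit = [], []
    for m in pool.members:
        v = descriptor_vector(m)
        z = np.abs((v[usable] - mean[usable]) / sd[usable])
        zmax = float(z.max()) if z.size else 0.0
        if zmax <= z_min:
            survivors.append(m)
        audit.append({"name": m.name, "max_abs_z": round(zmax, 3),
                      "kept": zmax <= z_min})
    return CandidatePool(members=survivors, pool_id=pool.pool_id, audit=audit)
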