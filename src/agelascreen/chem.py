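"""Molecule model, chemical file I/O, and conformer-ensemble generation.

The conformer policy mirrors the screening protocol the package implements:
an ensemble of at most ``cap`` (default 500) conformers per molecule, with a
retention budget of ``per_rot`` (default 20) conformers per rotatable bond.
Amide C-N bonds are deliberately counted as rotatable so that amide-containing
ligands sample cis/trans-like arrangements during shape matching; rigid
molecules (zero rotatable bonds) still receive a ``per_rot``-sized budget so
that ring-pucker variation is represented.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign

__all__ = [
    "Molecule",
    "ConformerSet",
    "ChemistryError",
    "FormatError",
    "GenerationError",
    "parse_structure",
    "rotatable_bond_count",
    "generate_conformers",
    "write_sdf",
    "read_smiles_file",
    "load_analogues",
    "ANALOGUE_NAMES",
]

DEFAULT_SEED = 2020
DEDUP_RMSD = 0.5  # Angstrom, heavy-atom
ANALOGUE_NAMES = ("AA", "CAA", "CEAA", "DCEAA", "EAA", "PAA", "DeBAA", "DeBEAA")


class ChemistryError(ValueError):
    """Chemically invalid input (valence, sanitization)."""


class FormatError(ValueError):
    """Syntactically invalid SMILES/SDF input."""


class GenerationError(RuntimeError):
    """3D embedding failed after the retry budget."""


@dataclass
class Molecule:
    """A sanitized small molecule: atom/bond graph plus optional name.

    Wraps an RDKit mol; the wrapper carries the name and convenience
    accessors used throughout the screening pipeline.
    """

    rdmol: Chem.Mol
    name: str = ""

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.rdmol))

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for atom in self.rdmol.GetAtoms():
            counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        return counts

    def amide_bonds(self) -> list[tuple[int, int]]:
        """C-N single bonds where the carbon bears a double-bonded oxygen."""
        patt = Chem.MolFromSmarts("[CX3](=O)-[NX3]")
        out = []
        for match in self.rdmol.GetSubstructMatches(patt):
            out.append((match[0], match[2]))
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Molecule({self.name or self.canonical_smiles!r})"


@dataclass
class ConformerSet:
    """An energy-sorted, RMSD-deduplicated conformer ensemble.

    ``coords`` holds one (n_heavy_or_all, 3) array per conformer in Angstrom;
    ``energies`` are force-field strains relative to the ensemble minimum and
    are used only for ordering.
    """

    molecule: Molecule
    coords: list[np.ndarray] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)
    seed: int = DEFAULT_SEED

    def __len__(self) -> int:
        return len(self.coords)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.coords)

    def heavy_coords(self, i: int) -> np.ndarray:
        """Coordinates of heavy atoms only, conformer ``i``."""
        mol = self.molecule.rdmol
        heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        return self.coords[i][heavy]

    def heavy_elements(self) -> list[str]:
        mol = self.molecule.rdmol
        return [a.GetSymbol() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]


def _looks_like_sdf(text: str) -> bool:
    lines = text.splitlines()
    return len(lines) >= 4 and ("V2000" in text or "V3000" in text or "$$$$" in text)


def parse_structure(text: str, name: str = "") -> Molecule:
    """Parse a SMILES string or an SDF block into a sanitized Molecule.

    Aromaticity is perceived and valences assigned; a valence violation is
    reported as :class:`ChemistryError`, a syntax problem as
    :class:`FormatError` naming the offending input.
    """
    text = text.strip()
    if not text:
        raise FormatError("empty structure input")
    if _looks_like_sdf(text):
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
        if mol is None:
            raise FormatError("unparsable SDF/mol block")
        if not name:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    else:
        token = text.split()[0]
        mol = Chem.MolFromSmiles(token, sanitize=False)
        if mol is None:
            raise FormatError(f"unparsable SMILES token {token!r}")
        if not name and len(text.split()) > 1:
            name = text.split()[1]
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitization subclasses
        raise ChemistryError(f"sanitization failed for {name or text!r}: {exc}") from exc
    mol = Chem.RemoveHs(mol)
    return Molecule(rdmol=mol, name=name)


def rotatable_bond_count(mol: Molecule) -> int:
    """Count rotatable bonds: non-ring single bonds between two heavy atoms
    that each carry at least one further heavy neighbor.

    Unlike the common "strict" definition, amide C-N bonds are counted, so
    amide linkages contribute to the conformer retention budget.
    """
    m = mol.rdmol
    n = 0
    for bond in m.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue

        def heavy_degree_excluding(atom, other):
            return sum(
                1
                for nb in atom.GetNeighbors()
                if nb.GetAtomicNum() > 1 and nb.GetIdx() != other.GetIdx()
            )

        if heavy_degree_excluding(a, b) >= 1 and heavy_degree_excluding(b, a) >= 1:
            n += 1
    return n


def conformer_budget(mol: Molecule, cap: int = 500, per_rot: int = 20) -> int:
    """Maximum ensemble size: min(cap, per_rot * max(1, rotatable bonds))."""
    return min(cap, per_rot * max(1, rotatable_bond_count(mol)))


def generate_conformers(
    mol: Molecule,
    seed: int = DEFAULT_SEED,
    cap: int = 500,
    per_rot: int = 20,
    dedup_rmsd: float = DEDUP_RMSD,
) -> ConformerSet:
    """Generate an energy-sorted, RMSD-deduplicated conformer ensemble.

    Embeds up to twice the retention budget with a seeded distance-geometry
    embedder, relaxes each conformer with MMFF94 (UFF fallback), sorts by
    strain, and greedily keeps conformers whose best heavy-atom RMSD to every
    kept conformer is at least ``dedup_rmsd``. Deterministic for a fixed seed.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if mol.num_heavy_atoms < 1:
        raise ValueError("molecule has no heavy atoms")
    budget = conformer_budget(mol, cap=cap, per_rot=per_rot)
    molH = Chem.AddHs(Chem.Mol(mol.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.useRandomCoords = False
    params.enforceChirality = True
    n_try = min(2 * budget, budget + 50)
    cids = list(AllChem.EmbedMultipleConfs(molH, numConfs=n_try, params=params))
    if not cids:
        # retry budget: one more attempt with random coordinates
        params.useRandomCoords = True
        cids = list(AllChem.EmbedMultipleConfs(molH, numConfs=n_try, params=params))
    if not cids:
        raise GenerationError(f"3D embedding failed for {mol.name or mol.canonical_smiles}")

    energies = []
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(molH, maxIters=500)
        if all(e is None for _, e in results):
            raise ValueError
        energies = [e if e is not None else np.inf for _, e in results]
    except Exception:
        results = AllChem.UFFOptimizeMoleculeConfs(molH, maxIters=500)
        energies = [e if e is not None else np.inf for _, e in results]

    order = sorted(range(len(cids)), key=lambda i: (energies[i], i))
    heavy = [a.GetIdx() for a in molH.GetAtoms() if a.GetAtomicNum() > 1]
    noH = Chem.RemoveHs(Chem.Mol(molH))

    kept: list[int] = []
    for i in order:
        if len(kept) >= budget:
            break
        ok = True
        for j in kept:
            rms = rdMolAlign.GetBestRMS(noH, noH, prbId=cids[i], refId=cids[j])
            if rms < dedup_rmsd:
                ok = False
                break
        if ok:
            kept.append(i)

    emin = min(energies[i] for i in kept)
    coords = []
    out_energies = []
    for i in kept:
        conf = molH.GetConformer(cids[i])
        xyz = np.array(conf.GetPositions(), dtype=float)
        coords.append(xyz[heavy])
        out_energies.append(float(energies[i] - emin))
    return ConformerSet(molecule=mol, coords=coords, energies=out_energies, seed=seed)


def write_sdf(confs: ConformerSet, path) -> None:
    """Write one V2000 SDF record per conformer (heavy atoms only)."""
    if len(confs) == 0:
        raise ValueError("cannot write an empty conformer set")
    mol = Chem.Mol(confs.molecule.rdmol)
    mol.RemoveAllConformers()
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for i, xyz in enumerate(confs.coords):
        conf = Chem.Conformer(mol.GetNumAtoms())
        for a in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(a, xyz[a].tolist())
        m = Chem.Mol(mol)
        m.AddConformer(conf, assignId=True)
        m.SetProp("_Name", f"{confs.molecule.name or 'mol'}_conf{i}")
        m.SetProp("rel_energy", f"{confs.energies[i]:.4f}")
        m.SetProp("seed", str(confs.seed))
        writer.write(m)
    writer.close()


def read_smiles_file(path) -> list[Molecule]:
    """Read a one-molecule-per-line SMILES file with an optional name column."""
    mols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            mols.append(parse_structure(line))
    return mols


def _packaged(fname: str):
    return importlib.resources.files("agelascreen.data").joinpath(fname)


def load_analogues() -> dict[str, Molecule]:
    """The packaged 8-analogue library (AA and seven analogues)."""
    text = _packaged("analogues.smi").read_text()
    out: dict[str, Molecule] = {}
    for line in text.splitlines():
        if line.strip():
            m = parse_structure(line)
            out[m.name] = m
    return out


def load_activity_table():
    """The packaged predicted-affinity table as a pandas DataFrame."""
    import pandas as pd

    with importlib.resources.as_file(_packaged("table1.csv")) as p:
        return pd.read_csv(p)
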