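"""Shared fixtures: packaged analogue library, cached conformer ensembles,
shape-aligned coordinates, and synthetic pose complexes.

Expensive artifacts (conformers, alignments) are session-scoped so the
worked 8-compound study is computed once and reused across tests.
"""

from __future__ import annotations

import itertools

import pytest

from agelascreen import chem, fixtures, pipeline

SEED = 2020


@pytest.fixture(scope="session")
def analogues():
    return chem.load_analogues()


@pytest.fixture(scope="session")
def activity_table():
    return chem.load_activity_table()


@pytest.fixture(scope="session")
def analogue_conformers(analogues):
    return {name: chem.generate_conformers(m, seed=SEED)
            for name, m in analogues.items()}


@pytest.fixture(scope="session")
def aligned_to_aa(analogue_conformers):
    """Every analogue's best-alignment coordinates in the AA frame."""
    return pipeline.align_library_to_reference(
        analogue_conformers, "AA", pipeline.ScreenConfig(seed=SEED))


def drug_like_smiles(n: int = 100) -> list[str]:
    """Deterministic combinatorial set of small drug-like molecules."""
    scaffolds = [
        "c1ccc({r})cc1", "c1ccnc({r})c1", "c1cc({r})c[nH]1",
        "C1CCN({r})CC1", "c1ccc2[nH]c({r})cc2c1", "C1CC({r})CCO1",
    ]
    subs = ["C", "CC", "Cl", "Br", "O", "OC", "N", "C(=O)O", "C(=O)NC",
            "CO", "C#N", "F", "CN", "CCN", "C(C)C", "OCC", "SC"]
    out = []
    for scaf, sub in itertools.product(scaffolds, subs):
        out.append(scaf.format(r=sub))
        if len(out) >= n:
            break
    return out[:n]


@pytest.fixture(scope="session")
def standard_pose(tmp_path_factory):
    """Synthetic complex with one planted interaction of each kind."""
    path = tmp_path_factory.mktemp("poses") / "standard.pdb"
    spec = [
        {"type": "hbond", "role": "ligand_donor", "distance": 2.9,
         "angle": 160.0, "residue": ("A", 2873, "U")},
        {"type": "hbond", "role": "ligand_acceptor", "distance": 2.9,
         "angle": 170.0, "residue": ("A", 2869, "U")},
        {"type": "halogen_pi", "distance": 3.4, "residue": ("A", 2875, "U")},
        {"type": "pi_stack", "distance": 3.6, "geometry": "parallel",
         "residue": ("A", 2821, "C")},
    ]
    fixtures.make_fixture_complex(spec, path)
    return path, spec


@pytest.fixture(scope="session")
def shell9_pose(tmp_path_factory):
    """Synthetic complex with a planted 9-residue contact shell."""
    path = tmp_path_factory.mktemp("poses") / "shell9.pdb"
    residues = [("A", 2403, "G"), ("A", 2820, "A"), ("A", 2821, "A"),
                ("A", 2869, "U"), ("A", 2870, "C"), ("A", 2872, "A"),
                ("A", 2873, "U"), ("A", 2874, "G"), ("A", 2875, "U")]
    directions = [(1, 0, 0), (-1, 0, 0), (0, 1, 0.3), (0, -1, 0), (0, 0.3, 1),
                  (0, 0, -1), (1, 1, 0), (-1, -1, 0.5), (1, 0, 1)]
    spec = [{"type": "contact", "distance": 4.0, "residue": r, "direction": d}
            for r, d in zip(residues, directions)]
    fixtures.make_fixture_complex(spec, path)
    return path, [r for r, _ in zip(residues, directions)]
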