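"""De novo analogue enumeration from the agelastatin core.

Separates AA into its tetracyclic core plus substituents, re-populates the
halogen slot exhaustively from a small fragment set, and pushes the pool
through the filter cascade (sanitization/embedding, protonation-state
enumeration, reactive-group screen, physicochemical Z-score vs the active
analogues). The printed counts show how each filter narrows the pool.
"""

from agelascreen import chem, denovo

analogues = chem.load_analogues()
core, frags = denovo.separate_core(analogues["AA"])
print(f"AA core: {core.n_slots} open slots; severed fragments:",
      [chem.Chem.MolToSmiles(f) for f in frags])

sets = {label: ["H", "[*:1]F", "[*:1]Cl", "[*:1]Br", "[*:1]C", "[*:1]OC"]
        for _, label in core.slots}
pool = denovo.enumerate_candidates(core, sets)
print(f"enumerated: {len(pool)} candidates "
      f"(= product of slot cardinalities before filtration)")

pool = denovo.chemical_filter(pool)
print(f"after chemical filtration (valence + 3D embedding): {len(pool)}")
pool = denovo.enumerate_states(pool, ph_range=(5.0, 9.0))
print(f"after tautomer/ionization expansion, pH 5-9: {len(pool)}")
pool = denovo.reactive_screen(pool)
print(f"after reactive-group screen: {len(pool)}")
actives = [analogues[n] for n in ("AA", "CAA", "CEAA", "DCEAA")]
pool = denovo.zscore_filter(pool, actives, z_min=3.0)
print(f"after Z-score filter (|z| <= 3 vs actives): {len(pool)}")
print("surviving candidates:", pool.smiles()[:10])
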