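"""Shape-screen the packaged analogue library against agelastatin A.

Builds conformer ensembles for AA and three analogues, superposes every
conformer pair, and reports the volume-overlap similarity Sim = V∩/V∪.
Hits below the 0.7 cutoff are dropped and at most 4 alignments per ligand
are kept. A similarity near 1 means the analogue fills almost exactly the
same space as AA; the chloro/ethyl analogues typically score 0.75-0.95.
"""

from agelascreen import chem, shape

analogues = chem.load_analogues()
subset = {n: analogues[n] for n in ("AA", "CAA", "CEAA", "DeBAA")}
confs = {n: chem.generate_conformers(m, seed=2020) for n, m in subset.items()}

table = shape.screen_library(list(confs.values()), confs["AA"],
                             cutoff=0.7, n_align=4, typed=True)
print(table.to_string(index=False))
best = table.groupby("query")["sim"].max()
print("\nbest Sim vs AA per ligand (1.0 = identical volume):")
print(best.to_string())
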