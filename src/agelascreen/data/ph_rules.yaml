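# Protonation / tautomer rule table used by denovo state enumeration.
# Each ionization rule: a SMARTS for the neutral group, its pKa, and the
# charged form produced when the pH window crosses the pKa.
# Each tautomer rule: a reaction SMARTS applied once per matching site.
ionization:
  - name: carboxylic_acid
    smarts: "[CX3](=O)[OX2H1]"
    pka: 4.76
    direction: acid            # deprotonates when pH_max > pKa
    transform: "[C:1](=[O:2])[OX2H1:3]>>[C:1](=[O:2])[O-:3]"
  - name: aliphatic_primary_amine
    smarts: "[NX3;H2;!$(NC=O);!$(Na)]"
    pka: 10.6
    direction: base            # protonates when pH_min < pKa
    transform: "[NX3;H2;!$(NC=O):1]>>[NX4H3+:1]"
  - name: aliphatic_secondary_amine
    smarts: "[NX3;H1;!$(NC=O);!$(Na);!$(N=*);!R0]"
    pka: 11.0
    direction: base
    transform: "[NX3;H1;!$(NC=O);!$(N=*):1]>>[NX4H2+:1]"
  - name: phenol
    smarts: "[c][OX2H1]"
    pka: 10.0
    direction: acid
    transform: "[c:1][OX2H1:2]>>[c:1][O-:2]"
# tautomer transforms are written against the kekulized graph
tautomers:
  - name: 2-pyridone_2-hydroxypyridine
    smarts: "[nH1]1[cX3](=O)cccc1"
    transform: "[NX3;H1:1]1-[C:2](=[O:3])-[C:4]=[C:5]-[C:6]=[C:7]-1>>[N:1]1=[C:2](-[OX2H1:3])-[C:4]=[C:5]-[C:6]=[C:7]-1"
  - name: keto_enol_1_3_dicarbonyl
    smarts: "[CX3](=O)[CX4H2][CX3](=O)"
    transform: "[C:1](=[O:2])[CH2:3][C:4](=[O:5])>>[C:1](=[O:2])[CH1:3]=[C:4][OX2H1:5]"
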