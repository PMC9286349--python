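"""Map peptides to their possible proteome origins.

Builds a two-protein toy proteome and classifies four peptides as
non-spliced, cis-spliced (normal or reverse order), trans-spliced or
unexplainable, printing every supporting explanation.
"""

from splicebench import (
    MapperParams,
    Proteome,
    ProteinEntry,
    build_index,
    classify,
)

proteome = Proteome(
    [
        ProteinEntry("PROT_A", "MKLLPETGALDDWNQ"),
        ProteinEntry("PROT_B", "CCHRFNWYGG"),
    ]
)
index = build_index(proteome)
params = MapperParams(max_intervening=25)

for peptide in ["LPETG", "MKGAL", "GALMK", "MKYGG", "WWWWW"]:
    cls = classify(peptide, index, params)
    print(f"{peptide}: {cls.category} ({len(cls.explanations)} explanation(s))")
    for e in cls.explanations:
        left = f"{e.left_reactant.accession}[{e.left_reactant.start}:{e.left_reactant.end}]"
        if e.right_reactant is None:
            print(f"    {e.category}: {left}")
        else:
            right = f"{e.right_reactant.accession}[{e.right_reactant.start}:{e.right_reactant.end}]"
            iv = f", intervening={e.intervening_len}" if e.intervening_len is not None else ""
            print(f"    {e.category}: {left} + {right} (split {e.split_point}{iv})")

# MKGAL is cis-spliced in normal order (MK before GAL in PROT_A, 5 intervening
# residues); GALMK is the same pair ligated in reverse order; MKYGG needs two
# proteins, hence trans; WWWWW matches nothing.
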