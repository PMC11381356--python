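"""Published Ty3 retrotransposon reference data used in worked examples.

Small printed sequences and coordinates from the Ty3 (Saccharomyces
cerevisiae, element YGRWTy3-1) literature: the six palindromic hexamers in
the 5' region of the genomic RNA (candidate dimerization sites; PAL6 /
CUGCAG is the experimentally supported dimerization site), the polypurine
tract, the +1 frameshift heptamer, and the NCp9 nucleocapsid protein
sequence.  Coordinates are 1-based inclusive positions on the gRNA.
"""

from __future__ import annotations

#: length of the full Ty3 genomic RNA (nt)
TY3_GRNA_LENGTH = 5052

#: the in-vitro 5' transcript spans +1..429 of the gRNA
TY3_5P_RNA_SPAN = (1, 429)

#: palindromic hexamers in the Ty3 5' region: (sequence, 1-based start)
TY3_5P_PALINDROMES: list[tuple[str, int]] = [
    ("AUUAAU", 18),
    ("CUCGAG", 99),
    ("UAGCUA", 174),
    ("ACAUGU", 345),
    ("GAUAUC", 355),
    ("CUGCAG", 391),   # PAL6 — the dimerization site (DS)
]

#: polypurine tract: plus-strand primer for reverse transcription
TY3_PPT_SEQUENCE = "GAGAGAGAGGAAGA"
TY3_PPT_SPAN = (4776, 4789)

#: +1 programmed frameshift heptamer between GAG and POL
TY3_FS_SEQUENCE = "GCGAGUU"
TY3_FS_SPAN = (1046, 1052)

#: Ty3 nucleocapsid protein NCp9 (Gag3-derived; 57 residues)
NCP9_SEQUENCE = (
    "TVRTRRSYNKPMSNHRNRRNNNPSREECIKNRLCFYCKKEGHRLNECRARKASSNRS"
)
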