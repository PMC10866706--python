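"""Reference sequence and experiment layout for the KRAS ddPCA study.

The scans mutagenize the full KRAS4B isoform (UniProt P01116-2, residues
1-188). Positions everywhere in this package are 1-based indices into this
sequence.
"""

from __future__ import annotations

# KRAS4B, residues 1-188 (UniProt P01116-2).
KRAS_SEQUENCE = (
    "MTEYKLVVVGAGGVGKSALT"
    "IQLIQNHFVDEYDPTIEDSY"
    "RKQVVIDGETCLLDILDTAG"
    "QEEYSAMRDQYMRTGEGFLC"
    "VFAINNTKSFEDIHHYREQI"
    "KRVKDSEDVPMVLVGNKCDL"
    "PSRTVDTKQAQDLARSYGIP"
    "FIETSAKTRQGVDDAFYTLV"
    "REIRKHKEKMSKDGKKKKKK"
    "SKTKCVIM"
)

N_RESIDUES = len(KRAS_SEQUENCE)  # 188

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Stop codon symbol; parsed and carried in fitness tables but excluded from
#: energy-model fitting (the three-state model has no truncation state).
STOP = "*"

#: The six binding partners assayed by BindingPCA, in canonical order.
PARTNERS = ("RAF1", "PIK3CG", "RALGDS", "SOS1", "K27", "K55")

#: Mutagenesis blocks: the library was constructed and sequenced in three
#: blocks of consecutive positions; each block has its own experiments.
BLOCKS = (1, 2, 3)
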