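"""Shared constants: the 96 single-base-substitution channels and codon table."""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# The six pyrimidine-centred substitution types in canonical COSMIC order.
SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# 96 channels: substitution type blocks, 16 flank combinations each,
# 5' flank outer loop, 3' flank inner loop — e.g. "A[C>A]A", "A[C>A]C", ...
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_TYPES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS_96)}

CONSEQUENCES = ("missense", "nonsense", "splice", "synonymous", "indel", "other")

# Nonsynonymous consequences counted toward TMB and dN/dS numerators.
NONSYNONYMOUS = frozenset({"missense", "nonsense", "splice", "indel"})

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def channel_of(ref: str, alt: str, context3: str) -> str:
    """Map an SNV with its +strand trinucleotide context to a 96-channel name.

    Purine-reference mutations are reverse-complemented into the
    pyrimidine-centred convention.
    """
    ref, alt, context3 = ref.upper(), alt.upper(), context3.upper()
    if len(ref) != 1 or len(alt) != 1 or len(context3) != 3:
        raise ValueError(f"not an SNV with 3-mer context: {ref}>{alt} {context3}")
    if context3[1] != ref:
        raise ValueError(f"context {context3} does not match ref {ref}")
    if ref not in PYRIMIDINES:
        context3 = revcomp(context3)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"
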