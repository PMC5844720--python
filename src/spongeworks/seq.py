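"""Small nucleotide-string helpers used across modules.

All internal matching is done in DNA space; RNA inputs (miRNA matures) are
normalised with U->T at module boundaries.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def to_dna(seq: str) -> str:
    """Uppercase and map RNA to DNA alphabet (U -> T)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)
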