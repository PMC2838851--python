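"""Small sequence helpers shared across modules.

All genomic coordinates in this package are 0-based, half-open, on the
+ strand of the reference; minus-strand features carry a strand flag and
their sequences are reported in 5'->3' transcript orientation.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA alphabet (T->U)."""
    return seq.replace("T", "U").replace("t", "u")


def back_transcribe(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
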