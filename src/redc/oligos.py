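"""Oligonucleotide constants of the bridge-adapter chimera layout.

The library design places a fixed 37-nt bridge adapter between the DNA
fragment and the reverse-complemented RNA 3' fragment on the forward read,
and a template-switch GGG at the start of the reverse read.  All probe
sequences used for read-through trimming derive from these oligos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: complement lookup used throughout; N maps to N
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OligoCatalog:
    """Fixed oligo sequences scanned for during read demultiplexing.

    ``bridge_r1`` is the full bridge as it appears in the forward read;
    its rightmost two bases (``GA``) abut the RNA 3' end and must match
    exactly.  ``bridge_r2_probe`` is the start of the reverse-complemented
    bridge as it appears when the reverse read runs through the RNA into
    the adapter; ``sto_probe`` likewise marks switch-template read-through
    at the end of the forward read.
    """

    bridge_r1: str = "AGTCGGAGCGTTGCCTATCGCATTGATGGTGCTAGGA"
    bridge_r1_protected_suffix: str = "GA"
    bridge_r2_probe: str = "TCCTAGCACCATCA"
    sto_probe: str = "CCCAGATCGGAAGA"
    r2_prefix: str = "GGG"
    probe_len: int = 14

    def __post_init__(self) -> None:
        if len(self.bridge_r1) != 37:
            raise ValueError("bridge must be 37 nt")
        if not self.bridge_r1.endswith(self.bridge_r1_protected_suffix):
            raise ValueError("protected suffix must terminate the bridge")


#: read-through context appended after the STO probe start in the forward
#: read (Illumina adapter continuation); used by the simulator only.
STO_READTHROUGH = "CCCAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

DEFAULT_CATALOG = OligoCatalog()
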