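"""Restriction-enzyme model and degenerate-site scanning.

The enzyme of interest for maize-style genotyping-by-sequencing is ApeKI,
a type II endonuclease recognizing the degenerate 5 bp motif GCWGC
(W = A or T) and cutting after the first base on the top strand
(G^CWGC), which leaves a 3-base 5' overhang (CWG).  Because the
recognition family is its own reverse complement (GCAGC <-> GCTGC), a
single top-strand scan finds every cut position; no bottom-strand pass
is needed and no site is counted twice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def expand_iupac(motif: str) -> list[str]:
    """All concrete A/C/G/T strings matching an IUPAC motif."""
    out = [""]
    for ch in motif.upper():
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise ValueError(f"not an IUPAC DNA letter: {ch!r}") from None
        out = [p + b for p in out for b in bases]
    return out


@lru_cache(maxsize=None)
def _motif_regex(motif: str) -> re.Pattern:
    # Lookahead so overlapping matches are all reported.  Degenerate
    # letters in the *sequence* (for example N) never match: only
    # concrete A/C/G/T bases can constitute a recognition site.
    body = "".join(ch if len(IUPAC[ch]) == 1 else f"[{IUPAC[ch]}]"
                   for ch in motif.upper())
    return re.compile(f"(?={body})")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with a possibly degenerate recognition site.

    Parameters
    ----------
    name : str
    recognition : str
        IUPAC motif of the recognition site on the top strand.
    cut_offset_top : int
        Cut position on the top strand, in bases from the start of the
        recognition site (ApeKI: 1, i.e. G^CWGC).
    """

    name: str
    recognition: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset_top <= len(self.recognition):
            raise ValueError("cut offset outside recognition site")
        for ch in self.recognition.upper():
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC letter {ch!r} in recognition site")

    @property
    def overhang_length(self) -> int:
        """Length of the 5' overhang for palindromic-family sites."""
        return len(self.recognition) - 2 * self.cut_offset_top

    @property
    def remnant(self) -> str:
        """Motif left at the start of a cut fragment's top strand (ApeKI: CWGC)."""
        return self.recognition[self.cut_offset_top:].upper()

    def remnant_seqs(self) -> list[str]:
        """Concrete expansions of the remnant motif (ApeKI: CAGC, CTGC)."""
        return expand_iupac(self.remnant)

    def find_sites(self, seq: str) -> list[int]:
        """0-based start positions of recognition-site matches on the top strand.

        Overlapping matches are all reported.  For self-reverse-complementary
        families such as GCWGC the top-strand scan covers both strands.
        """
        return [m.start() for m in _motif_regex(self.recognition).finditer(seq.upper())]

    def occurs_in(self, seq: str) -> bool:
        return bool(_motif_regex(self.recognition).search(seq.upper()))


#: The enzyme used throughout: ApeKI, G^CWGC with a 3-base 5' overhang.
APEKI = RestrictionEnzyme("ApeKI", "GCWGC", 1)


def find_sites(seq: str, enzyme: RestrictionEnzyme = APEKI) -> list[int]:
    """Module-level convenience wrapper around :meth:`RestrictionEnzyme.find_sites`."""
    return enzyme.find_sites(seq)
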