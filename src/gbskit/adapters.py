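"""Adapter and primer sequences, and full PCR amplicon assembly.

Two double-stranded adapters are ligated to ApeKI-cut fragments: the
"barcode" adapter, whose top strand ends in a 4-8 bp sample barcode, and
the "common" adapter.  Both present a CWG sticky end compatible with the
ApeKI 5' overhang.  PCR primers 1 and 2 prime off the ligated adapters
and add the flow-cell binding tails, so the complete single-insert
amplicon (top strand) is

    primer-1 tail | barcode-adapter top | barcode | fragment | CWG |
    common-adapter top remainder | revcomp(primer-2 tail)

which is ``122 + len(barcode) + len(fragment)`` bases; with no insert at
all the two adapters ligate to each other and the product is an adapter
dimer of ``122 + len(barcode)`` bp (~128 bp for a 6-base barcode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .enzyme import revcomp

_BARCODE_ADAPTER_TOP = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"
_COMMON_ADAPTER_TOP = "CWGAGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"
_COMMON_ADAPTER_BOTTOM = "CTCGGCATTCCTGCTGAACCGCTCTTCCGATCT"
_PCR_PRIMER_1 = ("AATGATACGGCGACCACCGAGATCT"
                 "ACACTCTTTCCCTACACGACGCTCTTCCGATCT")
_PCR_PRIMER_2 = ("CAAGCAGAAGACGGCATACGAGATCGGT"
                 "CTCGGCATTCCTGCTGAACCGCTCTTCCGATCT")

#: First 8 bases of the common adapter as seen past the CWG remnant in a
#: read-through read; detecting this inside a 64-base window marks a
#: fragment shorter than 64 bases.
ADAPTER_READTHROUGH_START = "AGATCGGA"


@dataclass(frozen=True)
class AdapterKit:
    """The oligonucleotide set used for library construction.

    ``W`` positions in stored sequences are kept as the IUPAC letter;
    they are instantiated when a concrete molecule is assembled (the
    ligated W always reconstitutes the genomic base of the cut site).
    """

    barcode_adapter_top: str = _BARCODE_ADAPTER_TOP
    common_adapter_top: str = _COMMON_ADAPTER_TOP
    common_adapter_bottom: str = _COMMON_ADAPTER_BOTTOM
    pcr_primer_1: str = _PCR_PRIMER_1
    pcr_primer_2: str = _PCR_PRIMER_2

    def __post_init__(self) -> None:
        if not self.common_adapter_top.startswith(("CWG", "CAG", "CTG")):
            raise ValueError("common adapter top must begin with the CWG remnant")
        if self.common_adapter_top[3:11] != ADAPTER_READTHROUGH_START:
            raise ValueError("common adapter must continue with AGATCGGA")
        if not self.pcr_primer_1.endswith(self.barcode_adapter_top):
            raise ValueError("primer 1 3' segment must match the barcode adapter")
        if not self.pcr_primer_2.endswith(self.common_adapter_bottom):
            raise ValueError("primer 2 3' segment must match the common adapter")

    @property
    def pcr1_tail(self) -> str:
        """Primer-1 5' tail upstream of the barcode-adapter binding site."""
        return self.pcr_primer_1[: -len(self.barcode_adapter_top)]

    @property
    def pcr2_tail(self) -> str:
        """Primer-2 5' tail upstream of the common-adapter binding site."""
        return self.pcr_primer_2[: -len(self.common_adapter_bottom)]

    @property
    def common_adapter_top_rest(self) -> str:
        """Common adapter top strand past the CWG sticky end."""
        return self.common_adapter_top[3:]

    def barcode_adapter_bottom(self, barcode: str, w: str = "A") -> str:
        """Bottom strand of the barcode adapter for a given barcode."""
        return "C" + w + "G" + revcomp(barcode) + revcomp(self.barcode_adapter_top)


DEFAULT_KIT = AdapterKit()


def build_amplicon(insert: str, barcode: str, kit: AdapterKit = DEFAULT_KIT,
                   w: str = "A") -> str:
    """Assemble the top strand of a full PCR product.

    Parameters
    ----------
    insert : str
        Top-strand sequence of an internal digest fragment, cut to cut
        (it therefore starts with its own CWGC remnant), or the empty
        string for an adapter dimer.
    barcode : str
        The sample barcode (4-8 bases, A/C/G/T).
    w : str
        Base instantiating the common adapter's W position.  In a real
        molecule the ligated W reconstitutes the genomic base of the far
        cut site; for standalone assembly it defaults to A.

    Returns
    -------
    str of length ``122 + len(barcode) + len(insert)``.
    """
    barcode = barcode.upper()
    if not 4 <= len(barcode) <= 8 or set(barcode) - set("ACGT"):
        raise ValueError(f"invalid barcode: {barcode!r}")
    if w not in ("A", "T"):
        raise ValueError("W must instantiate to A or T")
    insert = insert.upper()
    if set(insert) - set("ACGT"):
        raise ValueError("insert must be a concrete DNA string")
    return (kit.pcr1_tail
            + kit.barcode_adapter_top
            + barcode
            + insert
            + "C" + w + "G"
            + kit.common_adapter_top_rest
            + revcomp(kit.pcr2_tail))
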