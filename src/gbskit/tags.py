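"""The 64-base sequence tag: the atomic marker unit.

A tag is a canonical 64-base string derived from one flank of a
restriction cut.  It begins with the 4-base cut-site remnant (CWGC for
ApeKI) and, when the underlying fragment runs out before 64 bases, is
filled to length with polyA.  ``real_length`` records how many leading
bases are genuine sequence (fragment plus, for short fragments, the far
CWG remnant regenerated by adapter ligation); everything after that is
fill.  Tags compare as full 64-base strings, padding included.
"""

from __future__ import annotations

from dataclasses import dataclass

TAG_LENGTH = 64

_REMNANTS = ("CAGC", "CTGC")


@dataclass(frozen=True, slots=True)
class Tag:
    sequence: str
    real_length: int

    def __post_init__(self) -> None:
        if len(self.sequence) != TAG_LENGTH:
            raise ValueError(f"tag must be exactly {TAG_LENGTH} bases")
        if not 4 <= self.real_length <= TAG_LENGTH:
            raise ValueError("real_length must be in [4, 64]")
        if self.sequence[:4] not in _REMNANTS:
            raise ValueError("tag must begin with the cut-site remnant C[AT]GC")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("tag may contain only A/C/G/T")
        if any(b != "A" for b in self.sequence[self.real_length:]):
            raise ValueError("bases beyond real_length must be polyA fill")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.sequence


def make_tag(raw: str) -> Tag:
    """Canonicalize a raw flank sequence into a 64-base tag.

    ``raw`` is truncated to 64 bases or polyA-filled up to 64 bases;
    its retained length is recorded as ``real_length``.
    """
    raw = raw.upper()
    keep = min(len(raw), TAG_LENGTH)
    return Tag(raw[:keep] + "A" * (TAG_LENGTH - keep), keep)
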