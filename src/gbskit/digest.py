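"""In-silico restriction digests, expected sequence tags, and size histograms.

Coordinates are 0-based and half-open throughout, so the fragments of a
digest tile their source exactly.  For ApeKI (G^CWGC) a cut at
recognition start ``s`` separates the sequence at ``s + 1``: the left
fragment ends with the recognition G, the right fragment begins with the
CWGC remnant.

Expected 64-base tags are read inward from each cut.  The left-flank tag
of an internal fragment is the top strand starting at the remnant; the
right-flank tag is the bottom strand read from the other cut (reverse
complement), which likewise begins with a C[AT]GC remnant.  A fragment
shorter than 64 bases yields tags that run through the far cut's CWG
remnant (the three bases that adapter ligation regenerates) and are then
polyA-filled to 64 — the same sequence the read filter produces from a
real read-through read, so in-silico and observed tags collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .enzyme import APEKI, RestrictionEnzyme, revcomp
from .tags import TAG_LENGTH, Tag, make_tag


@dataclass(frozen=True, slots=True)
class Fragment:
    source_id: str
    start: int
    end: int
    sequence: str
    left_cut: bool
    right_cut: bool

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("fragment coordinates inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_internal(self) -> bool:
        return self.left_cut and self.right_cut


def digest(seq: str, enzyme: RestrictionEnzyme = APEKI,
           source_id: str = "seq") -> list[Fragment]:
    """Cut a linear sequence at every recognition site.

    The fragments are returned left to right; their concatenation
    reproduces the input.
    """
    seq = seq.upper()
    cuts = [s + enzyme.cut_offset_top for s in enzyme.find_sites(seq)]
    # Overlapping degenerate sites can nominate duplicate or out-of-order
    # cut positions only if the motif overlaps itself; dedupe defensively.
    cuts = sorted(set(c for c in cuts if 0 < c < len(seq)))
    bounds = [0] + cuts + [len(seq)]
    out = []
    for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
        out.append(Fragment(source_id, a, b, seq[a:b],
                            left_cut=i > 0, right_cut=i < len(bounds) - 2))
    return out


@dataclass(frozen=True, slots=True)
class TagLocus:
    """Where a tag comes from: its source sequence, the coordinate of the
    cut it flanks (top-strand cut position), and the flank read direction
    ('L' = top strand rightward, 'R' = bottom strand leftward)."""

    tag: Tag
    source_id: str
    cut_position: int
    flank: str


def _internal_tag_loci(seq: str, enzyme: RestrictionEnzyme,
                       source_id: str) -> Iterable[TagLocus]:
    seq = seq.upper()
    sites = enzyme.find_sites(seq)
    off = enzyme.cut_offset_top
    rem = len(enzyme.remnant) - 1  # bases of far remnant regenerated by ligation (CWG)
    for s1, s2 in zip(sites, sites[1:]):
        c1, c2 = s1 + off, s2 + off
        if c2 <= c1:
            continue
        # fragment plus the far CWG remnant: the maximal real sequence a read can see
        window = seq[c1:s2 + off + rem]
        yield TagLocus(make_tag(window[:TAG_LENGTH]), source_id, c1, "L")
        yield TagLocus(make_tag(revcomp(window[-TAG_LENGTH:])), source_id, c2, "R")


def reference_tag_loci(genome: Mapping[str, str], enzyme: RestrictionEnzyme = APEKI,
                       ) -> list[TagLocus]:
    """Expected tags with their genomic anchors, internal fragments only.

    Terminal (sequence-end) fragments carry only one cut, so no amplicon
    with both adapters can form from them; their flanks emit no tag.
    """
    out: list[TagLocus] = []
    for name, seq in genome.items():
        out.extend(_internal_tag_loci(seq, enzyme, name))
    return out


def expected_tags_from_reference(genome: Mapping[str, str],
                                 enzyme: RestrictionEnzyme = APEKI) -> set[Tag]:
    """The set of 64-base tags an in-silico digest of ``genome`` predicts."""
    return {locus.tag for locus in reference_tag_loci(genome, enzyme)}


def tag_position_table(genome: Mapping[str, str],
                       enzyme: RestrictionEnzyme = APEKI) -> pd.DataFrame:
    """Unique physical position per tag, for anchoring and biallelic merging.

    Returns a DataFrame indexed by tag sequence with columns
    ``source``, ``position`` (cut coordinate) and ``strand`` ('+' for a
    left flank, '-' for a right flank).  Tags observed at more than one
    locus are dropped: they cannot be anchored to a unique position.
    """
    rows = [(l.tag.sequence, l.source_id, l.cut_position,
             "+" if l.flank == "L" else "-")
            for l in reference_tag_loci(genome, enzyme)]
    df = pd.DataFrame(rows, columns=["tag", "source", "position", "strand"])
    df = df.drop_duplicates()
    df = df[~df["tag"].duplicated(keep=False)]
    return df.set_index("tag")


@dataclass(frozen=True)
class SizeHistogram:
    """Fragment-length histogram with fixed-width bins.

    Bin ``k`` (labelled by its upper edge ``k * bin_width``) covers
    lengths in ``(bin_width * (k - 1), bin_width * k]``, so the "50" bin
    holds fragments of 1-50 bp.
    """

    bin_width: int
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def fragment_size_histogram(fragments: Iterable[Fragment | int],
                            bin_width: int = 50) -> SizeHistogram:
    counts: dict[int, int] = {}
    for frag in fragments:
        size = frag if isinstance(frag, int) else len(frag)
        if size <= 0:
            continue
        label = -(-size // bin_width) * bin_width  # ceil to the bin's upper edge
        counts[label] = counts.get(label, 0) + 1
    return SizeHistogram(bin_width, dict(sorted(counts.items())))
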