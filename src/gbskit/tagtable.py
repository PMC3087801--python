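"""Reference tag sets and the tags-by-samples count table.

Tag discovery is a two-pass procedure.  The first pass collects tags
from reads whose minimum quality over the first 72 bases is at least 10
and keeps those seen at least twice across all samples (random
sequencing errors should not recur); the expected tags of an in-silico
digest of a reference genome can be unioned in.  The second pass counts,
for every sample, reads whose 64-base tag exactly matches a reference
tag — regardless of quality this time — yielding an integer count table.
Tags are then screened by how many samples they occur in, and the table
can be collapsed to presence/absence, which is how tags are treated as
dominant markers downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .reads import ACCEPTED, ClassifiedRead
from .tags import Tag

OBSERVED = "observed"
IN_SILICO = "in_silico"
BOTH = "both"


@dataclass(frozen=True)
class ReferenceTagSet:
    """64-base reference tags with per-tag provenance."""

    provenance: dict[str, str]  # tag sequence -> observed | in_silico | both

    @property
    def sequences(self) -> set[str]:
        return set(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def __contains__(self, tag: str | Tag) -> bool:
        return str(tag) in self.provenance

    def to_frame(self) -> pd.DataFrame:
        return (pd.DataFrame({"provenance": pd.Series(self.provenance)})
                .rename_axis("tag").sort_index())


def _accepted(reads: Iterable[ClassifiedRead]) -> Iterable[ClassifiedRead]:
    return (r for r in reads if r.status == ACCEPTED)


def build_reference_tags(samples: Mapping[str, Iterable[ClassifiedRead]],
                         min_q: int = 10,
                         min_count: int = 2,
                         in_silico: Iterable[Tag | str] | None = None,
                         ) -> ReferenceTagSet:
    """First pass: assemble the reference tag set.

    A tag qualifies if it is carried by reads with ``min_q72 >= min_q``
    occurring at least ``min_count`` times in total across all samples.
    ``in_silico`` tags (from a reference-genome digest) are unioned in
    unconditionally.
    """
    counts: Counter[str] = Counter()
    for reads in samples.values():
        for r in _accepted(reads):
            if r.min_q72 >= min_q:
                counts[r.tag.sequence] += 1
    prov = {seq: OBSERVED for seq, c in counts.items() if c >= min_count}
    for t in in_silico or ():
        seq = str(t)
        prov[seq] = BOTH if prov.get(seq) == OBSERVED else IN_SILICO
    return ReferenceTagSet(prov)


def count_tags_second_pass(samples: Mapping[str, Iterable[ClassifiedRead]],
                           reference: ReferenceTagSet) -> pd.DataFrame:
    """Second pass: exact-match counts of reference tags per sample.

    Quality is ignored here by design: a low-quality read that perfectly
    matches a reference tag still counts.  Returns a tags x samples
    DataFrame of non-negative integers covering every reference tag.
    """
    ref = reference.sequences
    data = {}
    for sample, reads in samples.items():
        c: Counter[str] = Counter()
        for r in _accepted(reads):
            seq = r.tag.sequence
            if seq in ref:
                c[seq] += 1
        data[sample] = c
    table = pd.DataFrame(data, index=sorted(ref), dtype=float).fillna(0).astype(int)
    table.index.name = "tag"
    return table


def filter_by_sample_presence(table: pd.DataFrame, min_samples: int,
                              mode: str = "maize") -> pd.DataFrame:
    """Drop tags occurring in too few samples.

    ``mode='maize'`` keeps tags occurring in strictly more than
    ``min_samples`` samples ("10 or fewer" are removed); ``mode='barley'``
    keeps tags present in at least ``min_samples`` lines ("five or more").
    """
    n_present = (table > 0).sum(axis=1)
    if mode == "maize":
        keep = n_present > min_samples
    elif mode == "barley":
        keep = n_present >= min_samples
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return table.loc[keep]


def to_presence_absence(table: pd.DataFrame, min_reads: int = 1) -> pd.DataFrame:
    """Binary view of the count table: present iff count >= ``min_reads``."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return table >= min_reads


def write_table(table: pd.DataFrame, path,
                reference: ReferenceTagSet | None = None) -> None:
    out = table.copy()
    if reference is not None:
        out.insert(0, "provenance",
                   [reference.provenance.get(t, "") for t in out.index])
    out.to_csv(path, sep="\t")


def read_table(path) -> tuple[pd.DataFrame, pd.Series | None]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    prov = None
    if "provenance" in df.columns:
        prov = df.pop("provenance")
    return df.astype(int), prov
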