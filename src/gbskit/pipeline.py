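"""End-to-end orchestration: reads -> tags -> table -> genetic map.

This ties the stages together the way a genotyping run uses them:
demultiplex and filter raw reads, build the reference tag set (optionally
unioned with an in-silico digest of a reference genome), fill the
tags-by-samples count table in a second exact-match pass, screen tags by
sample occurrence, and map the surviving presence/absence markers by
binomial co-segregation.  When a reference genome is supplied, tags are
anchored to unique physical positions by exact 64-mer lookup against its
expected-tag table, enabling directed tests and biallelic merging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .digest import expected_tags_from_reference, tag_position_table
from .enzyme import APEKI, RestrictionEnzyme
from .mapping import (FrameworkMap, MappingThresholds, TagMapping,
                      map_tags_barley, map_tags_maize)
from .reads import ACCEPTED, DemuxResult, RawRead, demultiplex
from .tagtable import (ReferenceTagSet, build_reference_tags,
                       count_tags_second_pass, filter_by_sample_presence,
                       to_presence_absence)

#: sample-occurrence screens as printed for the two study populations:
#: maize drops tags in 10 or fewer samples, barley keeps tags in >= 5 lines
PRESENCE_RULES = {"maize": 10, "barley": 5}


@dataclass
class PipelineResult:
    demux: DemuxResult
    reference: ReferenceTagSet
    table: pd.DataFrame
    presence: pd.DataFrame
    positions: pd.DataFrame | None
    mappings: dict[str, TagMapping | None]

    @property
    def mapped(self) -> dict[str, TagMapping]:
        return {t: m for t, m in self.mappings.items() if m is not None}


def run_pipeline(reads: Iterable[RawRead], key: Mapping[str, str],
                 framework: FrameworkMap,
                 reference_genome: Mapping[str, str] | None = None,
                 mode: str = "maize",
                 thresholds: MappingThresholds = MappingThresholds(),
                 min_q: int = 10, min_count: int = 2,
                 min_samples: int | None = None,
                 positions: pd.DataFrame | None = None,
                 enzyme: RestrictionEnzyme = APEKI,
                 exclude_lines: Iterable[str] = (),
                 ) -> PipelineResult:
    """Run the full pipeline on one lane of reads.

    ``mode`` selects both the sample-occurrence rule (strictly more than
    ``min_samples`` for maize, at least ``min_samples`` for barley) and
    the mapping regime.  ``exclude_lines`` drops samples from the
    mapping stage only (for cross-validation), keeping their counts in
    the table.
    """
    if mode not in PRESENCE_RULES:
        raise ValueError(f"mode must be one of {sorted(PRESENCE_RULES)}")
    if min_samples is None:
        min_samples = PRESENCE_RULES[mode]

    demux = demultiplex(reads, key, enzyme)
    in_silico = None
    if reference_genome is not None:
        in_silico = expected_tags_from_reference(reference_genome, enzyme)
        if positions is None:
            positions = tag_position_table(reference_genome, enzyme)
    reference = build_reference_tags(demux.by_sample, min_q=min_q,
                                     min_count=min_count, in_silico=in_silico)
    table = count_tags_second_pass(demux.by_sample, reference)
    table = filter_by_sample_presence(table, min_samples, mode=mode)
    presence = to_presence_absence(table)

    map_presence = presence.drop(columns=list(exclude_lines), errors="ignore")
    if mode == "maize":
        mappings = map_tags_maize(map_presence, framework, thresholds, positions)
    else:
        mappings = map_tags_barley(map_presence, framework, thresholds)
    return PipelineResult(demux, reference, table, presence, positions, mappings)


@dataclass(frozen=True)
class RecoveryReport:
    """Agreement between a pipeline run and simulator ground truth."""

    n_truth: int
    n_mapped: int
    n_parent_correct: int
    dimer_reads: int
    dimer_accepted: int

    @property
    def sensitivity(self) -> float:
        return self.n_mapped / self.n_truth if self.n_truth else float("nan")

    @property
    def parent_accuracy(self) -> float:
        return self.n_parent_correct / self.n_mapped if self.n_mapped else float("nan")


def evaluate_against_truth(result: PipelineResult, labels, truth,
                           min_lines: int = 10) -> RecoveryReport:
    """Score a run against :class:`~gbskit.simulate.SimTruth`.

    The truth set comprises segregating tags expected in at least
    ``min_lines`` lines (the binomial test's minimum sample size).
    ``labels`` are the per-read truth labels aligned with the read
    stream given to :func:`run_pipeline`.
    """
    expected_counts = truth.presence.sum(axis=1)
    truth_tags = [t for t in truth.segregating if expected_counts[t] >= min_lines]
    mapped = result.mapped
    n_mapped = sum(1 for t in truth_tags if t in mapped)
    n_correct = sum(1 for t in truth_tags
                    if t in mapped and mapped[t].parent == truth.tags.loc[t, "source"])
    dimer_reads = sum(1 for lab in labels if lab.kind == "dimer")
    dimer_accepted = sum(1 for lab, status in zip(labels, result.demux.statuses)
                         if lab.kind == "dimer" and status == ACCEPTED)
    return RecoveryReport(len(truth_tags), n_mapped, n_correct,
                          dimer_reads, dimer_accepted)
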