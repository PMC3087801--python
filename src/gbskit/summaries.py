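"""Small read-accounting and coverage arithmetic used in run reports."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .tags import TAG_LENGTH


def megabases_covered(n_tags: int, tag_length: int = TAG_LENGTH) -> float:
    """Genome span of a set of fixed-length tags, in Mbp."""
    return n_tags * tag_length / 1e6


def genome_fraction(n_tags: int, genome_size_bp: float,
                    tag_length: int = TAG_LENGTH) -> float:
    """Fraction of a genome covered by the tags."""
    return n_tags * tag_length / genome_size_bp


def reads_per_unit(total_reads: int, n_units: int) -> int:
    """Average reads per lane/sample, rounded to the nearest read."""
    if n_units <= 0:
        raise ValueError("need at least one unit")
    return round(total_reads / n_units)


def percent(part: float, whole: float, digits: int = 0) -> float:
    """``part / whole`` as a percentage, rounded to ``digits`` places."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return round(100.0 * part / whole, digits) if digits else round(100.0 * part / whole)


def coefficient_of_variation(counts: Iterable[float]) -> float:
    """Population standard deviation over mean of per-sample read counts."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0 or arr.mean() == 0:
        return float("nan")
    return float(arr.std() / arr.mean())
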