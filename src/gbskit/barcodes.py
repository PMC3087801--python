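"""Design and validation of variable-length inline barcodes.

Barcodes sit between the sequencing primer and the ApeKI cut-site
remnant, so the first bases of every read are barcode + CWGC.  To keep
demultiplexing robust against sequencing and oligo-synthesis errors, and
to keep early sequencing cycles base-diverse (the instrument's phasing
model needs variable bases in the first twelve cycles), a usable set
obeys:

* lengths between 4 and 8 bases;
* every pair at least ``min_distance`` mutational steps apart
  (Levenshtein distance: substitutions and indels both count, since
  barcode lengths differ);
* no mononucleotide run of 3+ within barcodes longer than 5 bases;
* no barcode containing another barcode of the set as a substring
  (otherwise a prefix read is ambiguous between samples);
* no barcode containing the enzyme recognition site, or regenerating
  one at the junction with the CWGC remnant;
* base composition per position kept as close to uniform as the search
  allows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np

from .enzyme import APEKI, RestrictionEnzyme

MIN_LENGTH = 4
MAX_LENGTH = 8
_DNA = set("ACGT")


def _check_dna(seq: str, what: str = "barcode") -> str:
    seq = seq.upper()
    if not seq or set(seq) - _DNA:
        raise ValueError(f"invalid {what}: {seq!r} (A/C/G/T only)")
    return seq


@dataclass(frozen=True, slots=True)
class Barcode:
    """A single inline barcode, 4-8 bases of A/C/G/T."""

    sequence: str

    def __post_init__(self) -> None:
        seq = _check_dna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
            raise ValueError(f"barcode length must be in [{MIN_LENGTH}, {MAX_LENGTH}]")

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def pairwise_distance(a: str | Barcode, b: str | Barcode) -> int:
    """Mutational steps between two barcodes (Levenshtein distance).

    Substitutions, insertions and deletions each count one step; the
    result is symmetric and zero iff the sequences are identical.
    """
    a = _check_dna(str(a))
    b = _check_dna(str(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _has_run(seq: str, length: int = 3) -> bool:
    run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run >= length:
            return True
    return length <= 1


@dataclass(frozen=True, slots=True)
class Violation:
    kind: str  # invalid | duplicate | distance | run | containment | enzyme_site
    barcodes: tuple[str, ...]
    detail: str

    def __str__(self) -> str:
        return f"{self.kind}: {', '.join(self.barcodes)} ({self.detail})"


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def by_kind(self, kind: str) -> list[Violation]:
        return [v for v in self.violations if v.kind == kind]

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self) -> Iterator[Violation]:
        return iter(self.violations)


@dataclass(frozen=True)
class BarcodeSet:
    """An ordered collection of barcodes with a pairwise-distance floor."""

    barcodes: tuple[str, ...]
    min_distance: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcodes",
                           tuple(_check_dna(str(b)) for b in self.barcodes))

    def __iter__(self) -> Iterator[str]:
        return iter(self.barcodes)

    def __len__(self) -> int:
        return len(self.barcodes)

    def lengths(self) -> set[int]:
        return {len(b) for b in self.barcodes}

    def validate(self, enzyme: RestrictionEnzyme = APEKI) -> ValidationReport:
        return validate_barcode_set(self, enzyme)


def _single_barcode_violations(bc: str, enzyme: RestrictionEnzyme) -> list[Violation]:
    out = []
    if not MIN_LENGTH <= len(bc) <= MAX_LENGTH:
        out.append(Violation("invalid", (bc,),
                             f"length {len(bc)} outside [{MIN_LENGTH}, {MAX_LENGTH}]"))
    if len(bc) > 5 and _has_run(bc):
        out.append(Violation("run", (bc,), "mononucleotide run of 3+ in a >5-base barcode"))
    # The recognition site must neither occur inside the barcode nor be
    # regenerated when the barcode is followed by the cut-site remnant:
    # such a read prefix would mimic an internal cut.
    for remnant in enzyme.remnant_seqs():
        if enzyme.occurs_in(bc + remnant):
            out.append(Violation("enzyme_site", (bc,),
                                 f"creates {enzyme.recognition} within {bc}+{remnant}"))
            break
    return out


def validate_barcode_set(bcset: BarcodeSet | Sequence[str],
                         enzyme: RestrictionEnzyme = APEKI) -> ValidationReport:
    """Report every constraint violation in a barcode set.

    An empty report means the set is valid.  Violations are report
    entries, never exceptions.
    """
    if not isinstance(bcset, BarcodeSet):
        bcset = BarcodeSet(tuple(bcset))
    if len(bcset) == 0:
        raise ValueError("barcode set is empty")
    seqs = list(bcset)
    out: list[Violation] = []
    seen: set[str] = set()
    for bc in seqs:
        if bc in seen:
            out.append(Violation("duplicate", (bc,), "appears more than once"))
        seen.add(bc)
        out.extend(_single_barcode_violations(bc, enzyme))
    for a, b in itertools.combinations(sorted(set(seqs)), 2):
        d = pairwise_distance(a, b)
        if d < bcset.min_distance:
            out.append(Violation("distance", (a, b),
                                 f"distance {d} < {bcset.min_distance}"))
        if a in b or b in a:
            short, long_ = (a, b) if len(a) <= len(b) else (b, a)
            out.append(Violation("containment", (short, long_),
                                 f"{short} is a substring of {long_}"))
    return ValidationReport(tuple(out))


@dataclass(frozen=True)
class BalanceReport:
    """Per-position base composition of a barcode set.

    ``per_position_counts[i]`` maps base -> count at 1-based position
    ``i + 1``, over the barcodes long enough to have that position.
    ``worst_position_skew`` is ``max_p (max_b fraction(b at p) - 0.25)``.
    """

    per_position_counts: tuple[dict[str, int], ...]
    worst_position_skew: float


def base_balance(bcset: BarcodeSet | Sequence[str]) -> BalanceReport:
    seqs = [str(b) for b in bcset]
    if not seqs:
        raise ValueError("barcode set is empty")
    maxlen = max(len(s) for s in seqs)
    counts = []
    worst = 0.0
    for pos in range(maxlen):
        c = {b: 0 for b in "ACGT"}
        for s in seqs:
            if len(s) > pos:
                c[s[pos]] += 1
        total = sum(c.values())
        worst = max(worst, max(c.values()) / total - 0.25)
        counts.append(c)
    return BalanceReport(tuple(counts), worst)


class SearchExhaustedError(RuntimeError):
    """Raised when no constraint-satisfying barcode set of the requested size exists."""


def _candidate_pool(lengths: Iterable[int], enzyme: RestrictionEnzyme) -> dict[int, list[str]]:
    pools: dict[int, list[str]] = {}
    for L in sorted(set(lengths)):
        if not MIN_LENGTH <= L <= MAX_LENGTH:
            raise ValueError(f"barcode length {L} outside [{MIN_LENGTH}, {MAX_LENGTH}]")
        pool = []
        for tup in itertools.product("ACGT", repeat=L):
            bc = "".join(tup)
            if not _single_barcode_violations(bc, enzyme):
                pool.append(bc)
        pools[L] = pool
    return pools


def _compatible(cand: str, accepted: list[str], min_distance: int) -> bool:
    for acc in accepted:
        if cand in acc or acc in cand:
            return False
        k = edlib.align(cand, acc, mode="NW", task="distance",
                        k=min_distance - 1)["editDistance"]
        if k != -1:  # distance below the floor
            return False
    return True


def _worst_skew_with(counts: np.ndarray, totals: np.ndarray, cand: str) -> float:
    # counts: (maxlen, 4) running composition; totals: per-position totals
    c = counts.copy()
    t = totals.copy()
    for i, ch in enumerate(cand):
        c[i, "ACGT".index(ch)] += 1
        t[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(t[:, None] > 0, c / np.maximum(t[:, None], 1), 0.25)
    return float((frac.max(axis=1) - 0.25).max())


def generate_barcode_set(n_target: int,
                         lengths: Iterable[int] = range(MIN_LENGTH, MAX_LENGTH + 1),
                         min_distance: int = 3,
                         enzyme: RestrictionEnzyme = APEKI,
                         seed: int = 0,
                         tournament: int = 16,
                         max_restarts: int = 5) -> BarcodeSet:
    """Seeded greedy randomized search for a valid barcode set.

    Candidates of each requested length are pooled (pre-filtered for the
    run and enzyme-site rules), shuffled, and visited round-robin across
    lengths so the output mixes lengths over the whole requested range.
    At each step up to ``tournament`` constraint-compatible candidates
    are examined and the one that keeps per-position base composition
    most balanced is accepted.  Deterministic for a given seed; raises
    :class:`SearchExhaustedError` if ``n_target`` is unreachable.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    lengths = sorted(set(lengths))
    pools = _candidate_pool(lengths, enzyme)

    for restart in range(max_restarts):
        rng = np.random.default_rng((seed + 7919 * restart) % 2**31)
        shuffled = {L: [pool[i] for i in rng.permutation(len(pool))]
                    for L, pool in pools.items()}
        # Round-robin interleave of the per-length streams.
        stream: list[str] = []
        for group in itertools.zip_longest(*(shuffled[L] for L in lengths)):
            stream.extend(bc for bc in group if bc is not None)

        accepted: list[str] = []
        maxlen = max(lengths)
        counts = np.zeros((maxlen, 4), dtype=int)
        totals = np.zeros(maxlen, dtype=int)
        it = iter(stream)
        exhausted = False
        while len(accepted) < n_target and not exhausted:
            batch: list[str] = []
            while len(batch) < tournament:
                cand = next(it, None)
                if cand is None:
                    exhausted = True
                    break
                if _compatible(cand, accepted, min_distance):
                    batch.append(cand)
            if not batch:
                break
            best = min(batch, key=lambda c: _worst_skew_with(counts, totals, c))
            accepted.append(best)
            for i, ch in enumerate(best):
                counts[i, "ACGT".index(ch)] += 1
                totals[i] += 1
        if len(accepted) >= n_target:
            result = BarcodeSet(tuple(accepted), min_distance=min_distance)
            if set(lengths) <= result.lengths() or restart == max_restarts - 1:
                return result
            continue  # did not span the length range; retry with a fresh shuffle
    raise SearchExhaustedError(
        f"could not assemble {n_target} barcodes from lengths {lengths} "
        f"at min_distance {min_distance}")
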