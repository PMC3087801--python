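"""Genetic mapping of sequence tags by binomial co-segregation.

A tag, scored present/absent across a biparental population, is tested
against each SNP of an independent framework map.  For a presumed
parental source, a success is a line in which the tag co-occurs with
that parent's SNP allele.  The binomial sample size ``n`` is the number
of lines where the tag is present and the SNP call is neither missing
nor heterozygous; the success probability is the proportion of
informative lines carrying the tested allele; the p-value is the exact
upper tail P(X >= successes).  Co-segregation is a one-sided
excess-of-success alternative, hence the upper tail.

Two decision regimes are supported.  The maize-style regime runs a
directed test against the physically closest SNP at p < 0.001 (sample
size at least 10) and otherwise scans the whole map at p < 0.0001.  The
barley-style regime is stricter: a tag maps only if it always co-occurs
with one allele and never the other, with binomial p < 0.0001.

Pairs of tags anchored to exactly the same physical position and strand
that each pass the directed test are merged into biallelic markers,
re-tested with Fisher's exact test (p < 0.001), and can be incorporated
into a high-density framework against which remaining dominant tags are
re-mapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PARENT_A = "A"
PARENT_B = "B"
HET = "H"
MISSING = "-"
CALL_VALUES = (PARENT_A, PARENT_B, HET, MISSING)


class UndefinedTestError(ValueError):
    """A test whose sampling distribution is empty (n = 0 or an all-zero table)."""


@dataclass(frozen=True)
class MappingThresholds:
    p_directed: float = 1e-3
    p_global: float = 1e-4
    min_n: int = 10
    barley_p: float = 1e-4

    def __post_init__(self) -> None:
        for p in (self.p_directed, self.p_global, self.barley_p):
            if not 0 < p < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.min_n < 1:
            raise ValueError("min_n must be >= 1")


@dataclass(frozen=True)
class FrameworkMap:
    """An independent set of mapped SNPs with per-line genotype calls.

    ``markers``: DataFrame indexed by marker id with columns ``chrom``,
    ``cm`` and optional ``bp``; sorted within chromosome.  ``calls``:
    DataFrame (markers x lines) over {'A', 'B', 'H', '-'} where A/B are
    the two parental alleles.
    """

    markers: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        markers = self.markers.copy()
        if "bp" not in markers.columns:
            markers["bp"] = np.nan
        markers = markers.sort_values(["chrom", "cm", "bp"], kind="stable")
        calls = self.calls.reindex(markers.index)
        bad = set(np.unique(calls.values.astype(str))) - set(CALL_VALUES)
        if bad:
            raise ValueError(f"invalid genotype calls: {sorted(bad)}")
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "calls", calls)

    @property
    def lines(self) -> list[str]:
        return list(self.calls.columns)

    def __len__(self) -> int:
        return len(self.markers)

    def closest_marker(self, chrom: str, bp: float) -> str | None:
        """Marker id physically closest to ``bp`` on ``chrom`` (None if no
        marker on that chromosome has a physical position)."""
        sub = self.markers[(self.markers["chrom"] == chrom)
                           & self.markers["bp"].notna()]
        if sub.empty:
            return None
        return (sub["bp"] - bp).abs().idxmin()

    def to_tsv(self, path) -> None:
        out = self.markers.join(self.calls)
        out.rename_axis("marker_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FrameworkMap":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
        meta_cols = [c for c in ("chrom", "cm", "bp") if c in df.columns]
        markers = df[meta_cols]
        calls = df.drop(columns=meta_cols).astype(str)
        return cls(markers, calls)


@dataclass(frozen=True)
class SegregationResult:
    tag: str
    marker: str
    presumed_parent: str
    n: int
    successes: int
    p_success: float
    p_value: float


@dataclass(frozen=True)
class TagMapping:
    tag: str
    marker: str
    parent: str
    n: int
    successes: int
    p_value: float
    mode: str  # directed | global | barley
    chrom: str
    cm: float


def binomial_tail(successes: int, n: int, p_success: float) -> float:
    """Exact upper-tail binomial probability P(X >= successes)."""
    if n == 0:
        raise UndefinedTestError("binomial test undefined for n = 0")
    return float(stats.binom.sf(successes - 1, n, p_success))


def binomial_cosegregation_test(tag_presence: pd.Series,
                                marker_calls: pd.Series,
                                presumed_parent: str,
                                tag: str = "tag", marker: str = "marker",
                                ) -> SegregationResult:
    """Test co-segregation of one tag with one framework SNP.

    ``tag_presence`` (bool) and ``marker_calls`` ({'A','B','H','-'}) must
    share the same line index.  Raises :class:`UndefinedTestError` when
    no line is both tag-positive and informative (this is a signal, not
    a p-value of 1).
    """
    if presumed_parent not in (PARENT_A, PARENT_B):
        raise ValueError("presumed_parent must be 'A' or 'B'")
    calls = marker_calls.reindex(tag_presence.index)
    informative = calls.isin([PARENT_A, PARENT_B])
    n = int((tag_presence & informative).sum())
    if n == 0:
        raise UndefinedTestError(f"no informative tag-positive lines for {tag}/{marker}")
    successes = int((tag_presence & (calls == presumed_parent)).sum())
    p_success = float((calls[informative] == presumed_parent).mean())
    return SegregationResult(tag, marker, presumed_parent, n, successes,
                             p_success, binomial_tail(successes, n, p_success))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Uses the minimum-likelihood convention: the sum of probabilities of
    all tables (at fixed margins) no more likely than the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    if a + b + c + d == 0:
        raise UndefinedTestError("Fisher test undefined for an all-zero table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


class SegregationScanner:
    """Vectorized binomial co-segregation of many tags against a framework map."""

    def __init__(self, framework: FrameworkMap, lines: Sequence[str]) -> None:
        missing = set(lines) - set(framework.lines)
        if missing:
            raise ValueError(f"lines absent from framework map: {sorted(missing)}")
        self.framework = framework
        self.lines = list(lines)
        calls = framework.calls[self.lines].values.astype(str)
        self._inf = np.isin(calls, [PARENT_A, PARENT_B])
        self._allele = {PARENT_A: (calls == PARENT_A) & self._inf,
                        PARENT_B: (calls == PARENT_B) & self._inf}
        inf_tot = self._inf.sum(axis=1)
        with np.errstate(invalid="ignore"):
            self.p_success = {p: np.where(inf_tot > 0,
                                          self._allele[p].sum(axis=1) / np.maximum(inf_tot, 1),
                                          np.nan)
                              for p in (PARENT_A, PARENT_B)}

    def scan(self, presence: pd.DataFrame) -> dict[str, dict[str, np.ndarray]]:
        """For each parent: matrices (tags x markers) of n, successes, p-value.

        Entries with n = 0 carry a NaN p-value (undefined test).
        """
        P = presence[self.lines].values.astype(np.int64)
        out: dict[str, dict[str, np.ndarray]] = {}
        n = P @ self._inf.T.astype(np.int64)
        for parent in (PARENT_A, PARENT_B):
            succ = P @ self._allele[parent].T.astype(np.int64)
            with np.errstate(invalid="ignore"):
                pval = stats.binom.sf(succ - 1, n, self.p_success[parent][None, :])
            pval = np.where(n > 0, pval, np.nan)
            out[parent] = {"n": n, "successes": succ, "p_value": pval}
        return out


def _best_entry(entries: list[tuple[float, int, int, str]]) -> tuple | None:
    # (p, n, marker_order, parent): smallest p, then largest n, then map order
    if not entries:
        return None
    return min(entries, key=lambda e: (e[0], -e[1], e[2], e[3]))


def map_tags_maize(presence: pd.DataFrame, framework: FrameworkMap,
                   thresholds: MappingThresholds = MappingThresholds(),
                   positions: pd.DataFrame | None = None,
                   ) -> dict[str, TagMapping | None]:
    """Map each tag of a presence matrix under the maize decision regime.

    ``positions``, when given, is indexed by tag sequence with columns
    ``source`` (chromosome) and ``position`` (bp); tags with a unique
    physical position get a directed test against the physically closest
    SNP at ``p_directed``; all tags fall back to a global scan of every
    marker and both parents at ``p_global``.  Tests with fewer than
    ``min_n`` informative tag-positive lines are skipped.
    """
    scanner = SegregationScanner(framework, list(presence.columns))
    scanned = scanner.scan(presence)
    marker_ids = list(framework.markers.index)
    marker_pos = {m: i for i, m in enumerate(marker_ids)}
    results: dict[str, TagMapping | None] = {}

    directed_marker: dict[str, str | None] = {}
    if positions is not None:
        for tag in presence.index:
            if tag in positions.index:
                row = positions.loc[tag]
                directed_marker[tag] = framework.closest_marker(
                    str(row["source"]), float(row["position"]))

    def entry(i: int, j: int, parent: str) -> tuple[float, int, int, str] | None:
        d = scanned[parent]
        n = int(d["n"][i, j])
        p = d["p_value"][i, j]
        if n < thresholds.min_n or not np.isfinite(p):
            return None
        return (float(p), n, j, parent)

    for i, tag in enumerate(presence.index):
        mapping = None
        j_directed = None
        target = directed_marker.get(tag)
        if target is not None:
            j_directed = marker_pos[target]
            cands = [e for pa in (PARENT_A, PARENT_B)
                     if (e := entry(i, j_directed, pa)) is not None
                     and e[0] < thresholds.p_directed]
            best = _best_entry(cands)
            if best is not None:
                mapping = _to_mapping(tag, best, framework, marker_ids,
                                      scanned, i, "directed")
        if mapping is None:
            cands = [e for j in range(len(marker_ids))
                     for pa in (PARENT_A, PARENT_B)
                     if (e := entry(i, j, pa)) is not None
                     and e[0] < thresholds.p_global]
            best = _best_entry(cands)
            if best is not None:
                mapping = _to_mapping(tag, best, framework, marker_ids,
                                      scanned, i, "global")
        results[tag] = mapping
    return results


def _to_mapping(tag: str, best: tuple, framework: FrameworkMap,
                marker_ids: list[str], scanned: dict, i: int,
                mode: str) -> TagMapping:
    p, n, j, parent = best
    marker = marker_ids[j]
    meta = framework.markers.loc[marker]
    return TagMapping(tag, marker, parent, n,
                      int(scanned[parent]["successes"][i, j]), p, mode,
                      str(meta["chrom"]), float(meta["cm"]))


def map_tags_barley(presence: pd.DataFrame, framework: FrameworkMap,
                    thresholds: MappingThresholds = MappingThresholds(),
                    ) -> dict[str, TagMapping | None]:
    """Map tags under the strict barley rule.

    A tag maps only where it always co-occurs with one parental allele
    and never the other (successes = n, i.e. zero co-occurrences with
    the alternative) and the binomial p-value beats ``barley_p``.
    """
    scanner = SegregationScanner(framework, list(presence.columns))
    scanned = scanner.scan(presence)
    marker_ids = list(framework.markers.index)
    results: dict[str, TagMapping | None] = {}
    for i, tag in enumerate(presence.index):
        cands = []
        for j in range(len(marker_ids)):
            for parent in (PARENT_A, PARENT_B):
                d = scanned[parent]
                n = int(d["n"][i, j])
                p = d["p_value"][i, j]
                if (n > 0 and np.isfinite(p)
                        and int(d["successes"][i, j]) == n
                        and p < thresholds.barley_p):
                    cands.append((float(p), n, j, parent))
        best = _best_entry(cands)
        results[tag] = (None if best is None else
                        _to_mapping(tag, best, framework, marker_ids,
                                    scanned, i, "barley"))
    return results


def map_tag_maize(tag: str, presence: pd.Series, framework: FrameworkMap,
                  thresholds: MappingThresholds = MappingThresholds(),
                  position: tuple[str, float] | None = None) -> TagMapping | None:
    """Single-tag convenience wrapper around :func:`map_tags_maize`."""
    df = presence.to_frame(tag).T.astype(bool)
    pos = None
    if position is not None:
        pos = pd.DataFrame({"source": [position[0]], "position": [position[1]]},
                           index=[tag])
    return map_tags_maize(df, framework, thresholds, pos)[tag]


def map_tag_barley(tag: str, presence: pd.Series, framework: FrameworkMap,
                   thresholds: MappingThresholds = MappingThresholds(),
                   ) -> TagMapping | None:
    df = presence.to_frame(tag).T.astype(bool)
    return map_tags_barley(df, framework, thresholds)[tag]


@dataclass(frozen=True)
class BiallelicMarker:
    """Two allelic tags at the same physical position and strand."""

    tag_a: str  # allele inherited from parent A
    tag_b: str
    chrom: str
    position: int
    strand: str
    anchor_marker: str
    cm: float
    fisher_p: float

    @property
    def marker_id(self) -> str:
        return f"bi:{self.chrom}:{self.position}:{self.strand}"


def merge_biallelic(positions: pd.DataFrame, presence: pd.DataFrame,
                    framework: FrameworkMap,
                    thresholds: MappingThresholds = MappingThresholds(),
                    ) -> list[BiallelicMarker]:
    """Merge tag pairs sharing a physical position into biallelic markers.

    ``positions`` is indexed by tag sequence with columns ``source``,
    ``position``, ``strand`` (unique anchors only).  Each tag of a pair
    must individually pass the directed binomial test against the
    physically closest SNP (p < ``p_directed``); the pair must then pass
    Fisher's exact test of tag-A presence versus that SNP's alleles at
    p < 0.001.  Positions carrying more than two tags are skipped and
    logged.  Output is ordered by genomic position.
    """
    positions = positions.loc[positions.index.intersection(presence.index)]
    out: list[BiallelicMarker] = []
    for (chrom, pos, strand), group in positions.groupby(
            ["source", "position", "strand"], sort=True):
        tags = list(group.index)
        if len(tags) < 2:
            continue
        if len(tags) > 2:
            logger.warning("position %s:%s%s carries %d tags; skipped",
                           chrom, pos, strand, len(tags))
            continue
        if tags[0] == tags[1]:
            continue  # duplicates are not two alleles
        marker = framework.closest_marker(str(chrom), float(pos))
        if marker is None:
            continue
        maps = {}
        ok = True
        for t in tags:
            m = map_tag_maize(t, presence.loc[t], framework,
                              replace(thresholds, p_global=np.nextafter(0, 1)),
                              position=(str(chrom), float(pos)))
            if m is None or m.mode != "directed":
                ok = False
                break
            maps[t] = m
        if not ok:
            continue
        parents = {maps[t].parent for t in tags}
        if parents != {PARENT_A, PARENT_B}:
            continue  # both tags favour the same parent: not an allele pair
        tag_a = next(t for t in tags if maps[t].parent == PARENT_A)
        tag_b = next(t for t in tags if maps[t].parent == PARENT_B)
        calls = framework.calls.loc[marker, presence.columns]
        informative = calls.isin([PARENT_A, PARENT_B])
        pa = presence.loc[tag_a, presence.columns].astype(bool)
        a = int((pa & (calls == PARENT_A)).sum())
        b = int((pa & (calls == PARENT_B)).sum())
        c = int((~pa & informative & (calls == PARENT_A)).sum())
        d = int((~pa & informative & (calls == PARENT_B)).sum())
        try:
            fp = fisher_exact_2x2(a, b, c, d)
        except UndefinedTestError:
            continue
        if fp >= 1e-3:
            continue
        cm = float(framework.markers.loc[marker, "cm"])
        out.append(BiallelicMarker(tag_a, tag_b, str(chrom), int(pos), strand,
                                   marker, cm, fp))
    out.sort(key=lambda m: (m.chrom, m.position, m.strand))
    return out


def high_density_map(framework: FrameworkMap, markers: Iterable[BiallelicMarker],
                     presence: pd.DataFrame) -> FrameworkMap:
    """Incorporate biallelic GBS markers into the framework map.

    A line's call at a biallelic marker is 'A' when only the parent-A
    tag is present, 'B' when only the parent-B tag is, 'H' when both are
    seen and '-' when neither is.
    """
    lines = list(framework.calls.columns)
    meta_rows, call_rows, ids = [], [], []
    for m in markers:
        pa = presence.loc[m.tag_a].reindex(lines).fillna(False).astype(bool)
        pb = presence.loc[m.tag_b].reindex(lines).fillna(False).astype(bool)
        calls = np.where(pa & ~pb, PARENT_A,
                         np.where(pb & ~pa, PARENT_B,
                                  np.where(pa & pb, HET, MISSING)))
        ids.append(m.marker_id)
        meta_rows.append({"chrom": m.chrom, "cm": m.cm, "bp": m.position})
        call_rows.append(calls)
    if not ids:
        return framework
    new_markers = pd.concat([framework.markers,
                             pd.DataFrame(meta_rows, index=ids)])
    new_calls = pd.concat([framework.calls,
                           pd.DataFrame(call_rows, index=ids, columns=lines)])
    return FrameworkMap(new_markers, new_calls)


def remap_dominant(presence: pd.DataFrame, hd_framework: FrameworkMap,
                   thresholds: MappingThresholds = MappingThresholds(),
                   ) -> dict[str, TagMapping | None]:
    """Re-run the global binomial scan of unmapped dominant tags against a
    high-density framework map (threshold ``p_global``)."""
    return map_tags_maize(presence, hd_framework, thresholds, positions=None)


@dataclass(frozen=True)
class CrossValidation:
    line: str
    correct: int
    total: int
    excluded: int
    track: pd.DataFrame  # ordered per-chromosome parent-of-origin calls

    @property
    def accuracy(self) -> float:
        return self.correct / self.total if self.total else float("nan")


def cross_validate(line: str, mappings: Mapping[str, TagMapping | None],
                   presence: pd.DataFrame,
                   framework: FrameworkMap) -> CrossValidation:
    """Score parent-of-origin agreement for one held-out line.

    ``mappings`` must come from a mapping run that excluded ``line``;
    ``presence`` and ``framework`` must still contain it.  For every
    mapped tag present in the line, the tag's presumed parent is
    compared with the parent of the chromosome segment at its map
    position, derived from the line's framework genotypes.  Tags falling
    between two framework markers whose calls disagree (i.e. inside a
    recombination breakpoint window) cannot be assigned and are
    excluded from the denominator.
    """
    if line not in presence.columns or line not in framework.calls.columns:
        raise ValueError(f"line {line!r} not present in population")
    calls = framework.calls[line]
    informative = calls.isin([PARENT_A, PARENT_B])
    track = (framework.markers.assign(call=calls)
             .loc[informative, ["chrom", "cm", "call"]]
             .sort_values(["chrom", "cm"], kind="stable"))
    by_chrom = {c: sub for c, sub in track.groupby("chrom")}
    correct = total = excluded = 0
    for tag, mapping in mappings.items():
        if mapping is None or tag not in presence.index:
            continue
        if not bool(presence.loc[tag, line]):
            continue
        sub = by_chrom.get(mapping.chrom)
        if sub is None or sub.empty:
            continue
        left = sub[sub["cm"] <= mapping.cm]
        right = sub[sub["cm"] >= mapping.cm]
        flanks = {str(left.iloc[-1]["call"])} if not left.empty else set()
        if not right.empty:
            flanks.add(str(right.iloc[0]["call"]))
        if not flanks:
            continue
        if len(flanks) > 1:
            excluded += 1
            continue
        total += 1
        if flanks.pop() == mapping.parent:
            correct += 1
    return CrossValidation(line, correct, total, excluded, track)
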