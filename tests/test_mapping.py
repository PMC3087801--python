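import numpy as np
import pandas as pd
import pytest

from gbskit import (FrameworkMap, MappingThresholds, UndefinedTestError,
                    binomial_cosegregation_test, binomial_tail, cross_validate,
                    fisher_exact_2x2, high_density_map, map_tag_barley,
                    map_tag_maize, map_tags_maize, merge_biallelic,
                    remap_dominant)

from ._oracles import binom_tail_enum, fisher_two_sided_enum


def make_framework(calls: dict[str, list[str]], spacing_cm: float = 10.0,
                   chrom: str = "chr1", lines=None):
    ids = list(calls)
    lines = lines or [f"L{i}" for i in range(len(next(iter(calls.values()))))]
    markers = pd.DataFrame({"chrom": chrom,
                            "cm": [i * spacing_cm for i in range(len(ids))],
                            "bp": [int(i * spacing_cm * 1e5) for i in range(len(ids))]},
                           index=ids)
    return FrameworkMap(markers, pd.DataFrame(calls, index=lines).T)


def balanced_calls(n_lines: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    return ["A" if rng.random() < 0.5 else "B" for _ in range(n_lines)]


class TestBinomial:
    @pytest.mark.parametrize("successes,n,p,expected", [
        (10, 10, 0.5, 0.5 ** 10),          # perfect co-segregation
        (5, 10, 0.5, 0.623046875),         # exact sum, indifferent tag
        (12, 12, 0.5, 0.5 ** 12),
        (0, 10, 0.0, 1.0),                 # degenerate allele frequency
        (10, 10, 1.0, 1.0),
    ])
    def test_closed_forms(self, successes, n, p, expected):
        assert binomial_tail(successes, n, p) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_oracle_exhaustively(self):
        for n in range(1, 13):
            for p in (0.25, 0.5, 0.75):
                for k in range(n + 1):
                    assert binomial_tail(k, n, p) == pytest.approx(
                        float(binom_tail_enum(k, n, p)), rel=1e-9, abs=1e-300)

    def test_n_zero_is_a_signal_not_a_pvalue(self):
        with pytest.raises(UndefinedTestError):
            binomial_tail(0, 0, 0.5)
        presence = pd.Series([False] * 4, index=list("wxyz"))
        calls = pd.Series(list("ABAB"), index=list("wxyz"))
        with pytest.raises(UndefinedTestError):
            binomial_cosegregation_test(presence, calls, "A")

    def test_het_and_missing_calls_shrink_n_only(self):
        presence = pd.Series([True] * 6, index=list("uvwxyz"))
        calls = pd.Series(["A", "A", "H", "-", "B", "A"], index=list("uvwxyz"))
        res = binomial_cosegregation_test(presence, calls, "A")
        assert res.n == 4                       # H and - excluded
        assert res.successes == 3
        assert res.p_success == pytest.approx(3 / 4)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((10, 0, 0, 10), 2 / 184756),      # perfect 10v10 split
        ((5, 5, 5, 5), 1.0),
        ((1, 0, 0, 1), 1.0),               # margins of one: no information
    ])
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-9)

    def test_matches_enumeration_oracle(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if a + b + c + d == 0:
                            continue
                        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                            float(fisher_two_sided_enum(a, b, c, d)), rel=1e-9)

    def test_all_zero_table_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            fisher_exact_2x2(0, 0, 0, 0)


class TestMaizeRegime:
    def test_perfect_cosegregation_maps_directed(self):
        calls = balanced_calls(24, seed=1)
        fw = make_framework({"m0": calls, "m1": balanced_calls(24, seed=2)})
        presence = pd.Series([c == "A" for c in calls], index=fw.lines)
        n = int(presence.sum())
        m = map_tag_maize("t", presence, fw, position=("chr1", 10))
        assert m is not None and m.mode == "directed"
        assert m.marker == "m0" and m.parent == "A" and m.n == n
        p_a = calls.count("A") / len(calls)
        assert m.p_value == pytest.approx(p_a ** n, rel=1e-9)

    def test_sample_size_below_ten_is_skipped(self):
        calls = ["A"] * 9 + ["B"] * 15
        fw = make_framework({"m0": calls})
        presence = pd.Series([c == "A" for c in calls], index=fw.lines)
        assert map_tag_maize("t", presence, fw, position=("chr1", 0)) is None

    def test_global_scan_used_without_position(self):
        calls = balanced_calls(30, seed=3)
        fw = make_framework({"m0": balanced_calls(30, seed=4), "m1": calls})
        presence = pd.Series([c == "B" for c in calls], index=fw.lines)
        m = map_tag_maize("t", presence, fw)  # no physical position
        assert m is not None and m.mode == "global"
        assert m.marker == "m1" and m.parent == "B"

    def test_directed_threshold_is_looser_than_global(self):
        # n = 11 at p_success 0.5: p = 4.9e-4 passes 1e-3 but not 1e-4
        calls = ["A"] * 11 + ["B"] * 11
        fw = make_framework({"m0": calls})
        presence = pd.Series([c == "A" for c in calls], index=fw.lines)
        assert map_tag_maize("t", presence, fw, position=("chr1", 0)) is not None
        assert map_tag_maize("t", presence, fw) is None  # global only: fails

    def test_unlinked_tags_rarely_map(self, rng):
        lines = [f"L{i}" for i in range(40)]
        fw = make_framework({f"m{j}": balanced_calls(40, seed=100 + j)
                             for j in range(10)}, lines=lines)
        tags = pd.DataFrame(rng.random((200, 40)) < 0.5,
                            index=[f"t{i}" for i in range(200)], columns=lines)
        mapped = sum(m is not None
                     for m in map_tags_maize(tags, fw).values())
        # 200 tags x 10 markers x 2 parents at 1e-4: expect << 200 hits
        assert mapped <= 3


class TestBarleyRegime:
    @pytest.mark.parametrize("n_concordant,n_discordant,mapped", [
        (14, 0, True),    # always/never rule met, 0.5^14 < 1e-4
        (13, 1, False),   # one discordant line breaks the strict rule
        (12, 0, False),   # all concordant but 0.5^12 > 1e-4
    ])
    def test_strict_always_never_rule(self, n_concordant, n_discordant, mapped):
        half = 14  # allele ratio one half, so p = 0.5^n
        calls = ["A"] * half + ["B"] * half
        present = ([True] * n_concordant + [False] * (half - n_concordant)
                   + [True] * n_discordant + [False] * (half - n_discordant))
        fw = make_framework({"m0": calls})
        presence = pd.Series(present, index=fw.lines)
        result = map_tag_barley("t", presence, fw)
        assert (result is not None) == mapped
        if mapped:
            assert result.parent == "A" and result.n == n_concordant


class TestBiallelic:
    @staticmethod
    def _setup(seed=7, flips=0):
        # 40 lines, allele ratio one half at m0; the allele pair tracks m0
        # except in `flips` lines of each parental class
        calls = ["A"] * 20 + ["B"] * 20
        fw = make_framework({"m0": calls, "m1": balanced_calls(40, seed + 1)})
        pa = pd.Series([c == "A" for c in calls], index=fw.lines)
        for i in range(flips):
            pa.iloc[i] = False        # an A-line showing the B allele
            pa.iloc[20 + i] = True    # and vice versa
        presence = pd.DataFrame([pa, ~pa], index=["tagA", "tagB"]).astype(bool)
        positions = pd.DataFrame({"source": ["chr1", "chr1"],
                                  "position": [500, 500],
                                  "strand": ["+", "+"]},
                                 index=["tagA", "tagB"])
        return fw, presence, positions

    def test_allele_pair_merges_with_tiny_fisher_p(self):
        fw, presence, positions = self._setup()
        merged = merge_biallelic(positions, presence, fw)
        assert len(merged) == 1
        m = merged[0]
        assert {m.tag_a, m.tag_b} == {"tagA", "tagB"}
        assert m.fisher_p < 1e-3 and m.anchor_marker == "m0"
        # 1:1 consistency: each line shows exactly one allele tag
        assert (presence.loc[m.tag_a] ^ presence.loc[m.tag_b]).all()

    def test_pair_with_one_failing_tag_is_not_merged(self, rng):
        fw, presence, positions = self._setup()
        presence.loc["tagB"] = rng.random(presence.shape[1]) < 0.5
        assert merge_biallelic(positions, presence, fw) == []

    def test_crowded_or_duplicate_positions_are_skipped(self):
        fw, presence, positions = self._setup()
        presence.loc["tagC"] = presence.loc["tagA"]
        extra = pd.DataFrame({"source": ["chr1"], "position": [500],
                              "strand": ["+"]}, index=["tagC"])
        assert merge_biallelic(pd.concat([positions, extra]), presence, fw) == []

    def test_remap_dominant_against_high_density_map(self):
        # the allele pair tracks m0 in 18/20 lines per class: strong enough
        # for the directed merge (p = 2.0e-4 < 1e-3) but a dominant tag with
        # the same pattern fails the global scan of the original map
        # (2.0e-4 > 1e-4) — until the biallelic marker joins the framework
        fw, presence, positions = self._setup(seed=9, flips=2)
        merged = merge_biallelic(positions, presence, fw)
        assert len(merged) == 1
        hd = high_density_map(fw, merged, presence)
        assert len(hd) == len(fw) + 1
        dom_presence = presence.loc["tagA"].to_frame("dom").T
        assert remap_dominant(dom_presence, fw)["dom"] is None
        after = remap_dominant(dom_presence, hd)["dom"]
        assert after is not None
        assert after.marker == merged[0].marker_id
        assert after.successes == after.n == 20


class TestCrossValidation:
    @staticmethod
    def _framework():
        calls = {f"m{i}": ["A"] if i < 3 else ["B"] for i in range(6)}
        return make_framework(calls, lines=["L0"])

    def _mapping(self, tag, marker, parent, cm):
        from gbskit.mapping import TagMapping
        return TagMapping(tag, marker, parent, 20, 20, 1e-6, "directed",
                          "chr1", cm)

    def test_scores_and_breakpoint_exclusion(self):
        fw = self._framework()
        presence = pd.DataFrame({"L0": [True, True, True, True]},
                                index=["t1", "t2", "t3", "t4"])
        mappings = {
            "t1": self._mapping("t1", "m1", "A", 10.0),   # correct
            "t2": self._mapping("t2", "m4", "B", 40.0),   # correct
            "t3": self._mapping("t3", "m4", "A", 40.0),   # wrong parent
            "t4": self._mapping("t4", "m2", "A", 25.0),   # inside the breakpoint
        }
        cv = cross_validate("L0", mappings, presence, fw)
        assert (cv.correct, cv.total, cv.excluded) == (2, 3, 1)
        assert cv.accuracy == pytest.approx(2 / 3)

    def test_absent_tags_do_not_count(self):
        fw = self._framework()
        presence = pd.DataFrame({"L0": [False]}, index=["t1"])
        cv = cross_validate("L0", {"t1": self._mapping("t1", "m0", "A", 0.0)},
                            presence, fw)
        assert cv.total == 0 and np.isnan(cv.accuracy)

    def test_unknown_line_raises(self):
        fw = self._framework()
        with pytest.raises(ValueError):
            cross_validate("L9", {}, pd.DataFrame({"L0": [True]}, index=["t"]), fw)

    def test_error_free_simulated_line_is_perfect(self, clean_bundle):
        from gbskit import map_tags_maize, tag_position_table
        truth = clean_bundle.truth
        fw = clean_bundle.population.framework
        held_out = clean_bundle.population.lines[0]
        presence = truth.presence
        seg = presence.loc[truth.tags["segregating"]]
        mappings = map_tags_maize(
            seg.drop(columns=[held_out]), fw,
            MappingThresholds(min_n=3, p_directed=0.1, p_global=5e-3),
            positions=tag_position_table(clean_bundle.parents.genomes["A"]))
        assert sum(m is not None for m in mappings.values()) > 0
        cv = cross_validate(held_out, mappings, presence, fw)
        assert cv.total > 0 and cv.accuracy == 1.0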