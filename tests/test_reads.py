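import gzip

import pytest

from gbskit import (DEFAULT_KIT, RawRead, Tag, classify_read, demultiplex,
                    expected_tags_from_reference, revcomp, trim_to_tag)
from gbskit.reads import (ACCEPTED, REJECT_DIMER, REJECT_N, REJECT_NO_BARCODE,
                          ConfigError, Demultiplexer, ParseError, read_fastq,
                          read_qseq)

BARCODES = ("CTCC", "TGCA", "ACTA", "AGGAT")  # pairwise distance >= 3, clean set
CONT = DEFAULT_KIT.common_adapter_top_rest + revcomp(DEFAULT_KIT.pcr2_tail)


def _read(seq, q=30):
    seq = seq[:86].ljust(86, "T")
    return RawRead(seq, [q] * 86)


def _genomic(barcode, insert64):
    assert len(insert64) >= 64
    return _read(barcode + insert64)


CLEAN64 = ("CAGC" + "ACTTGA" * 10).ljust(64, "C")


class TestParsers:
    def test_qseq_yields_failed_filter_reads_and_decodes_dots(self, tmp_path):
        qual = chr(30 + 64) * 8
        lines = ["M\t1\t3\t1\t5\t6\t0\t1\tACGT.CGT\t" + qual + "\t0",
                 "M\t1\t3\t1\t5\t7\t0\t1\tACGTACGT\t" + qual + "\t1"]
        path = tmp_path / "a.qseq"
        path.write_text("\n".join(lines) + "\n")
        reads = list(read_qseq(path))
        assert len(reads) == 2              # flag-0 read still yielded
        assert reads[0].sequence == "ACGTNCGT"
        assert reads[0].passed_filter is False
        assert list(reads[0].qualities) == [30] * 8

    def test_qseq_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.qseq"
        path.write_text("only\tthree\tfields\n")
        with pytest.raises(ParseError, match="line 1"):
            list(read_qseq(path))

    def test_empty_file_gives_empty_stream(self, tmp_path):
        path = tmp_path / "empty.qseq"
        path.write_text("")
        assert list(read_qseq(path)) == []

    def test_fastq_roundtrip_gz_and_crlf(self, tmp_path):
        rec = "@r1\r\nACGTACGT\r\n+\r\n" + chr(40 + 33) * 8 + "\r\n"
        gz = tmp_path / "r.fastq.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(rec)
        reads = list(read_fastq(gz))
        assert len(reads) == 1
        assert reads[0].sequence == "ACGTACGT"
        assert list(reads[0].qualities) == [40] * 8

    def test_fastq_truncated_record_raises(self, tmp_path):
        path = tmp_path / "t.fastq"
        path.write_text("@r1\nACGT\n+\n")
        with pytest.raises(ParseError):
            list(read_fastq(path))


class TestClassify:
    def test_clean_read_accepted(self):
        cr = classify_read(_genomic("CTCC", CLEAN64), BARCODES)
        assert cr.status == ACCEPTED
        assert cr.barcode == "CTCC"
        assert cr.tag.sequence == CLEAN64
        assert cr.min_q72 == 30

    def test_dimer_read_rejected(self):
        # adapter dimer: barcode, CWG sticky end, then common adapter directly
        cr = classify_read(_read("TGCA" + "CTG" + CONT), BARCODES)
        assert cr.status == REJECT_DIMER

    def test_n_in_first_72_rejects(self):
        seq = "CTCC" + CLEAN64
        seq = seq[:69] + "N" + seq[70:]
        cr = classify_read(_read(seq), BARCODES)
        assert cr.status == REJECT_N

    def test_n_beyond_72_is_tolerated(self):
        seq = ("CTCC" + CLEAN64).ljust(86, "T")
        seq = seq[:80] + "N" + seq[81:]
        assert classify_read(RawRead(seq, [30] * 86), BARCODES).status == ACCEPTED

    def test_missing_barcode_or_remnant_rejected(self):
        assert classify_read(_read("GGGG" + CLEAN64), BARCODES).status \
            == REJECT_NO_BARCODE
        # right barcode, wrong remnant
        assert classify_read(_read("CTCC" + "CCGC" + CLEAN64[4:]), BARCODES).status \
            == REJECT_NO_BARCODE

    def test_dimer_outranks_n_filter(self):
        seq = ("TGCA" + "CTG" + CONT)[:86].ljust(86, "T")
        seq = seq[:70] + "N" + seq[71:]
        assert classify_read(RawRead(seq, [30] * 86), BARCODES).status == REJECT_DIMER

    def test_min_q72_spans_the_raw_read(self):
        quals = [30] * 86
        quals[71] = 7   # inside the first 72 bases
        quals[80] = 2   # beyond them: ignored
        cr = Demultiplexer(BARCODES, validate=False).classify(
            RawRead("CTCC" + CLEAN64 + "T" * 18, quals))
        assert cr.min_q72 == 7


class TestTrim:
    def test_clean_window_is_identity(self):
        tag = trim_to_tag(CLEAN64 + "G" * 20)
        assert tag.sequence == CLEAN64 and tag.real_length == 64

    def test_adapter_readthrough_keeps_far_remnant(self):
        # remnant + 16 bases + CTG + adapter: 23 real bases, 41 fill
        seq = ("CAGC" + "ATTGACCTAAGGACCT" + "CTG" + CONT).ljust(86, "T")
        tag = trim_to_tag(seq)
        assert tag.real_length == 23
        assert tag.sequence == ("CAGC" + "ATTGACCTAAGGACCT" + "CTG").ljust(64, "A")

    def test_internal_site_collapses_onto_completed_digest(self):
        # partial digestion: a full GCAGC inside the window truncates the
        # read at the near-side cut product (through the regenerated CWG)
        insert = "ATTGACCTAAGGACCTACCT"
        partial = ("CAGC" + insert + "GCAGC" + "ACCTGA" * 12)[:86]
        tag = trim_to_tag(partial)
        assert tag.real_length == 4 + len(insert) + 4
        assert tag.sequence == ("CAGC" + insert + "GCAG").ljust(64, "A")
        # a completed digest of the same locus reads through into adapter
        completed = ("CAGC" + insert + "G" + "CAG" + CONT)[:86]
        assert trim_to_tag(completed).sequence == tag.sequence

    def test_leftmost_signature_wins(self):
        seq = ("CAGC" + "A" * 10 + "GCTGC" + "T" * 10 + "CTG" + CONT).ljust(86, "T")
        tag = trim_to_tag(seq)
        assert tag.real_length == 4 + 10 + 4  # the internal site, not the adapter

    def test_signature_straddling_the_window_edge_still_truncates(self):
        # adapter start at position 60: only 4 of its 8 bases fall inside
        # the 64-base window, but the truncation point is inside it
        seq = ("CAGC" + "C" * 53 + "CTG" + CONT).ljust(90, "T")
        tag = trim_to_tag(seq)
        assert tag.real_length == 60
        assert tag.sequence.endswith("CTG" + "A" * 4)


class TestDemultiplex:
    def test_counts_conserve_and_cv(self):
        reads = ([_genomic("CTCC", CLEAN64)] * 100
                 + [_genomic("TGCA", "CTGC" + CLEAN64[4:])] * 300
                 + [_read("TGCA" + "CTG" + CONT)] * 10
                 + [_read("T" * 86)] * 5)
        res = demultiplex(reads, {"s1": "CTCC", "s2": "TGCA"}, validate=False)
        stats = res.stats
        assert stats.per_sample_counts == {"s1": 100, "s2": 300}
        assert stats.accepted + sum(stats.reject_counts.values()) == stats.total == 415
        assert stats.reject_counts[REJECT_DIMER] == 10
        assert stats.cv == pytest.approx(0.5)  # sd/mean of {100, 300}

    def test_equal_representation_has_zero_cv(self):
        reads = [_genomic("CTCC", CLEAN64)] * 10 + \
                [_genomic("TGCA", CLEAN64)] * 10
        res = demultiplex(reads, {"a": "CTCC", "b": "TGCA"}, validate=False)
        assert res.stats.cv == 0.0

    def test_duplicate_barcode_in_key_is_config_error(self):
        with pytest.raises(ConfigError):
            demultiplex([], {"a": "CTCC", "b": "CTCC"})

    def test_roundtrip_with_simulator_is_exact(self, clean_bundle):
        """Error-free simulated reads are all accepted and trim to exactly
        the tags an in-silico digest of the line genomes predicts."""
        res = demultiplex(clean_bundle.reads.reads, clean_bundle.key)
        assert res.stats.accepted == res.stats.total
        truth_tags = set(clean_bundle.truth.tags.index)
        for sample, records in res.by_sample.items():
            assert {r.tag.sequence for r in records} <= truth_tags
        # per-line: observed tags equal exactly the truth tags of the reads
        # that were synthesized (expected presence minus Poisson-depth zeros)
        sequenced: dict[str, set] = {s: set() for s in res.by_sample}
        presence = clean_bundle.truth.presence
        for lab in clean_bundle.reads.labels:
            sequenced[lab.sample].add(lab.tag)
        for sample, records in res.by_sample.items():
            observed = {r.tag.sequence for r in records}
            assert observed == sequenced[sample]
            assert observed <= set(presence.index[presence[sample]])


def test_tag_invariants_enforced():
    with pytest.raises(ValueError):
        Tag("A" * 64, 64)            # missing remnant
    with pytest.raises(ValueError):
        Tag(CLEAN64[:63], 63)        # wrong length
    with pytest.raises(ValueError):
        Tag(CLEAN64[:32] + "C" * 32, 32)  # fill region not polyA
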