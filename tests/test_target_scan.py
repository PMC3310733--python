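"""Unit and oracle tests for the allele-aware seed scanner.

The brute-force oracle classifies by testing Watson-Crick complementarity
base-by-base at every start position, independently of the string-search
implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsel.errors import DataError
from mirsel.io_formats import MirnaFamily, UtrSequence, revcomp
from mirsel.target_scan import (
    attach_alt_bases,
    build_windows,
    classify_site,
    count_polymorphic_sites,
    scan_alleles,
)

PAIR = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def oracle_classify(sequence, seed, allow_6mer=False):
    """Independent brute-force classifier from the pairing definitions."""
    seq = sequence.upper().replace("U", "T")
    seed = seed.upper()

    def pairs_reverse(site, mirna):
        # mRNA site (5'->3') pairs the miRNA fragment antiparallel:
        # site base i pairs miRNA base (len-1-i)
        return len(site) == len(mirna) and all(
            PAIR[m] == s for s, m in zip(site, reversed(mirna))
        )

    classes = []
    for start in range(len(seq)):
        # 8mer: positions 2-8 pairing + A at the position opposite miRNA pos 1
        if start + 8 <= len(seq) and pairs_reverse(seq[start : start + 7], seed) and seq[start + 7] == "A":
            classes.append(("8mer", start))
        if start + 7 <= len(seq) and pairs_reverse(seq[start : start + 7], seed):
            classes.append(("7mer-m8", start))
        if start + 7 <= len(seq) and pairs_reverse(seq[start : start + 6], seed[:6]) and seq[start + 6] == "A":
            classes.append(("7mer-A1", start))
        if allow_6mer and start + 6 <= len(seq) and pairs_reverse(seq[start : start + 6], seed[:6]):
            classes.append(("6mer", start))
    priority = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}
    if not classes:
        return None
    return min(classes, key=lambda c: (priority[c[0]], c[1]))


class TestClassifySite:
    def test_8mer_example(self):
        assert classify_site("CCAGCAUUAACC", "UAAUGCU") == ("8mer", 2)
        assert oracle_classify("CCAGCAUUAACC", "UAAUGCU") == ("8mer", 2)

    def test_7mer_m8_example(self):
        assert classify_site("CCAGCAUUACC", "UAAUGCU") == ("7mer-m8", 2)
        assert oracle_classify("CCAGCAUUACC", "UAAUGCU") == ("7mer-m8", 2)

    def test_no_site(self):
        assert classify_site("CCCCCCCCCCCCC", "UAAUGCU") is None

    def test_6mer_only_with_flag(self):
        hexamer = revcomp("TAATGC")  # seed positions 2-7
        seq = "CC" + hexamer + "CC"
        assert classify_site(seq, "UAAUGCU", allow_6mer=False) is None
        assert classify_site(seq, "UAAUGCU", allow_6mer=True) == ("6mer", 2)

    def test_bad_seed_length(self):
        with pytest.raises(DataError):
            classify_site("ACGTACGT", "UAAUGC")

    @settings(max_examples=300, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=6, max_size=20),
        seed=st.text(alphabet="ACGU", min_size=7, max_size=7),
        allow=st.booleans(),
    )
    def test_matches_brute_force_oracle(self, seq, seed, allow):
        assert classify_site(seq, seed, allow) == oracle_classify(seq, seed, allow)

    def test_class_ordering_when_higher_masked(self):
        """Any 8mer site also contains the lower classes for the oracle."""
        seed = "UAAUGCU"
        site = revcomp("TAATGCT") + "A"  # 8mer
        seq = "CCC" + site + "CCC"
        assert oracle_classify(seq, seed)[0] == "8mer"
        # mask 8mer by removing the trailing A requirement context
        assert oracle_classify("CCC" + site[:-1] + "C", seed)[0] == "7mer-m8"
        # hexamer alone
        hexamer = revcomp("TAATGC")
        assert oracle_classify("CCC" + hexamer + "C", seed, allow_6mer=True)[0] == "6mer"


def make_utr(sequence, offsets, alt_bases, strand="+"):
    utr = UtrSequence(
        transcript_id="tx1",
        gene_id="g1",
        chrom="1",
        strand=strand,
        genomic_start=0,
        sequence=sequence,
        snp_offsets=offsets,
    )
    utr.snp_alt_bases = alt_bases
    return utr


class TestBuildWindows:
    def test_window_arithmetic(self):
        seq = "A" * 200
        utr = make_utr(seq, {"rs1": 50}, {"rs1": "G"})
        (win,) = build_windows(utr)
        assert win.window_start == 43
        assert len(win.window_seq_ref) == 15
        assert win.center == 7
        assert not win.truncated_left and not win.truncated_right

    def test_left_truncation_flag(self):
        utr = make_utr("A" * 200, {"rs1": 3}, {"rs1": "G"})
        (win,) = build_windows(utr)
        assert len(win.window_seq_ref) == 11
        assert win.center == 3
        assert win.truncated_left and not win.truncated_right

    def test_alleles_differ_only_at_center(self):
        utr = make_utr("ACGTACGTACGTACGTACGT", {"rs1": 10}, {"rs1": "C"})
        (win,) = build_windows(utr)
        diffs = [
            i
            for i, (a, b) in enumerate(zip(win.window_seq_ref, win.window_seq_alt))
            if a != b
        ]
        assert diffs == [win.center]

    def test_offset_outside_utr_is_error(self):
        utr = make_utr("ACGT", {}, {})
        utr.snp_offsets = {"rs1": 10}
        utr.snp_alt_bases = {"rs1": "G"}
        with pytest.raises(DataError):
            build_windows(utr)


class TestScanAlleles:
    SEED = "UAAUGCU"
    FAMILY = MirnaFamily("fam1", SEED)

    def test_disrupting_call(self):
        site = revcomp("TAATGCT")  # 7mer-m8 on the mRNA
        seq = "CCCC" + site + "CCCC"
        offset = 7  # a site base; REF completes the site
        alt = "C" if seq[offset] != "C" else "G"
        utr = make_utr(seq, {"rs1": offset}, {"rs1": alt})
        calls = scan_alleles(build_windows(utr), [self.FAMILY])
        assert len(calls) == 1
        assert calls[0].verdict == "disrupting"
        assert calls[0].site_type_ref == "7mer-m8"
        assert calls[0].site_type_alt == "none"

    def test_both_intact_when_snp_outside_site(self):
        site = revcomp("TAATGCT")
        seq = "CCCCC" + site + "CCCCCCCC"  # site at offsets 5..11
        offset = 12  # SNP just right of the site; window covers offsets 5..19
        utr = make_utr(seq, {"rs1": offset}, {"rs1": "G" if seq[offset] != "G" else "T"})
        calls = scan_alleles(build_windows(utr), [self.FAMILY])
        assert [c.verdict for c in calls] == ["both-intact"]
        summary = count_polymorphic_sites(calls)
        assert summary["n_snps"] == 0
        assert summary["n_both_intact"] == 1

    def test_one_snp_multiple_families(self):
        site = revcomp("TAATGCT")
        seq = "CCCC" + site + "CCCC"
        utr = make_utr(seq, {"rs1": 7}, {"rs1": "C" if seq[7] != "C" else "G"})
        fams = [MirnaFamily("famA", self.SEED), MirnaFamily("famB", self.SEED)]
        calls = scan_alleles(build_windows(utr), fams)
        assert len(calls) == 2
        summary = count_polymorphic_sites(calls)
        assert summary["n_calls"] == 2
        assert summary["n_snps"] == 1

    def test_context_score_threshold_drops_calls(self):
        site = revcomp("TAATGCT")
        seq = "CCCC" + site + "CCCC"
        utr = make_utr(seq, {"rs1": 7}, {"rs1": "C" if seq[7] != "C" else "G"})
        windows = build_windows(utr)
        scores = {("rs1", "fam1"): -0.1}  # above the -0.2 cutoff: low confidence
        assert scan_alleles(windows, [self.FAMILY], context_scores=scores) == []
        scores = {("rs1", "fam1"): -0.5}
        assert len(scan_alleles(windows, [self.FAMILY], context_scores=scores)) == 1

    def test_oracle_equivalence_on_random_windows(self, rng):
        families = [
            MirnaFamily("f1", "UAAUGCU"),
            MirnaFamily("f2", "GGAGUGU"),
        ]
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=15))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            seq = seq[:7] + ref + seq[8:]
            utr = make_utr(seq, {"rs": 7}, {"rs": alt})
            calls = scan_alleles(build_windows(utr), families, allow_6mer=True)
            by_family = {c.family_id: c for c in calls}
            for fam in families:
                alt_seq = seq[:7] + alt + seq[8:]
                hit_ref = oracle_classify(seq, fam.seed, True)
                hit_alt = oracle_classify(alt_seq, fam.seed, True)
                call = by_family.get(fam.family_id)
                if hit_ref is None and hit_alt is None:
                    assert call is None
                else:
                    assert call is not None
                    assert call.site_type_ref == (hit_ref[0] if hit_ref else "none")
                    assert call.site_type_alt == (hit_alt[0] if hit_alt else "none")


class TestStrandInvariance:
    def test_minus_strand_scan_equals_sense_scan(self, tmp_path):
        from mirsel.io_formats import read_utrs

        sense = "CCCC" + revcomp("TAATGCT") + "CCCC"
        genomic = revcomp(sense)  # what a minus-strand FASTA record stores
        fasta = f">tx1 gene=g1 strand=- start=0\n{genomic}\n"
        path = tmp_path / "u.fa"
        path.write_text(fasta)
        offset_plus = len(sense) - 1 - 7  # plus-strand offset of sense offset 7
        ref_plus = genomic[offset_plus]
        table = pd.DataFrame(
            [("rs1", "tx1", offset_plus, ref_plus, "G")],
            columns=["snp_id", "transcript_id", "offset", "ref", "alt"],
        )
        (utr,) = read_utrs(path, table)
        attach_alt_bases(utr, {"rs1": (ref_plus, "G")})
        calls_minus = scan_alleles(build_windows(utr), [MirnaFamily("fam1", "UAAUGCU")])

        direct = make_utr(sense, {"rs1": 7}, {"rs1": revcomp("G")})
        calls_plus = scan_alleles(build_windows(direct), [MirnaFamily("fam1", "UAAUGCU")])
        assert [(c.verdict, c.site_type_ref, c.site_type_alt) for c in calls_minus] == [
            (c.verdict, c.site_type_ref, c.site_type_alt) for c in calls_plus
        ]


def test_count_polymorphic_sites_empty():
    summary = count_polymorphic_sites([])
    assert summary["n_calls"] == 0
    assert summary["n_snps"] == 0
    assert all(v == 0 for v in summary["calls_by_site_type"].values())


def test_count_distinct_snps(rng):
    site = revcomp("TAATGCT")
    fam = MirnaFamily("fam1", "UAAUGCU")
    calls = []
    for i in range(5):
        seq = "CCCC" + site + "CCCC"
        utr = make_utr(seq, {f"rs{i}": 7}, {f"rs{i}": "C" if seq[7] != "C" else "G"})
        calls.extend(scan_alleles(build_windows(utr), [fam]))
    summary = count_polymorphic_sites(calls)
    assert summary["n_snps"] == 5
    assert summary["n_calls"] == 5
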