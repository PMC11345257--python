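"""Consensus CAZyme voting, SusC/D classes, tandem pairs, motifs, GH16 rules."""

import itertools

import numpy as np
import pytest

from lamipul import (
    ConfigError,
    DomainArchitecture,
    DomainHit,
    GeneRecord,
    GenomeAnnotation,
    SusCall,
    ValidationError,
    classify_gh16_architecture,
    classify_sus,
    consensus_cazyme,
    detect_suscd_pairs,
    scan_motif,
)
from lamipul.annotation import (
    GH16_REQUIRED_DOMAINS,
    MOTIF_GALACTOSIDASE_FINGER1,
    MOTIF_LAMINARINASE_FINGER3,
)
from oracles import exhaustive_tandem_pairs, naive_motif_positions

AA = "ACDEFGHIKLMNPQRSTVWY"


def hit(pid, tool, label, hit_class="specific"):
    return DomainHit(pid, tool, label, hit_class)


class TestConsensusCazyme:
    def test_single_tool_below_threshold(self):
        assert consensus_cazyme([hit("p1", "hmmer", "GH16")]) == []

    def test_three_tool_subfamily_call(self):
        hits = [hit("p1", "hmmer", "GH16"), hit("p1", "diamond", "GH16"),
                hit("p1", "dbcan_sub", "GH16_3")]
        calls = consensus_cazyme(hits, subfamily_tool="dbcan_sub")
        assert len(calls) == 1
        call = calls[0]
        assert (call.family, call.subfamily, call.support) == ("GH16", "GH16_3", 3)

    def test_votes_counted_per_family(self):
        """Oracle: per-family distinct-tool vote count."""
        hits = [hit("p1", "toolA", "GH16"), hit("p1", "toolB", "GH16"),
                hit("p1", "toolC", "GH17")]
        calls = consensus_cazyme(hits)
        assert [(c.family, c.support) for c in calls] == [("GH16", 2)]

    def test_idempotent_and_order_invariant(self, rng):
        tools = ["hmmer", "dbcan_sub", "diamond"]
        hits = [hit(f"p{i%5}", tools[int(rng.integers(3))],
                    ["GH16", "GH16_3", "GH3", "CBM6"][int(rng.integers(4))])
                for i in range(60)]
        forward = consensus_cazyme(hits)
        shuffled = consensus_cazyme([hits[i] for i in rng.permutation(len(hits))])
        assert forward == shuffled
        assert all(c.support <= 3 for c in forward)

    def test_min_tools_above_tool_set_errors(self):
        with pytest.raises(ConfigError):
            consensus_cazyme([], min_tools=4, tool_set_size=3)

    def test_duplicate_hits_from_one_tool_count_once(self):
        hits = [hit("p1", "hmmer", "GH16"), hit("p1", "hmmer", "GH16_3")]
        assert consensus_cazyme(hits) == []


class TestClassifySus:
    def test_specific_motif_hit(self):
        calls = classify_sus([hit("p1", "cdd", "TIGR04056", "specific")])
        assert calls == [SusCall("p1", "susC_specific",
                                 (hit("p1", "cdd", "TIGR04056", "specific"),))]

    def test_superfamily_only(self):
        calls = classify_sus([hit("p1", "cdd", "TIGR04056", "superfamily")])
        assert calls[0].sus_class == "susC_superfamily"

    def test_susd_and_unlabeled(self):
        calls = classify_sus([hit("p1", "cdd", "SusD"), hit("p2", "cdd", "PF00001")])
        assert [(c.protein_id, c.sus_class) for c in calls] == [("p1", "susD")]

    def test_conflict_excluded_and_partition(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="lamipul.annotation"):
            calls = classify_sus([hit("p1", "cdd", "TIGR04056"), hit("p1", "cdd", "SusD")])
        assert calls == []
        assert "both" in caplog.text
        # partition: one class per protein on a mixed table
        mixed = [hit("a", "cdd", "TIGR04056"), hit("a", "cdd", "TIGR04056", "superfamily"),
                 hit("b", "cdd", "SusD")]
        classes = [c.sus_class for c in classify_sus(mixed)]
        assert classes == ["susC_specific", "susD"]


def tandem_genome(layout):
    """layout: list of (kind, strand); genes laid out left to right."""
    genes = [GeneRecord(f"g{i}", "c", 1 + i * 100, i * 100 + 90, strand,
                        protein_id=f"g{i}")
             for i, (_, strand) in enumerate(layout)]
    genome = GenomeAnnotation(genes)
    sus = [SusCall(f"g{i}", kind) for i, (kind, _) in enumerate(layout)
           if kind != "none"]
    return genome, sus


class TestTandemPairs:
    def test_lone_susc_unpaired(self):
        genome, sus = tandem_genome([("susC_specific", "+"), ("none", "+")])
        assert detect_suscd_pairs(genome, sus) == []

    def test_adjacent_same_strand_pairs(self):
        genome, sus = tandem_genome([("susC_specific", "+"), ("susD", "+")])
        pairs = detect_suscd_pairs(genome, sus)
        assert [(c.gene_id, d.gene_id) for c, d in pairs] == [("g0", "g1")]

    def test_gap_of_three_is_no_pair(self):
        genome, sus = tandem_genome([
            ("susC_specific", "+"), ("none", "+"), ("none", "+"), ("susD", "+")])
        assert detect_suscd_pairs(genome, sus) == []

    def test_minus_strand_reading_direction(self):
        # susD must sit at rank-1 when susC is on the minus strand
        genome, sus = tandem_genome([("susD", "-"), ("susC_specific", "-")])
        pairs = detect_suscd_pairs(genome, sus)
        assert [(c.gene_id, d.gene_id) for c, d in pairs] == [("g1", "g0")]
        genome, sus = tandem_genome([("susC_specific", "-"), ("susD", "-")])
        assert detect_suscd_pairs(genome, sus) == []

    def test_opposite_strands_rejected(self):
        genome, sus = tandem_genome([("susC_specific", "+"), ("susD", "-")])
        assert detect_suscd_pairs(genome, sus) == []
        assert len(detect_suscd_pairs(genome, sus, strand_agnostic=True)) == 1

    def test_matches_exhaustive_pair_scan(self, rng):
        """Oracle: exhaustive scan of all gene pairs against the predicate."""
        for _ in range(20):
            n = 30
            kinds = rng.choice(["susC_specific", "susD", "none"], size=n,
                               p=[0.15, 0.15, 0.7])
            strands = rng.choice(["+", "-"], size=n)
            genome, sus = tandem_genome(list(zip(kinds, strands)))
            got = {(c.gene_id, d.gene_id)
                   for c, d in detect_suscd_pairs(genome, sus)}
            susc = {f"g{i}" for i in range(n) if kinds[i] == "susC_specific"}
            susd = {f"g{i}" for i in range(n) if kinds[i] == "susD"}
            oracle = set(exhaustive_tandem_pairs(genome, susc, susd))
            # greedy output is a subset; every greedy-eligible pair is found
            assert got <= oracle
            used = set()
            for c, d in sorted(oracle):
                if c not in used and d not in used:
                    assert (c, d) in got or d in {x for p in got for x in p}
                used |= {c, d}
            # each gene joins at most one pair
            flat = [g for p in got for g in p]
            assert len(flat) == len(set(flat))


class TestScanMotif:
    def test_planted_finger_motifs_found(self, rng):
        for motif in (MOTIF_LAMINARINASE_FINGER3, MOTIF_GALACTOSIDASE_FINGER1):
            seq = "".join(rng.choice(list(AA), size=200))
            planted = seq[:80] + motif + seq[80:]
            matches = scan_motif(planted, motif)
            assert (81, motif) in matches

    def test_empty_sequence_and_long_motif(self):
        assert scan_motif("", "WPA") == []
        assert scan_motif("WP", "WPA") == []

    def test_x_never_matches(self):
        assert scan_motif("AXA", "AXA") == []
        # X is a mismatch even against motif X; a budget of 1 absorbs it
        assert scan_motif("AXA", "AXA", max_mismatch=1) == [(1, "AXA")]
        assert scan_motif("AXA", "ABA", max_mismatch=1) == [(1, "AXA")]

    def test_mismatch_tolerance(self):
        assert scan_motif("GGTWPAQ", "GGTWPAL") == []
        assert scan_motif("GGTWPAQ", "GGTWPAL", max_mismatch=1) == [(1, "GGTWPAQ")]

    def test_agrees_with_naive_substring_search(self, rng):
        """Property over 1,000 random sequences with occasional planted motifs."""
        motifs = (MOTIF_LAMINARINASE_FINGER3, MOTIF_GALACTOSIDASE_FINGER1, "WPA")
        alphabet = list(AA + "X")
        for i in range(1000):
            seq = "".join(rng.choice(alphabet, size=60))
            motif = motifs[i % 3]
            if i % 4 == 0:
                pos = int(rng.integers(0, 40))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            got = [p for p, _ in scan_motif(seq, motif)]
            assert got == naive_motif_positions(seq, motif)

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            scan_motif("AAA", "")


def architecture(present, length=700):
    """Build a well-ordered architecture containing the given domain names."""
    spans = {
        "signal_peptide": (1, 20), "PKD": (48, 109), "laminarin_binding": (120, 294),
        "GH16_cat_N": (300, 420), "inserted_DUF": (430, 560), "GH16_cat_C": (570, 690),
        "WPA_site": (600, 602),
    }
    domains = [(name, *spans[name]) for name in present]
    return DomainArchitecture("prot", length, domains)


class TestGh16Architecture:
    def test_full_canonical(self):
        call = classify_gh16_architecture(architecture(GH16_REQUIRED_DOMAINS))
        assert call.verdict == "canonical_large_laminarinase"
        assert call.flags == () and call.missing_domains == ()

    def test_missing_pkd_demotes(self):
        present = [d for d in GH16_REQUIRED_DOMAINS if d != "PKD"]
        call = classify_gh16_architecture(architecture(present))
        assert call.verdict == "non_canonical"
        assert call.missing_domains == ("PKD",)

    def test_length_flag_does_not_demote(self):
        call = classify_gh16_architecture(architecture(GH16_REQUIRED_DOMAINS, 720))
        assert call.verdict == "canonical_large_laminarinase"
        assert call.flags == ("length_outside_687_705",)

    def test_overlapping_mandatory_domains_rejected(self):
        arch = DomainArchitecture("p", 700, [
            ("signal_peptide", 1, 60), ("PKD", 48, 109),
        ])
        with pytest.raises(ValidationError):
            classify_gh16_architecture(arch)

    def test_rule_on_full_presence_grid(self):
        """Oracle: direct rule evaluation over every domain-presence subset."""
        for r in range(len(GH16_REQUIRED_DOMAINS) + 1):
            for subset in itertools.combinations(GH16_REQUIRED_DOMAINS, r):
                call = classify_gh16_architecture(architecture(subset))
                expected = ("canonical_large_laminarinase"
                            if set(subset) == set(GH16_REQUIRED_DOMAINS)
                            else "non_canonical")
                assert call.verdict == expected
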