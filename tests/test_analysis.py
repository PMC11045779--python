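"""PWM scanning with exact p-values, enrichment, reference comparison,
EPM clustering."""

import math

import numpy as np
import pytest

from epmkit.analysis import (ScanConfig, ScoreTable, cluster_epms,
                             compare_to_reference, consensus_distance,
                             enrichment, flag_preferred, occurrence_chi2,
                             presence_scan, rc_consensus, scan)
from epmkit.discovery import EPM, _rc_matrix, motif_properties
from epmkit.regions import RegionConfig, one_hot

UNIFORM = ScanConfig(background=(0.25, 0.25, 0.25, 0.25))


def epm_from(pattern, name="epmSynt-S0-p0m00", metacluster="p0", ranges=None):
    pwm = one_hot(pattern).astype(float)
    e = EPM(name, metacluster, pwm.copy(), pwm, 10,
            preferred_ranges=ranges or {})
    e.info_content, e.consensus = motif_properties(e)
    return e


class TestScan:
    def test_single_forward_match_at_known_offset(self):
        e = epm_from("ACGG")
        cfg = ScanConfig(background=(0.25,) * 4, both_strands=False,
                         evalue_threshold=1.0)
        seqs = {"g": "TTTTTTACGGTTTTTT"}
        matches = scan([e], seqs, cfg)
        strong = [m for m in matches if m.score == max(x.score for x in matches)]
        assert len(strong) == 1
        assert strong[0].start == 6 and strong[0].strand == "+"

    def test_minus_strand_match_found(self):
        e = epm_from("ACGG")  # rc = CCGT
        cfg = ScanConfig(background=(0.25,) * 4, evalue_threshold=1.0)
        matches = scan([e], {"g": "TTTTCCGTTTTT"}, cfg)
        best = max(matches, key=lambda m: m.score)
        assert best.strand == "-" and best.start == 4

    def test_max_score_pvalue_is_quarter_to_the_width(self):
        """p of the best score of a width-4 one-hot motif under uniform
        background is (1/4)^4, the exhaustive enumeration value."""
        table = ScoreTable(one_hot("ACGT").astype(float), np.full(4, 0.25))
        top = table.s_int.max(axis=1).sum()
        assert table.pvalue(np.array([top]))[0] == pytest.approx(0.25 ** 4, abs=1e-12)

    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_pvalues_match_exhaustive_enumeration(self, width, rng):
        """DP lattice p-values equal brute-force enumeration over all 4^W
        words at every achievable score."""
        pwm = rng.dirichlet(np.ones(4) * 0.5, size=width)
        bg = rng.dirichlet(np.ones(4) * 5)
        table = ScoreTable(pwm, bg, pseudocount=0.01)
        # oracle: enumerate words, same per-column lattice rounding
        from itertools import product
        word_scores, word_probs = [], []
        for word in product(range(4), repeat=width):
            word_scores.append(sum(int(table.s_int[i, b]) for i, b in enumerate(word)))
            word_probs.append(np.prod([bg[b] for b in word]))
        word_scores = np.array(word_scores)
        word_probs = np.array(word_probs)
        for s in np.unique(word_scores)[::7]:
            expect = word_probs[word_scores >= s].sum()
            assert table.pvalue(np.array([s]))[0] == pytest.approx(expect, abs=1e-9)

    def test_evalue_threshold_excludes_weak_matches(self):
        e = epm_from("ACGG")
        seq = {"g": "TTTTTTACGGTTTTTT" * 40}  # large search space
        strict = scan([e], seq, ScanConfig(background=(0.25,) * 4,
                                           evalue_threshold=1e-6))
        loose = scan([e], seq, ScanConfig(background=(0.25,) * 4,
                                          evalue_threshold=50.0))
        assert strict == []
        assert loose and all(m.e_value < 50.0 for m in loose)

    def test_strand_closure_under_reverse_complement(self):
        """Scanning the RC sequence with the RC motif mirrors the match set."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 60)) + "ACGGTAC" + \
              "".join(rng.choice(list("ACGT"), 60))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_seq = "".join(comp[c] for c in reversed(seq))
        e = epm_from("ACGGTAC")
        e_rc = EPM("rc", "p0", _rc_matrix(e.pwm), _rc_matrix(e.pwm), 10)
        cfg = ScanConfig(background=(0.25,) * 4, evalue_threshold=10.0)
        fwd = scan([e], {"g": seq}, cfg)
        rev = scan([e_rc], {"g": rc_seq}, cfg)
        W = 7
        # a +-strand hit of the motif maps to a +-strand hit of the RC motif
        # on the RC sequence at the mirrored coordinate (and '-' to '-')
        mirror = {(len(seq) - m.start - W, m.strand, round(m.score, 6))
                  for m in rev}
        direct = {(m.start, m.strand, round(m.score, 6)) for m in fwd}
        assert direct == mirror

    def test_degenerate_background_rejected(self):
        with pytest.raises(ValueError):
            ScoreTable(one_hot("AC").astype(float), np.array([0.5, 0.5, 0.0, 0.0]),
                       pseudocount=0.0)


class TestFlagPreferred:
    RC_CFG = RegionConfig(promoter_len=60, utr5_len=40, utr3_len=40,
                          terminator_len=60, spacer_len=10)

    def make_match(self, epm, start):
        cfg = ScanConfig(background=(0.25,) * 4, evalue_threshold=10)
        from epmkit.analysis import MotifMatch, _anchor_match
        m = MotifMatch(epm.name, "g", start, "+", 1.0, 1e-5, 1e-3)
        _anchor_match(m, self.RC_CFG)
        return m

    def test_match_inside_range_flagged(self):
        e = epm_from("ACGG", ranges={"upstream": (17.5, 32.5)})
        m = self.make_match(e, self.RC_CFG.tss_index() + 25)
        flag_preferred([m], [e])
        assert m.within_preferred

    def test_half_without_range_never_in_range(self):
        e = epm_from("ACGG", ranges={"upstream": (0, 10)})
        m = self.make_match(e, self.RC_CFG.tts_index() + 5)  # downstream half
        flag_preferred([m], [e])
        assert not m.within_preferred

    def test_boundary_offset_included(self):
        e = epm_from("ACGG", ranges={"upstream": (17.5, 32.5)})
        m = self.make_match(e, self.RC_CFG.tss_index() + 18)
        flag_preferred([m], [e])
        assert m.within_preferred


class TestEnrichment:
    def test_eighty_twenty_case_is_exactly_four(self):
        r = enrichment("e", 80, 100, 20, 100, eps=0.0)
        assert r.enrichment == pytest.approx(4.0, abs=1e-12)

    def test_equal_fractions_give_zero(self):
        assert enrichment("e", 30, 100, 30, 100, eps=0.0).enrichment == 0.0

    def test_depleted_motif_negative(self):
        assert enrichment("e", 10, 100, 40, 100, eps=0.0).enrichment < 0

    def test_antisymmetry_under_class_swap(self, rng):
        for _ in range(20):
            A, B = int(rng.integers(2, 200)), int(rng.integers(2, 200))
            a, b = int(rng.integers(1, A)), int(rng.integers(1, B))
            r1 = enrichment("e", a, A, b, B, eps=0.0)
            r2 = enrichment("e", b, B, a, A, eps=0.0)
            assert r1.enrichment == pytest.approx(-r2.enrichment, abs=1e-12)

    def test_zero_cells_finite_with_continuity_correction(self):
        r = enrichment("e", 0, 50, 25, 50)  # default eps = 0.5
        assert math.isfinite(r.enrichment) and r.enrichment < 0


class TestOccurrenceChi2:
    def test_equal_counts_give_zero(self):
        chi2, p = occurrence_chi2(25, 100, 25, 100)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_ninety_ten_gives_sixty_four(self):
        chi2, p = occurrence_chi2(90, 100, 10, 100)
        assert chi2 == pytest.approx(64.0, abs=1e-12)

    def test_pvalue_matches_erfc_tail(self, rng):
        """1-df chi-square survival function equals erfc(sqrt(x/2))."""
        for _ in range(20):
            a, b = int(rng.integers(1, 500)), int(rng.integers(1, 500))
            chi2, p = occurrence_chi2(a, 600, b, 600)
            assert p == pytest.approx(math.erfc(math.sqrt(chi2 / 2)), abs=1e-10)


class TestCompareToReference:
    def test_self_similarity_is_one(self):
        e = epm_from("ACGGTACC")
        hits = compare_to_reference(e, {"self": e.pwm}, n_shuffles=20, seed=0)
        assert hits[0].pcc == pytest.approx(1.0)

    def test_reverse_complement_found_in_rev_orientation(self, rng):
        pfm = rng.dirichlet(np.ones(4) * 0.3, size=10)
        e = EPM("epmSynt-S0-p0m00", "p0", pfm.copy(), pfm, 10)
        hits = compare_to_reference(e, {"rc": _rc_matrix(pfm)}, n_shuffles=20,
                                    seed=0)
        assert hits[0].pcc == pytest.approx(1.0)
        assert hits[0].orientation == "rev"

    def test_informative_reference_hit_is_significant(self, rng):
        # a continuous-valued PFM: column shuffles essentially never realign
        pfm = rng.dirichlet(np.ones(4) * 0.3, size=10)
        e = EPM("epmSynt-S0-p0m01", "p0", pfm.copy(), pfm, 10)
        hits = compare_to_reference(e, {"self": pfm}, n_shuffles=99, seed=2)
        assert hits[0].pcc == pytest.approx(1.0)
        assert hits[0].p_value <= 0.05 and hits[0].significant

    def test_unrelated_reference_not_significant(self, rng):
        e = epm_from("ACGTACGT")
        noise = rng.dirichlet(np.ones(4), size=8)
        hits = compare_to_reference(e, {"noise": noise}, n_shuffles=99, seed=1)
        assert not hits[0].significant

    def test_narrow_reference_rejected(self):
        e = epm_from("ACGT")
        with pytest.raises(ValueError):
            compare_to_reference(e, {"w2": np.full((2, 4), 0.25)})


class TestClusterEpms:
    def test_identical_consensus_distance_zero(self):
        assert consensus_distance("CTCTCT", "CTCTCT") == pytest.approx(0.0)

    def test_reverse_complement_family_grouped(self):
        assert consensus_distance("CTCTCT", "AGAGAG") == pytest.approx(0.0)

    def test_rc_consensus_iupac_aware(self):
        assert rc_consensus("ARN") == "NYT"

    def test_three_planted_families_three_clusters(self):
        fams = {"CTCTCTCTCT": 3, "GGCGGCGGCA": 3, "TATATAAAGC": 3}
        epms = []
        for pat, n in fams.items():
            for i in range(n):
                # small per-member variation in one position
                variant = pat[:5] + "ACGT"[i % 4] + pat[6:]
                epms.append(epm_from(variant, name=f"epmSynt-S0-p0m{len(epms):02d}"))
        labels, Z, dmat = cluster_epms(epms, cut_height=0.5)
        groups = {}
        for lab, e in zip(labels, epms):
            groups.setdefault(lab, []).append(e.consensus)
        assert len(groups) == 3
        for members in groups.values():
            stems = {m[:5] for m in members}
            assert len(stems) == 1

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError):
            consensus_distance("", "ACGT")


class TestPresenceScan:
    CFG = RegionConfig(promoter_len=60, utr5_len=40, utr3_len=40,
                       terminator_len=60, spacer_len=10)

    def build_gene(self, rng, pattern=None, offset=20):
        seq = "".join(rng.choice(list("ACGT"), self.CFG.total_input_len))
        seq = seq[:100] + "N" * 10 + seq[110:]
        if pattern is not None:
            pos = self.CFG.tss_index() + offset
            seq = seq[:pos] + pattern + seq[pos + len(pattern):]
        return seq

    def test_in_range_occurrence_detected_per_gene(self):
        rng = np.random.default_rng(0)
        e = epm_from("CACCTGTC", ranges={"upstream": (10.0, 35.0)})
        seqs = {"with": self.build_gene(rng, "CACCTGTC", 20),
                "without": self.build_gene(rng)}
        matches, presence = presence_scan([e], seqs, self.CFG, per_gene_evalue=0.05)
        assert ("with", e.name) in presence
        assert ("without", e.name) not in presence
        assert all(m.within_preferred for m in matches)

    def test_out_of_range_occurrence_not_counted(self):
        rng = np.random.default_rng(1)
        e = epm_from("CACCTGTC", ranges={"upstream": (-50.0, -30.0)})
        seqs = {"g": self.build_gene(rng, "CACCTGTC", 20)}
        _, presence = presence_scan([e], seqs, self.CFG, per_gene_evalue=0.05)
        assert presence == set()
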