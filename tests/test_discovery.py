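"""Seqlet calling, clustering into EPMs, positional preference, naming."""

import numpy as np
import pytest

from epmkit.attribution import ImportanceTrack
from epmkit.discovery import (EPM, Seqlet, _rc_matrix, cluster_and_aggregate,
                              extract_seqlets, motif_properties, name_epm,
                              parse_epm_name, positional_preference,
                              reverse_complement_epm, split_metaclusters, trim_epm)
from epmkit.regions import RegionConfig, one_hot

CFG = RegionConfig(promoter_len=60, utr5_len=40, utr3_len=40,
                   terminator_len=60, spacer_len=10)  # total 210
L = CFG.total_input_len


def track_with(spikes, gene="g"):
    """ImportanceTrack with unit one-hot-style scores at given (pos, value)."""
    actual = np.zeros((L, 4))
    for pos, val in spikes:
        actual[pos, 0] = val
    return ImportanceTrack(gene, actual, actual.copy())


def onehot_for(gene_len=L):
    rng = np.random.default_rng(0)
    x = np.zeros((gene_len, 4))
    x[np.arange(gene_len), rng.integers(0, 4, gene_len)] = 1
    return x


class TestExtractSeqlets:
    def test_zero_tracks_give_no_seqlets(self):
        tracks = [track_with([]) for _ in range(3)]
        enc = {"g": onehot_for()}
        assert extract_seqlets(tracks, enc, CFG, window_len=7, null_reps=5) == []

    def test_single_spike_recovered_by_brute_force_oracle(self):
        t = track_with([(30, 5.0)])
        out = extract_seqlets([t], {"g": onehot_for()}, CFG, window_len=7,
                              null_reps=10, fdr_level=0.05, seed=1)
        assert len(out) >= 1
        top = max(out, key=lambda s: abs(s.total_score))
        # oracle: scan all windows for the max |sum|
        sums = [t.per_position[i:i + 7].sum() for i in range(L - 6)]
        best = int(np.argmax(np.abs(sums)))
        assert top.start <= 30 < top.end
        assert abs(top.total_score) == pytest.approx(abs(sums[best]))

    def test_overlapping_candidates_resolved_greedily(self):
        # two spikes 3 nt apart: windows overlap, only the stronger survives
        t = track_with([(30, 5.0), (33, 3.0)])
        out = extract_seqlets([t], {"g": onehot_for()}, CFG, window_len=7,
                              null_reps=10, fdr_level=0.05, seed=1)
        covering = [s for s in out if s.start <= 33 and 30 < s.end]
        assert len(covering) == 1
        assert covering[0].total_score == pytest.approx(8.0)  # both spikes inside

    def test_windows_never_cross_the_spacer(self):
        t = track_with([(CFG.upstream_len - 3, 9.0)])
        out = extract_seqlets([t], {"g": onehot_for()}, CFG, window_len=7,
                              null_reps=10, fdr_level=0.05, seed=1)
        for s in out:
            assert s.end <= CFG.upstream_len or s.start >= CFG.upstream_len + CFG.spacer_len

    def test_anchor_offsets_relative_to_tss_and_tts(self):
        up = track_with([(CFG.tss_index() + 12, 6.0)])
        dn = track_with([(CFG.tts_index() + 20, 6.0)])
        out_up = extract_seqlets([up], {"g": onehot_for()}, CFG, 7, 10,
                                 fdr_level=0.05, seed=2)
        out_dn = extract_seqlets([dn], {"g": onehot_for()}, CFG, 7, 10,
                                 fdr_level=0.05, seed=2)
        s_up = max(out_up, key=lambda s: abs(s.total_score))
        s_dn = max(out_dn, key=lambda s: abs(s.total_score))
        assert s_up.half == "upstream" and s_up.anchor_offset == s_up.start - CFG.tss_index()
        assert s_dn.half == "downstream" and s_dn.anchor_offset == s_dn.start - CFG.tts_index()

    def test_window_longer_than_track_rejected(self):
        with pytest.raises(ValueError):
            extract_seqlets([track_with([])], {"g": onehot_for()}, CFG,
                            window_len=L + 1)


class TestMetaclusters:
    def seqlet(self, score):
        return Seqlet("g", 0, 7, "fwd", np.zeros((7, 4)), np.zeros((7, 4)),
                      score, "upstream", 0)

    def test_sign_split_and_zero_dropped(self):
        meta = split_metaclusters([self.seqlet(0.3), self.seqlet(-0.3), self.seqlet(0.0)])
        assert [s.total_score for s in meta["p0"]] == [0.3]
        assert [s.total_score for s in meta["p1"]] == [-0.3]


def seqlet_from_pattern(pattern, score=1.0, noise_seed=None, offset=0, W=12):
    """Seqlet whose patch and one-hot carry the pattern at ``offset``."""
    rng = np.random.default_rng(noise_seed if noise_seed is not None else 0)
    seq = "".join(rng.choice(list("ACGT"), size=W))
    seq = seq[:offset] + pattern + seq[offset + len(pattern):]
    oh = one_hot(seq[:W])
    patch = oh * score + rng.normal(0, 0.01 * abs(score), (W, 4))
    return Seqlet("g", 0, W, "fwd", patch, oh, score * len(pattern), "upstream", 0)


class TestClusterAndAggregate:
    def test_identical_seqlets_form_one_pure_cluster(self):
        s = seqlet_from_pattern("CTCTCT", noise_seed=1)
        members = [Seqlet("g", 0, 12, "fwd", s.patch.copy(), s.onehot.copy(),
                          s.total_score, "upstream", 0) for _ in range(12)]
        epms = cluster_and_aggregate(members, "p0", min_seqlets=10)
        assert len(epms) == 1
        assert np.allclose(epms[0].cwm, s.patch)
        assert set(np.unique(epms[0].pwm)) <= {0.0, 1.0}

    def test_two_planted_patterns_give_two_matching_clusters(self):
        seqs = [seqlet_from_pattern("CTCTCTCTCTCT", noise_seed=i) for i in range(15)]
        seqs += [seqlet_from_pattern("CATCATCATCAT", noise_seed=100 + i) for i in range(15)]
        epms = cluster_and_aggregate(seqs, "p0", min_seqlets=10)
        assert len(epms) == 2
        planted = [one_hot("CTCTCTCTCTCT"), one_hot("CATCATCATCAT")]
        for target in planted:
            best = max(np.corrcoef(e.pwm.ravel(), target.ravel())[0, 1] for e in epms)
            assert best >= 0.95  # oracle: generator truth

    def test_reverse_complement_joins_the_same_cluster(self):
        fwd = [seqlet_from_pattern("CCCTTTAAAGGG", noise_seed=i) for i in range(11)]
        rc_patch = _rc_matrix(fwd[0].patch)
        rc_oh = _rc_matrix(fwd[0].onehot)
        rev = Seqlet("g", 0, 12, "fwd", rc_patch, rc_oh, fwd[0].total_score,
                     "upstream", 0)
        epms = cluster_and_aggregate(fwd + [rev], "p0", min_seqlets=10)
        assert len(epms) == 1
        assert epms[0].n_seqlets == 12

    def test_small_clusters_discarded(self):
        seqs = [seqlet_from_pattern("ACACACACACAC", noise_seed=i) for i in range(5)]
        assert cluster_and_aggregate(seqs, "p0", min_seqlets=10) == []

    def test_discovery_on_rc_inputs_gives_rc_motifs(self):
        """Clustering the reverse-complemented seqlets yields a PWM matching
        the reverse complement of the original motif."""
        seqs = [seqlet_from_pattern("CCGTTACGATGG", noise_seed=i) for i in range(12)]
        rc_seqs = [Seqlet("g", 0, 12, "fwd", _rc_matrix(s.patch),
                          _rc_matrix(s.onehot), s.total_score, "upstream", 0)
                   for s in seqs]
        fwd_epm = cluster_and_aggregate(seqs, "p0", min_seqlets=10)[0]
        rc_epm = cluster_and_aggregate(rc_seqs, "p0", min_seqlets=10)[0]
        pcc = np.corrcoef(rc_epm.pwm.ravel(),
                          _rc_matrix(fwd_epm.pwm).ravel())[0, 1]
        assert pcc >= 0.95


class TestPositionalPreference:
    def make_epm(self, offsets, halves, n_total=None):
        seqlets = [Seqlet("g", 0, 7, "fwd", np.zeros((7, 4)), np.zeros((7, 4)),
                          1.0, h, o) for o, h in zip(offsets, halves)]
        epm = EPM("e", "p0", np.zeros((7, 4)), np.full((7, 4), 0.25),
                  n_seqlets=len(seqlets), seqlet_indices=list(range(len(seqlets))))
        return epm, seqlets

    def test_quartile_range(self):
        epm, seqlets = self.make_epm([10, 20, 30, 40], ["upstream"] * 4)
        ranges = positional_preference(epm, seqlets)
        assert ranges["upstream"] == (17.5, 32.5)

    def test_sparse_half_excluded(self):
        offsets = [5] * 5 + list(range(100))
        halves = ["upstream"] * 5 + ["downstream"] * 100
        epm, seqlets = self.make_epm(offsets, halves)
        ranges = positional_preference(epm, seqlets)
        assert "upstream" not in ranges and "downstream" in ranges

    def test_degenerate_constant_offsets(self):
        epm, seqlets = self.make_epm([7, 7, 7], ["downstream"] * 3)
        assert positional_preference(epm, seqlets)["downstream"] == (7.0, 7.0)


class TestMotifProperties:
    def test_one_hot_pwm_has_maximal_information(self):
        pwm = one_hot("ACGT").astype(float)
        epm = EPM("e", "p0", pwm.copy(), pwm, 1)
        ic, consensus = motif_properties(epm)
        assert ic == pytest.approx(8.0)
        assert consensus == "ACGT"

    def test_uniform_row_contributes_zero_bits_and_n(self):
        pwm = np.full((1, 4), 0.25)
        ic, consensus = motif_properties(EPM("e", "p0", pwm.copy(), pwm, 1))
        assert ic == pytest.approx(0.0)
        assert consensus == "N"

    def test_half_half_row_gets_iupac_code(self):
        pwm = np.array([[0.5, 0.0, 0.5, 0.0]])
        _, consensus = motif_properties(EPM("e", "p0", pwm.copy(), pwm, 1))
        assert consensus == "R"  # A or G

    def test_unnormalised_pwm_rejected(self):
        pwm = np.array([[0.5, 0.1, 0.1, 0.1]])
        with pytest.raises(ValueError):
            motif_properties(EPM("e", "p0", pwm.copy(), pwm, 1))


class TestTrim:
    def test_low_information_flanks_trimmed_and_ranges_shifted(self):
        pwm = np.vstack([np.full((3, 4), 0.25), one_hot("ACGT"), np.full((2, 4), 0.25)])
        epm = EPM("e", "p0", pwm.copy(), pwm, 20,
                  preferred_ranges={"upstream": (10.0, 30.0)})
        t = trim_epm(epm, min_ic=0.3)
        assert t.width == 4
        assert t.consensus == "ACGT"
        assert t.preferred_ranges["upstream"] == (13.0, 33.0)


class TestNaming:
    def test_reference_name_composition(self):
        assert name_epm("Arth", "S", 0, 19, "p0", 6) == "epmArth-S019-p0m06"

    def test_short_dialect_without_run_index(self):
        assert name_epm("Soly", "M", 0, None, "p0", 2) == "epmSoly-M0-p0m02"

    def test_round_trip(self):
        for name in ["epmArth-S019-p0m06", "epmSoly-M0-p0m02", "epmZema-S103-p1m11R"]:
            p = parse_epm_name(name)
            assert name_epm(p["species_code"], p["model_type"], p["condition"],
                            p["run_idx"], p["metacluster"], p["motif_idx"],
                            p["orientation"]) == name

    def test_malformed_names_rejected(self):
        with pytest.raises(ValueError):
            parse_epm_name("epmXX-S019-p0m06")
        with pytest.raises(ValueError):
            name_epm("arabidopsis", "S", 0, 1, "p0", 1)

    def test_reverse_complement_epm_is_linked_and_rc(self):
        pwm = one_hot("ACGGT").astype(float)
        epm = EPM("epmSynt-S0-p0m00", "p0", pwm.copy(), pwm, 10)
        epm.info_content, epm.consensus = motif_properties(epm)
        rc = reverse_complement_epm(epm)
        assert rc.name.endswith("R")
        assert rc.consensus == "ACCGT"
        assert np.array_equal(rc.pwm, _rc_matrix(epm.pwm))
        assert rc.reverse_complement is epm and epm.reverse_complement is rc
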