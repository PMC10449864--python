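"""Observation extraction, the stutter-aware caller, and the QC cascade."""

import math

import numpy as np
import pytest

from ystrkit.catalog import TandemRepeatLocus
from ystrkit.genotyper import (
    AlignedRead,
    FilterConfig,
    ReadObservation,
    StutterModel,
    depth_profile,
    extract_observations,
    female_read_counts,
    genotype_locus,
    site_filters,
)

LOCUS = TandemRepeatLocus("y", 1000, 1030, "ACT", 3, 10.0, 1.0, name="L1")


def read(pos, cigar, name="r", mapq=60, proper=True, primary=True, chrom="y"):
    return AlignedRead(
        name=name, chrom=chrom, pos=pos, cigar=tuple(cigar), mapq=mapq,
        properly_paired=proper, primary=primary,
    )


class TestExtractObservations:
    def test_full_match_spanning_read(self):
        obs, bad = extract_observations([read(950, [("M", 150)])], LOCUS)
        assert bad == 0 and len(obs) == 1
        assert obs[0].obs_len == 30 and not obs[0].flank_indel_flag

    def test_deletion_inside_repeat_shortens_observation(self):
        # 3 bp deletion inside the tract: M60 D3 M(rest)
        r = read(950, [("M", 60), ("D", 3), ("M", 90)])
        obs, _ = extract_observations([r], LOCUS)
        assert obs[0].obs_len == 27

    def test_insertion_extends_observation(self):
        r = read(950, [("M", 60), ("I", 3), ("M", 87)])
        obs, _ = extract_observations([r], LOCUS)
        assert obs[0].obs_len == 33 and not obs[0].flank_indel_flag

    def test_insertion_in_upstream_flank_sets_flag(self):
        # insertion 5 bp upstream of the tract start (ref position 995)
        r = read(950, [("M", 45), ("I", 1), ("M", 105)])
        obs, _ = extract_observations([r], LOCUS)
        assert obs[0].obs_len == 30 and obs[0].flank_indel_flag

    def test_non_spanning_read_excluded(self):
        # ends 2 bp inside the repeat
        obs, _ = extract_observations([read(900, [("M", 102)])], LOCUS)
        assert obs == []
        # ends exactly at the anchor boundary: still not spanning
        obs, _ = extract_observations([read(900, [("M", 139)])], LOCUS)
        assert obs == []
        obs, _ = extract_observations([read(900, [("M", 140)])], LOCUS)
        assert len(obs) == 1

    @pytest.mark.parametrize(
        "kw", [dict(mapq=9), dict(proper=False), dict(primary=False), dict(chrom="x")]
    )
    def test_ineligible_reads_skipped(self, kw):
        obs, _ = extract_observations([read(950, [("M", 150)], **kw)], LOCUS)
        assert obs == []

    def test_mapq_boundary_inclusive(self):
        # 'greater than 10' implemented as >= 10 (samtools -q semantics)
        obs, _ = extract_observations([read(950, [("M", 150)], mapq=10)], LOCUS)
        assert len(obs) == 1

    def test_clipped_read_not_spanning(self):
        # soft clip keeps the alignment from covering the anchor window
        r = read(992, [("S", 50), ("M", 100)])
        obs, _ = extract_observations([r], LOCUS)
        assert obs == []

    def test_malformed_cigar_counted(self):
        r = read(950, [("Z", 150)])
        obs, bad = extract_observations([r], LOCUS)
        assert obs == [] and bad == 1


def obs_list(lengths, flank=0):
    out = [ReadObservation("L1", x) for x in lengths]
    for o in out[:flank]:
        o.flank_indel_flag = True
    return out


class TestGenotypeLocus:
    def test_unanimous_reads_posterior_one(self):
        call = genotype_locus(obs_list([45] * 10), LOCUS)
        assert call.allele_len == 45
        assert call.posterior == pytest.approx(1.0)
        assert call.frac_stutter == 0.0 and call.missing_reason == "none"

    def test_posterior_matches_hand_computed_likelihood(self):
        # two candidates one unit apart; verify against the closed form
        model = StutterModel(p_s=0.05, rho=0.8, eps=1e-4)
        lengths = [30] * 8 + [27] * 2
        call = genotype_locus(obs_list(lengths), LOCUS, model)
        l30 = 8 * math.log(0.95) + 2 * math.log(0.05 * 0.5 * 0.2)
        l27 = 2 * math.log(0.95) + 8 * math.log(0.05 * 0.5 * 0.2)
        expected = math.exp(l30) / (math.exp(l30) + math.exp(l27))
        assert call.allele_len == 30
        assert call.posterior == pytest.approx(expected, rel=1e-12)

    def test_stutter_fraction_40pct_missing_30pct_called(self):
        missing = genotype_locus(obs_list([45] * 6 + [42] * 4), LOCUS)
        assert missing.is_missing and missing.missing_reason == "stutter_frac"
        assert missing.frac_stutter == pytest.approx(0.4)
        called = genotype_locus(obs_list([45] * 7 + [42] * 3), LOCUS)
        assert called.allele_len == 45 and called.frac_stutter == pytest.approx(0.3)

    def test_posterior_threshold_default_vs_lowcov(self):
        # construct a posterior between 0.75 and 0.90 with stutter <= 35%:
        # 7 vs 3 reads one unit apart under a noisy stutter model
        model = StutterModel(p_s=0.6, rho=0.1)
        lengths = [30] * 7 + [27] * 3
        call = genotype_locus(obs_list(lengths), LOCUS, model)
        assert call.posterior is not None and 0.75 <= call.posterior < 0.90
        assert call.is_missing and call.missing_reason == "low_posterior"
        lc = genotype_locus(obs_list(lengths), LOCUS, model, FilterConfig.lowcov())
        assert not lc.is_missing

    def test_no_reads_missing(self):
        call = genotype_locus([], LOCUS)
        assert call.is_missing and call.missing_reason == "no_reads" and call.depth == 0

    def test_flank_indel_fraction_rule(self):
        call = genotype_locus(obs_list([45] * 10, flank=4), LOCUS)
        assert call.is_missing and call.missing_reason == "flank_indel_frac"
        call = genotype_locus(obs_list([45] * 10, flank=3), LOCUS)
        assert not call.is_missing

    def test_posterior_is_a_distribution(self):
        # normalized likelihood over candidates sums to 1
        model = StutterModel()
        obs = obs_list([45] * 4 + [42] * 3 + [48] * 3)
        lengths = [o.obs_len for o in obs]
        cands = sorted(set(lengths))
        logs = [
            sum(model.log_emission(x, a, LOCUS.period) for x in lengths) for a in cands
        ]
        m = max(logs)
        total = sum(math.exp(v - m) for v in logs)
        probs = [math.exp(v - m) / total for v in logs]
        assert sum(probs) == pytest.approx(1.0)
        call = genotype_locus(obs, LOCUS, model)
        assert call.posterior == pytest.approx(max(probs))

    def test_tie_broken_toward_reference_length(self):
        model = StutterModel()
        # symmetric likelihoods; 27 and 33 equidistant from ref 30 -> smaller
        # wins (thresholds relaxed so the call is not masked as missing)
        cfg = FilterConfig(q_min=0.4, max_artifact_frac=0.6)
        call = genotype_locus(obs_list([27] * 5 + [33] * 5), LOCUS, model, cfg)
        assert call.allele_len == 27


class TestSiteFilters:
    def test_missingness_and_female_rules(self):
        from ystrkit.genotyper import GenotypeCall

        def call(sample, locus, missing):
            if missing:
                return GenotypeCall(sample, locus, None, None, 0, 0, 0, "no_reads")
            return GenotypeCall(sample, locus, 45, 1.0, 8, 0, 0)

        calls = {
            "L_bad": {f"M{i}": call(f"M{i}", "L_bad", i < 6) for i in range(10)},  # 60% missing
            "L_ok": {f"M{i}": call(f"M{i}", "L_ok", i < 5) for i in range(10)},  # 50% exactly
            "L_fem": {f"M{i}": call(f"M{i}", "L_fem", False) for i in range(10)},
            "L_fem2": {f"M{i}": call(f"M{i}", "L_fem2", False) for i in range(10)},
        }
        female = {"L_fem": {"F1": 3, "F2": 0}, "L_fem2": {"F1": 2, "F2": 2}}
        kept, dropped, stats = site_filters(calls, female)
        assert stats["L_bad"].drop_reason == "missingness"
        # exactly 50% missing is kept (strict inequality), as is a female at
        # exactly two reads ('more than two' rule)
        assert "L_ok" in kept and "L_fem2" in kept
        assert stats["L_fem"].drop_reason == "female_reads"
        assert set(kept) | set(dropped) == set(calls)

    def test_aggregate_female_mode(self):
        from ystrkit.genotyper import GenotypeCall

        calls = {"L": {"M0": GenotypeCall("M0", "L", 45, 1.0, 8, 0, 0)}}
        female = {"L": {"F1": 2, "F2": 1}}
        kept, dropped, _ = site_filters(calls, female, FilterConfig(female_aggregate=True))
        assert dropped == ["L"]
        kept, dropped, _ = site_filters(calls, female, FilterConfig())
        assert kept == ["L"]


def test_female_read_counts_overlap_rule():
    loci = [LOCUS]
    females = {
        "F1": [read(980, [("M", 100)], name=f"a{i}") for i in range(3)],  # overlap
        "F2": [read(900, [("M", 90)], name="b")],  # flank only, ends at 990
        "F3": [],
    }
    counts = female_read_counts(females, loci)
    assert counts["L1"] == {"F1": 3, "F2": 0, "F3": 0}


class TestDepthProfile:
    def test_uniform_coverage(self, clean_study):
        cfg, ref, catalog, truth, reads = clean_study
        profile, flags = depth_profile(reads["M1"], ref.id, ref.length, window_bp=1000)
        depths = np.array([d for _, d in profile])
        assert abs(depths.mean() - cfg.coverage) < 1.5
        assert flags == []

    def test_deletion_flagged(self):
        # reads everywhere except a 5 kb hole
        reads = []
        for pos in range(0, 20_000 - 100, 50):
            if 8_000 <= pos < 13_000:
                continue
            reads.append(read(pos, [("M", 100)], name=f"r{pos}"))
        profile, flags = depth_profile(reads, "y", 20_000, window_bp=1000)
        assert any(s <= 9000 and e >= 12_000 for s, e in flags)

    def test_empty_alignments_single_flag(self):
        profile, flags = depth_profile([], "y", 10_000, window_bp=1000)
        assert all(d == 0 for _, d in profile)
        assert flags == [(0, 10_000)]

    def test_window_floor(self):
        with pytest.raises(ValueError):
            depth_profile([], "y", 1000, window_bp=50)
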