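"""Crosslink-analysis contracts: deduplication vs a set oracle, hand-counted
profiles, RPM arithmetic, enrichment ratios against simulation, site calling
on planted ground truth, and the Fisher/Benjamini-Hochberg window test
against exact enumeration."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import m5cmap.crosslink as cl
import m5cmap.synthetic_data as sd
from m5cmap.align import AlignmentRecord

from conftest import manifest_records


def make_record(read_id="r1", umi="AAAA", ref="pre_rRNA_47S", start=10,
                length=30, score=60, strand="+"):
    return AlignmentRecord(read_id, umi, ref, start, strand, length, score,
                           f"{length}M", "A" * length)


class TestDeduplicate:
    def test_identical_key_collapses_to_one(self):
        recs = [make_record(read_id=f"r{i}") for i in range(3)]
        assert len(cl.deduplicate(recs)) == 1

    def test_distinct_umis_survive(self):
        recs = [make_record(umi="AAAA"), make_record(umi="CCCC")]
        assert len(cl.deduplicate(recs)) == 2

    def test_matches_distinct_key_set_oracle_with_injected_duplicates(
            self, refs, xmodel, tmp_path):
        cfg = sd.LibraryConfig(n_reads=500, sample_type="SMInput", seed=31,
                               duplicate_fraction=0.2)
        sd.simulate_miclip_library(refs, xmodel, cfg, tmp_path / "d.fastq",
                                   tmp_path / "d.tsv")
        recs = manifest_records(tmp_path / "d.tsv")
        keys = {(r.reference, r.start, r.strand, r.umi, r.aligned_length)
                for r in recs}
        assert len(keys) < len(recs)  # duplicates actually injected
        assert len(cl.deduplicate(recs)) == len(keys)

    def test_idempotent_and_order_independent(self):
        rng = random.Random(2)
        recs = [make_record(read_id=f"r{i}", umi=rng.choice(["AA", "CC"]),
                            start=rng.choice([5, 10]), score=rng.choice([50, 60]))
                for i in range(50)]
        once = cl.deduplicate(recs)
        assert cl.deduplicate(once) == once
        shuffled = recs[:]
        rng.shuffle(shuffled)
        assert cl.deduplicate(shuffled) == once

    def test_keeps_highest_score_per_key(self):
        low = make_record(read_id="rb", score=40)
        high = make_record(read_id="ra", score=70)
        kept = cl.deduplicate([low, high])
        assert kept == [high]


class TestStopProfile:
    def test_hand_counted_stops(self, refs):
        starts = [10, 10, 11, 30, 30]  # 1-based positions
        recs = [make_record(read_id=f"r{i}", umi=f"U{i}", start=s - 1)
                for i, s in enumerate(starts)]
        prof = cl.stop_profile(recs, refs)
        stops = prof.stops["pre_rRNA_47S"]
        assert stops[9] == 2 and stops[10] == 1 and stops[29] == 2
        assert prof.library_size == 5
        assert int(sum(a.sum() for a in prof.stops.values())) == 5

    def test_empty_records_zero_profile(self, refs):
        prof = cl.stop_profile([], refs)
        assert prof.library_size == 0
        assert all(a.sum() == 0 for a in prof.stops.values())

    def test_out_of_bounds_record_rejected(self, refs):
        bad = make_record(start=refs.length("pre_rRNA_47S") - 5, length=30)
        with pytest.raises(ValueError):
            cl.stop_profile([bad], refs)

    def test_argmax_over_28s_is_planted_site(self, c459a_profile, refs):
        ref28, abs4447 = refs.local_to_abs("28S", 4447)
        iv = next(i for i in refs.intervals if i.name == "28S")
        region = c459a_profile.stops[ref28][iv.start - 1: iv.end]
        assert int(np.argmax(region)) + iv.start == abs4447

    def test_coverage_dominates_stops(self, c459a_profile):
        for name in c459a_profile.stops:
            assert np.all(c459a_profile.coverage[name] >= c459a_profile.stops[name])


class TestNormalizeRpm:
    def test_per_million_identity(self, refs):
        prof = cl.StopProfile(
            {n: np.zeros(refs.length(n), np.int64) for n in refs.sequences},
            {n: np.zeros(refs.length(n), np.int64) for n in refs.sequences},
            1_000_000)  # synthetic profile, arithmetic only
        prof.stops["pre_rRNA_47S"][0] = 5
        track = cl.normalize_rpm(prof)
        assert track["pre_rRNA_47S"][0] == 5.0

    def test_arithmetic(self, refs):
        prof = cl.StopProfile(
            {n: np.zeros(refs.length(n), np.int64) for n in refs.sequences},
            {n: np.zeros(refs.length(n), np.int64) for n in refs.sequences},
            200_000)
        prof.stops["pre_rRNA_47S"][41] = 2
        assert cl.normalize_rpm(prof)["pre_rRNA_47S"][41] == pytest.approx(10.0)

    def test_scale_invariance(self, c459a_profile):
        track = cl.normalize_rpm(c459a_profile)
        doubled = cl.StopProfile(
            {n: 2 * a for n, a in c459a_profile.stops.items()},
            {n: 2 * a for n, a in c459a_profile.coverage.items()},
            2 * c459a_profile.library_size)
        track2 = cl.normalize_rpm(doubled)
        for name in track:
            assert np.allclose(track[name], track2[name])

    def test_zero_library_rejected(self, refs):
        with pytest.raises(ValueError):
            cl.normalize_rpm(cl.stop_profile([], refs))


class TestEnrichmentTrack:
    def test_identical_profiles_give_unit_ratio(self, c459a_profile):
        track = cl.enrichment_track(c459a_profile, c459a_profile)
        for name in track:
            assert np.allclose(track[name], 1.0)

    def test_pseudocount_arithmetic(self, refs):
        zeros = {n: np.zeros(refs.length(n), np.int64) for n in refs.sequences}
        ip = cl.StopProfile({n: a.copy() for n, a in zeros.items()},
                            {n: a.copy() for n, a in zeros.items()}, 10 ** 6)
        smi = cl.StopProfile({n: a.copy() for n, a in zeros.items()},
                             {n: a.copy() for n, a in zeros.items()}, 10 ** 6)
        ip.coverage["pre_rRNA_47S"][7] = 199
        smi.coverage["pre_rRNA_47S"][7] = 99
        assert cl.enrichment_track(ip, smi)["pre_rRNA_47S"][7] == pytest.approx(2.0)

    def test_simulated_window_recovers_relative_enrichment(self, refs, tmp_path):
        win = sd.BindingWindow(sd.PRE_RRNA, 2001, 3000, 5.0)
        model = sd.CrosslinkModel(binding_windows=[win])
        profs = {}
        for sample, seed in (("IP_WT", 41), ("SMInput", 42)):
            cfg = sd.LibraryConfig(n_reads=50_000, sample_type=sample, seed=seed)
            sd.simulate_miclip_library(refs, model, cfg, tmp_path / f"{sample}.fastq",
                                       tmp_path / f"{sample}.tsv")
            profs[sample] = cl.stop_profile(
                manifest_records(tmp_path / f"{sample}.tsv"), refs)
        track = cl.enrichment_track(profs["IP_WT"], profs["SMInput"])
        # window interior, clear of coverage ramps at the window borders
        inner = track[sd.PRE_RRNA][2100:2900]
        assert abs(inner.mean() - 5.0) <= 1.0

    def test_mismatched_references_rejected(self, refs, c459a_profile):
        other = cl.StopProfile({"x": np.zeros(10, np.int64)},
                               {"x": np.zeros(10, np.int64)}, 10)
        with pytest.raises(ValueError):
            cl.enrichment_track(c459a_profile, other)


class TestCallSites:
    def test_all_zero_profiles_no_calls(self, refs):
        empty = cl.stop_profile([], refs)
        assert len(cl.call_sites(empty, empty)) == 0

    def test_plug_in_arithmetic_example(self, refs):
        """stops 50/coverage 100 vs WT 0, both libraries 1e5: fraction 0.5 and
        depth-scaled pseudocount ratio 50.5/0.5 = 101 pass all defaults."""
        zeros = {n: np.zeros(refs.length(n), np.int64) for n in refs.sequences}
        mut = cl.StopProfile({n: a.copy() for n, a in zeros.items()},
                             {n: a.copy() for n, a in zeros.items()}, 100_000)
        wt = cl.StopProfile({n: a.copy() for n, a in zeros.items()},
                            {n: a.copy() for n, a in zeros.items()}, 100_000)
        p = 4446  # arbitrary 0-based position
        mut.stops["pre_rRNA_47S"][p] = 50
        mut.coverage["pre_rRNA_47S"][p] = 100
        df = cl.call_sites(mut, wt)
        row = df[(df.reference == "pre_rRNA_47S") & (df.position == p + 1)].iloc[0]
        assert row.stop_fraction == pytest.approx(0.5)
        assert row.ratio == pytest.approx(101.0)
        assert bool(row.passed)

    def test_end_to_end_exactly_planted_sites_pass(self, c459a_profile,
                                                   wt_profile, refs):
        df = cl.call_sites(c459a_profile, wt_profile, refs=refs)
        passed = df[df.passed]
        assert set(passed.label) == {"28S:4447", "vtRNA1_2:27"}
        assert passed.iloc[0].label in {"28S:4447", "vtRNA1_2:27"}  # sorted by ratio


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(k):
        return (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                / math.comb(n, row1))

    p_obs = pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestWindowEnrichment:
    def test_fisher_p_matches_hypergeometric_enumeration(self):
        from scipy.stats import fisher_exact

        table = (30, 970, 5, 995)
        p_scipy = fisher_exact([[table[0], table[1]], [table[2], table[3]]],
                               "two-sided")[1]
        assert p_scipy == pytest.approx(fisher_oracle(*table), abs=1e-9)

    def test_proportional_profiles_nothing_significant(self, refs):
        rng = np.random.default_rng(0)
        zeros = {n: np.zeros(refs.length(n), np.int64) for n in refs.sequences}
        stops = {n: a.copy() for n, a in zeros.items()}
        stops["pre_rRNA_47S"] = rng.integers(0, 5, refs.length("pre_rRNA_47S"))
        ip = cl.StopProfile(stops, zeros, int(stops["pre_rRNA_47S"].sum()))
        smi = cl.StopProfile({n: 2 * a for n, a in stops.items()}, zeros,
                             2 * ip.library_size)
        df = cl.window_enrichment(ip, smi)
        assert not df.significant.any()
        assert ((df.adjusted_p >= 0) & (df.adjusted_p <= 1)).all()

    def test_null_simulation_fdr_bounded(self, refs, tmp_path):
        """SMInput vs SMInput (no binding windows): mean significant-window
        fraction across 20 runs stays within the nominal 5% FDR."""
        model = sd.CrosslinkModel()
        fractions = []
        for run in range(20):
            profs = []
            for j in (0, 1):
                cfg = sd.LibraryConfig(n_reads=5000, sample_type="SMInput",
                                       seed=500 + 2 * run + j)
                mft = tmp_path / f"n{run}_{j}.tsv"
                sd.simulate_miclip_library(refs, model, cfg,
                                           tmp_path / f"n{run}_{j}.fastq", mft)
                profs.append(cl.stop_profile(manifest_records(mft), refs))
            df = cl.window_enrichment(profs[0], profs[1])
            fractions.append(df.significant.mean())
        assert np.mean(fractions) <= 0.05

    def test_invalid_window_geometry_rejected(self, c459a_profile):
        with pytest.raises(ValueError):
            cl.window_enrichment(c459a_profile, c459a_profile, window=10, step=25)

    def test_significant_windows_cover_planted_binding_window(
            self, refs, xmodel, c459a_profile, workdir, tmp_path):
        cfg = sd.LibraryConfig(n_reads=20_000, sample_type="SMInput", seed=1013)
        mft = tmp_path / "smi.tsv"
        sd.simulate_miclip_library(refs, xmodel, cfg, tmp_path / "smi.fastq", mft)
        smi = cl.stop_profile(manifest_records(mft), refs)
        df = cl.window_enrichment(c459a_profile, smi)
        sig = df[df.significant & (df.reference == sd.PRE_RRNA)]
        win = xmodel.binding_windows[0]
        overlapping = sig[(sig.start < win.end) & (sig.end > win.start - 1)]
        assert len(overlapping) > 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_benjamini_hochberg_monotone_in_raw_p_order(pvals):
    """BH-adjusted p-values are within [0,1] and non-decreasing when read in
    ascending raw-p order."""
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(pvals, method="fdr_bh")[1]
    assert np.all((adj >= 0) & (adj <= 1))
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


class TestClassSummary:
    def test_all_rrna(self, refs):
        recs = [make_record(read_id=f"r{i}", start=5000 + i) for i in range(10)]
        df = cl.class_summary(recs, refs)
        assert df.set_index("class").loc["rRNA", "fraction"] == 1.0

    def test_hand_counted_mixture(self, refs):
        recs = [make_record(read_id=f"r{i}", start=5000 + i) for i in range(9)]
        recs.append(make_record(read_id="sn", ref="SNORD_1", start=0, length=60))
        df = cl.class_summary(recs, refs).set_index("class")
        assert df.loc["rRNA", "fraction"] == pytest.approx(0.9)
        assert df.loc["snoRNA_CD", "fraction"] == pytest.approx(0.1)

    def test_fractions_sum_to_one(self, c459a_records, refs):
        df = cl.class_summary(c459a_records, refs)
        assert df.fraction.sum() == pytest.approx(1.0)

    def test_default_mutant_mixture_is_rrna_dominant(self, c459a_records, refs):
        df = cl.class_summary(c459a_records, refs).set_index("class")
        assert df.loc["rRNA", "fraction"] >= 0.97
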