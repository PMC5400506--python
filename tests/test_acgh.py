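"""Bulk aCGH scoring: chromosome calls, focal segments, burden, overlay."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from karyostat import (
    ScoringParams,
    SimConfig,
    aneuploidy_burden,
    assess_locus_recombination,
    chromosome_scores,
    cohort_threshold_overlay,
    count_whole_chromosome_events,
    detect_focal_cnvs,
    dosage_correlation,
    normalize_within_chromosome,
    render_bulk_acgh,
    simulate_lineage,
)
from karyostat.acgh import moving_average
from karyostat.simulate import CloneTable

from conftest import profile_from_values


def brute_force_runs(values, starts, ends, chrom, tau, min_probes, window):
    """Independent oracle: enumerate maximal beyond-threshold runs directly."""
    sm = moving_average(np.asarray(values, float), window)
    flags = [1 if v >= tau else (-1 if v <= -tau else 0) for v in sm]
    out = []
    for sign, group in itertools.groupby(enumerate(flags), key=lambda t: t[1]):
        idx = [i for i, _ in group]
        if sign != 0 and len(idx) >= min_probes:
            out.append((chrom, int(starts[idx[0]]), int(ends[idx[-1]]),
                        "amplification" if sign > 0 else "deletion"))
    return out


class TestChromosomeScores:
    def test_flat_zero_profile_all_neutral(self):
        prof = profile_from_values({"chr1": [0] * 5, "chr2": [0] * 5})
        scores = chromosome_scores(prof)
        assert (scores.scores["mean_ratio"] == 0).all()
        assert (scores.scores["call"] == "neutral").all()
        assert count_whole_chromosome_events(scores) == 0

    def test_mean_above_threshold_called_gain(self):
        prof = profile_from_values({"chr1": [0.3, 0.35, 0.31], "chr2": [0, 0, 0]})
        scores = chromosome_scores(prof)
        assert scores.mean_ratios()["chr1"] == pytest.approx(0.32)
        assert scores.calls()["chr1"] == "gain"
        assert scores.calls()["chr2"] == "neutral"

    @pytest.mark.parametrize(
        "value,call",
        [(0.30, "gain"), (-0.30, "loss"), (0.2999, "neutral"), (-0.2999, "neutral")],
    )
    def test_boundary_is_inclusive(self, value, call):
        prof = profile_from_values({"chr1": [value] * 4})
        assert chromosome_scores(prof).calls()["chr1"] == call

    def test_purity_dilution_flips_call_across_threshold(self, small_layout):
        # clonal +1 on chr1: R = log2((2+f)/2); callable at f=0.5, not at f=0.4
        karyo = np.full((1, 5), 2)
        karyo[0, 0] = 3
        ct = CloneTable(small_layout.chromosomes, karyo, np.array([1.0]))
        probes = small_layout.uniform_probes(1_000_000)
        calls = {}
        for f in (0.5, 0.4):
            prof = render_bulk_acgh(ct, small_layout, probes,
                                    SimConfig(seed=1, purity=f, noise_sd=0.0))
            calls[f] = chromosome_scores(prof).calls()["chr1"]
        assert calls[0.5] == "gain" and calls[0.4] == "neutral"

    def test_chromosome_without_probes_absent_not_zero(self):
        prof = profile_from_values({"chr1": [0.5, 0.5]})
        scores = chromosome_scores(prof)
        assert list(scores.scores["chrom"]) == ["chr1"]

    def test_counts_nonneutral_chromosomes(self):
        prof = profile_from_values(
            {"chr13": [-0.5] * 3, "chr15": [0.4] * 3, "chr2": [0.0] * 3}
        )
        assert count_whole_chromosome_events(chromosome_scores(prof)) == 2

    def test_empty_profile_rejected(self):
        prof = profile_from_values({"chr1": [0.1]})
        prof.probes = prof.probes.iloc[0:0]
        with pytest.raises(ValueError):
            chromosome_scores(prof)

    def test_sex_chromosomes_excluded_by_default(self):
        prof = profile_from_values({"chr1": [0.0] * 3, "chrX": [0.9] * 3})
        assert "chrX" not in chromosome_scores(prof).calls()
        scores_all = chromosome_scores(prof, ScoringParams(autosomes_only=False))
        assert scores_all.calls()["chrX"] == "gain"


class TestNormalization:
    def test_whole_chromosome_gain_removed(self):
        prof = profile_from_values({"chr1": [0.5] * 6})
        normed = normalize_within_chromosome(prof)
        assert np.allclose(normed.probes["log2_ratio"], 0.0)

    def test_focal_spike_arithmetic(self):
        prof = profile_from_values({"chr1": [0, 0, 1.2, 0]})
        normed = normalize_within_chromosome(prof)
        assert np.allclose(normed.probes["log2_ratio"], [-0.3, -0.3, 0.9, -0.3])

    def test_chromosome_means_zero_after_normalization(self, rng):
        vals = {f"chr{i}": list(rng.normal(i * 0.1, 0.4, size=40)) for i in range(1, 6)}
        normed = normalize_within_chromosome(profile_from_values(vals))
        means = normed.probes.groupby("chrom")["log2_ratio"].mean()
        assert (means.abs() < 1e-12).all()


class TestFocalDetection:
    def test_all_zero_profile_has_no_segments(self):
        prof = profile_from_values({"chr1": [0.0] * 20})
        assert detect_focal_cnvs(prof) == []

    def test_five_probe_amplification_detected_exactly(self):
        vals = [0.0] * 7 + [0.8] * 5 + [0.0] * 8
        prof = profile_from_values({"chr1": vals})
        segs = detect_focal_cnvs(prof, ScoringParams(window=1))
        assert len(segs) == 1
        seg = segs[0]
        assert seg.sign == "amplification"
        assert seg.n_probes == 5
        assert seg.start == 7 * 1_000_000
        assert seg.end == 11 * 1_000_000 + 1

    def test_short_runs_below_min_probes_ignored(self):
        prof = profile_from_values({"chr1": [0, 0, -0.9, -0.9, 0, 0]})
        assert detect_focal_cnvs(prof, ScoringParams(window=1, min_probes=3)) == []

    def test_smoothing_window_changes_support(self):
        # isolated spike survives window 1 only if long enough; window 3 dilutes it
        vals = [0.0] * 5 + [0.95, 0.95, 0.95] + [0.0] * 5
        prof = profile_from_values({"chr1": vals})
        raw = detect_focal_cnvs(prof, ScoringParams(window=1))
        assert len(raw) == 1
        smoothed = detect_focal_cnvs(prof, ScoringParams(window=3))
        # smoothed edges are 2/3 x 0.95 = 0.63 >= 0.3, so run widens to 5 probes
        assert len(smoothed) == 1 and smoothed[0].n_probes == 5

    def test_gene_counts_by_overlap(self):
        vals = [0.0] * 3 + [1.0] * 4 + [0.0] * 3
        prof = profile_from_values({"chr1": vals})
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [3_200_000, 9_500_000, 3_200_000],
                "end": [3_400_000, 9_600_000, 3_400_000],
                "name": ["inA", "outside", "wrongChrom"],
            }
        )
        segs = detect_focal_cnvs(prof, ScoringParams(window=1), gene_map=genes)
        assert len(segs) == 1 and segs[0].gene_count == 1

    @settings(max_examples=200, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=-2, max_value=2, allow_nan=False), min_size=1, max_size=200
        ),
        window=st.sampled_from([1, 3, 5]),
        min_probes=st.integers(min_value=1, max_value=4),
    )
    def test_matches_brute_force_enumeration(self, values, window, min_probes):
        prof = profile_from_values({"chr1": values})
        params = ScoringParams(window=window, min_probes=min_probes, autosomes_only=True)
        segs = detect_focal_cnvs(prof, params)
        got = [(s.chrom, s.start, s.end, s.sign) for s in segs]
        probes = prof.probes
        want = brute_force_runs(
            probes["log2_ratio"].to_numpy(), probes["start"].to_numpy(),
            probes["end"].to_numpy(), "chr1", 0.3, min_probes, window,
        )
        assert got == want


class TestBurden:
    def test_zero_for_flat_profile(self):
        burden = aneuploidy_burden(chromosome_scores(profile_from_values({"chr1": [0] * 3})))
        assert burden.total == 0.0

    def test_sums_absolute_chromosome_means(self):
        prof = profile_from_values(
            {"chr1": [0.32] * 3, "chr2": [-0.42] * 3, "chr3": [0.0] * 3}
        )
        burden = aneuploidy_burden(chromosome_scores(prof))
        assert burden.total == pytest.approx(0.74)

    def test_invariant_under_probe_reordering(self, rng):
        vals = {f"chr{i}": list(rng.normal(0, 0.5, size=30)) for i in range(1, 4)}
        prof = profile_from_values(vals)
        shuffled = prof.probes.sample(frac=1, random_state=0)
        from karyostat import ProbeProfile

        prof2 = ProbeProfile("t", shuffled, prof.chrom_order)
        b1 = aneuploidy_burden(chromosome_scores(prof)).total
        b2 = aneuploidy_burden(chromosome_scores(prof2)).total
        assert b1 == pytest.approx(b2, abs=1e-12)


class TestDosageCorrelation:
    def test_proportional_vectors_give_r_one(self):
        acgh = {"chr1": 0.1, "chr2": -0.2, "chr3": 0.3}
        mrna = {k: 0.8 * v for k, v in acgh.items()}
        r, _ = dosage_correlation(acgh, mrna)
        assert r == pytest.approx(1.0)

    def test_antiproportional_vectors_give_r_minus_one(self):
        acgh = {"chr1": 0.1, "chr2": -0.2, "chr3": 0.3}
        mrna = {k: -v for k, v in acgh.items()}
        r, _ = dosage_correlation(acgh, mrna)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula_exactly(self):
        x = np.array([0.1, -0.2, 0.3, 0.0])
        y = np.array([0.05, -0.1, 0.2, 0.02])
        xm, ym = x - x.mean(), y - y.mean()
        hand = float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
        r, p = dosage_correlation(
            dict(zip(["chr1", "chr2", "chr3", "chr4"], x)),
            dict(zip(["chr1", "chr2", "chr3", "chr4"], y)),
        )
        assert r == pytest.approx(hand, abs=1e-12)
        assert 0 <= p <= 1

    def test_rejects_short_or_degenerate_input(self):
        with pytest.raises(ValueError):
            dosage_correlation({"chr1": 1.0, "chr2": 2.0}, {"chr1": 1.0, "chr2": 2.0})
        with pytest.raises(ValueError):
            dosage_correlation(
                {"chr1": 1.0, "chr2": 1.0, "chr3": 1.0},
                {"chr1": 0.0, "chr2": 1.0, "chr3": 2.0},
            )


class TestOverlay:
    def _profiles(self, values_list):
        return [
            profile_from_values({"chr1": [v] * 3}, sample_id=f"t{i}")
            for i, v in enumerate(values_list)
        ]

    def test_counts_tumors_beyond_threshold(self, small_layout):
        profiles = self._profiles([0.4, 0.35, -0.1])
        table = cohort_threshold_overlay(profiles, layout=small_layout)
        occupied = table[table["gain_count"] + table["loss_count"] > 0]
        assert (occupied["gain_count"] == 2).all()
        assert (occupied["loss_count"] == 0).all()

    def test_all_zero_cohort_all_counts_zero(self, small_layout):
        table = cohort_threshold_overlay(self._profiles([0.0, 0.0]), layout=small_layout)
        assert table["gain_count"].sum() == 0 and table["loss_count"].sum() == 0

    def test_counts_bounded_and_order_invariant(self, small_layout, rng):
        profiles = [
            profile_from_values(
                {f"chr{i}": list(rng.normal(0, 0.5, size=10)) for i in range(1, 6)},
                sample_id=f"t{k}",
            )
            for k in range(4)
        ]
        t1 = cohort_threshold_overlay(profiles, layout=small_layout)
        t2 = cohort_threshold_overlay(profiles[::-1], layout=small_layout)
        assert ((t1["gain_count"] + t1["loss_count"]) <= 4).all()
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_cohort_rejected(self, small_layout):
        with pytest.raises(ValueError):
            cohort_threshold_overlay([], layout=small_layout)


class TestLocusRecombination:
    def _profile(self, inside, flanks=0.0):
        vals = [flanks, flanks, inside, flanks, flanks]
        return profile_from_values({"chr1": vals})

    def test_deep_deletion_with_quiet_flanks_is_recombined(self):
        # 75% tumor purity, homozygous deletion: log2((1-0.75)*2/2) = -2
        prof = self._profile(inside=np.log2(0.25))
        res = assess_locus_recombination(prof, ("chr1", 2_000_000, 2_000_001))
        assert res["status"] == "recombined"
        assert res["inside_mean"] == pytest.approx(-2.0)

    def test_flat_profile_is_unrecombined(self):
        res = assess_locus_recombination(self._profile(0.0), ("chr1", 2_000_000, 2_000_001))
        assert res["status"] == "unrecombined"

    def test_intermediate_value_is_partially_recombined(self):
        res = assess_locus_recombination(self._profile(-0.5), ("chr1", 2_000_000, 2_000_001))
        assert res["status"] == "partially_recombined"

    def test_missing_flank_rejected(self):
        prof = self._profile(-2.0)
        with pytest.raises(ValueError):
            assess_locus_recombination(prof, ("chr1", 0, 1))


class TestSimulatorRecovery:
    def test_calls_recover_dominant_clone_karyotype(self, small_layout):
        """At purity 1 and sigma 0, whole-chromosome calls equal a dominant
        clone's karyotype when its aberrations clear the threshold in the
        clone mixture (0.8 aberrant vs 0.2 euploid here)."""
        probes = small_layout.uniform_probes(1_000_000)
        major = np.array([3, 1, 2, 4, 2])
        ct = CloneTable(
            small_layout.chromosomes,
            np.vstack([major, np.full(5, 2)]),
            np.array([0.8, 0.2]),
        )
        cfg = SimConfig(seed=2, purity=1.0, noise_sd=0.0)
        prof = render_bulk_acgh(ct, small_layout, probes, cfg)
        calls = chromosome_scores(prof).calls()
        want = {3: "gain", 1: "loss", 2: "neutral", 4: "gain"}
        for chrom, s in zip(small_layout.chromosomes, major):
            assert calls[chrom] == want[int(s)]

    def test_pipeline_means_match_closed_form_mixture(self, small_layout):
        """Chromosome means of rendered noise-free profiles equal
        log2(mixture copy number / 2) computed directly from clone weights."""
        probes = small_layout.uniform_probes(1_000_000)
        for seed in range(10):
            cfg = SimConfig(p_mis=0.05, divisions=8, seed=seed, purity=1.0, noise_sd=0.0)
            ct = simulate_lineage(cfg, small_layout)
            prof = render_bulk_acgh(ct, small_layout, probes, cfg)
            means = chromosome_scores(prof).mean_ratios()
            for j, chrom in enumerate(small_layout.chromosomes):
                mixture = float(ct.weights @ ct.karyotypes[:, j])
                assert means[chrom] == pytest.approx(np.log2(max(mixture, 0.05) / 2), abs=1e-9)
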