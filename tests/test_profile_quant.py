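"""Profile quantification: baseline, segmentation, integration, FRP,
group statistics and Ward.D clustering."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polytrans import (
    FRPResult,
    GradientModel,
    PhenotypeRecord,
    PolysomeProfile,
    RegionAreas,
    cluster_mice,
    compare_frp,
    compute_frp,
    correct_baseline,
    correlate_phenotype,
    integrate_regions,
    read_profile,
    relative_phenotype,
    segment_peaks,
    simulate_cohort,
    simulate_profile,
    write_profile,
)
from polytrans.profile_quant import polysome_monosome_ratio, ward_d_linkage


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestProfileIO:
    def test_round_trip_is_lossless(self, tmp_path, noiseless_profile):
        profile, _ = noiseless_profile
        path = tmp_path / "p.tsv"
        write_profile(profile, path)
        back = read_profile(path)
        np.testing.assert_allclose(back.positions, profile.positions)
        np.testing.assert_allclose(back.absorbance, profile.absorbance)
        np.testing.assert_array_equal(back.fraction_index, profile.fraction_index)

    def test_non_monotone_positions_error_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("position\tabsorbance\tfraction_index\n"
                        "0.0\t1.0\t1\n0.2\t1.0\t1\n0.1\t1.0\t1\n0.3\t1.0\t1\n")
        with pytest.raises(ValueError, match="row 2"):
            read_profile(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("position\tabsorbance\n0.0\t1.0\n")
        with pytest.raises(ValueError, match="fraction_index"):
            read_profile(path)


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

class TestBaseline:
    def _flat(self, y):
        n = len(y)
        return PolysomeProfile(np.linspace(0, 10, n), y, np.ones(n, dtype=int))

    def test_offset_only_trace_becomes_zero(self):
        out = correct_baseline(self._flat(np.full(100, 0.7)))
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_pure_ramp_becomes_zero(self):
        pos = np.linspace(0, 10, 100)
        out = correct_baseline(self._flat(0.3 + 0.5 * pos))
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-10)

    def test_recovers_known_peak_areas_within_one_percent(self, separated_model):
        m = dataclasses.replace(separated_model, baseline_slope=0.05,
                                baseline_offset=0.3)
        profile, truth = simulate_profile(m, seed=0)
        corrected = correct_baseline(profile)
        areas = integrate_regions(corrected, segment_peaks(corrected))
        for region, true_area in truth.true_region_areas.items():
            assert areas.area[region] == pytest.approx(true_area, rel=0.01)

    def test_anchor_outside_trace_rejected(self, noiseless_profile):
        profile, _ = noiseless_profile
        with pytest.raises(ValueError, match="outside"):
            correct_baseline(profile, anchors=(0.0, 99.0))

    def test_short_trace_rejected(self):
        p = PolysomeProfile(np.arange(5, dtype=float), np.zeros(5), np.ones(5, dtype=int))
        with pytest.raises(ValueError, match="10"):
            correct_baseline(p)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_boundary_near_grid_search_minimum(self, noiseless_profile, default_model):
        profile, _ = noiseless_profile
        corrected = correct_baseline(profile)
        seg = segment_peaks(corrected)
        # oracle: exhaustive minimum of the noiseless trace between the 80S
        # and first polysomal peak centers
        c80, cp1 = default_model.peak_centers[3], default_model.peak_centers[4]
        pos = corrected.positions
        mask = (pos >= c80) & (pos <= cp1)
        oracle = pos[mask][np.argmin(corrected.absorbance[mask])]
        boundary = seg.regions["80S"][1]
        assert boundary == pytest.approx(oracle, abs=default_model.peak_widths[3])
        assert seg.regions["80S"][1] == seg.regions["POLYSOMES"][0]

    def test_single_peak_gives_zero_width_polysome_region(self):
        pos = np.linspace(0, 10, 500)
        y = 2.0 * np.exp(-0.5 * ((pos - 5.0) / 0.4) ** 2)
        p = PolysomeProfile(pos, y, np.ones(500, dtype=int))
        seg = segment_peaks(p, expected_species=["80S"])
        start, end = seg.regions["POLYSOMES"]
        assert start == end == pytest.approx(10.0)
        assert "polysome_region_empty" in seg.flags
        assert seg.regions["80S"][0] == pytest.approx(0.0)

    def test_flat_trace_errors(self):
        p = PolysomeProfile(np.linspace(0, 10, 200), np.zeros(200),
                            np.ones(200, dtype=int))
        with pytest.raises(ValueError, match="no peaks"):
            segment_peaks(p)

    def test_too_few_peaks_lists_detections(self):
        pos = np.linspace(0, 10, 500)
        y = np.exp(-0.5 * ((pos - 3) / 0.3) ** 2) + np.exp(-0.5 * ((pos - 7) / 0.3) ** 2)
        p = PolysomeProfile(pos, y, np.ones(500, dtype=int))
        with pytest.raises(ValueError, match="detected only 2"):
            segment_peaks(p)

    def test_determinism(self, default_model):
        m = dataclasses.replace(default_model, noise_sd=0.02)
        profile, _ = simulate_profile(m, seed=5)
        corrected = correct_baseline(profile)
        s1 = segment_peaks(corrected)
        s2 = segment_peaks(corrected)
        assert s1.regions == s2.regions


# ---------------------------------------------------------------------------
# integration and FRP
# ---------------------------------------------------------------------------

class TestIntegration:
    def test_unit_rectangle_area(self):
        pos = np.linspace(0, 10, 1001)
        y = np.where((pos >= 4) & (pos <= 6), 1.0, 0.0)
        p = PolysomeProfile(pos, y, np.ones(1001, dtype=int))
        from polytrans.profile_quant import PeakSegmentation
        seg = PeakSegmentation(regions={"80S": (3.0, 7.0), "POLYSOMES": (7.0, 10.0)},
                               detected_peak_positions=[5.0])
        areas = integrate_regions(p, seg)
        assert areas.area["80S"] == pytest.approx(2.0, rel=1e-2)

    def test_noiseless_profile_areas_match_closed_form(self, separated_model):
        profile, truth = simulate_profile(
            dataclasses.replace(separated_model, baseline_slope=0.0,
                                baseline_offset=0.0), seed=0)
        areas = integrate_regions(profile, segment_peaks(profile))
        for region, true_area in truth.true_region_areas.items():
            assert areas.area[region] == pytest.approx(true_area, rel=1e-3)

    def test_negative_region_clamped_with_flag(self):
        pos = np.linspace(0, 10, 200)
        y = np.exp(-0.5 * ((pos - 2) / 0.3) ** 2) - 0.2
        p = PolysomeProfile(pos, y, np.ones(200, dtype=int))
        from polytrans.profile_quant import PeakSegmentation
        seg = PeakSegmentation(regions={"80S": (0.0, 4.0), "POLYSOMES": (6.0, 10.0)},
                               detected_peak_positions=[2.0])
        areas = integrate_regions(p, seg)
        assert areas.area["POLYSOMES"] == 0.0
        assert "negative_area_clamped_POLYSOMES" in areas.qc_flags

    def test_region_outside_trace_rejected(self, noiseless_profile):
        profile, _ = noiseless_profile
        from polytrans.profile_quant import PeakSegmentation
        seg = PeakSegmentation(regions={"80S": (0.0, 4.0), "POLYSOMES": (4.0, 12.0)},
                               detected_peak_positions=[])
        with pytest.raises(ValueError, match="outside trace"):
            integrate_regions(profile, seg)


def _areas(poly, mono):
    return RegionAreas(area={"RNP": 0.1, "40S": 0.1, "60S": 0.1,
                             "80S": mono, "POLYSOMES": poly})


class TestFRP:
    def test_formula_cases(self):
        assert compute_frp(_areas(0.0, 5.0)).frp == 0.0
        assert compute_frp(_areas(3.0, 3.0)).frp == 0.5
        assert compute_frp(_areas(6.0, 2.0)).frp == 0.75

    def test_zero_denominator_is_explicit_error(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_frp(_areas(0.0, 0.0))

    def test_lighter_species_do_not_enter_the_ratio(self):
        a = _areas(3.0, 1.0)
        a.area["RNP"] = 100.0
        assert compute_frp(a).frp == 0.75

    def test_pm_ratio_variant(self):
        assert polysome_monosome_ratio(_areas(3.0, 1.5)) == 2.0

    @given(poly=st.floats(0.01, 100), mono=st.floats(0.01, 100),
           c=st.floats(0.01, 1000))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, poly, mono, c):
        f1 = compute_frp(_areas(poly, mono)).frp
        f2 = compute_frp(_areas(poly * c, mono * c)).frp
        assert f1 == pytest.approx(f2, rel=1e-12)
        assert 0.0 <= f1 <= 1.0

    @given(poly=st.floats(0.01, 100), mono=st.floats(0.01, 100),
           extra=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_polysome_mass(self, poly, mono, extra):
        assert compute_frp(_areas(poly + extra, mono)).frp > compute_frp(
            _areas(poly, mono)).frp

    def test_noiseless_pipeline_recovery(self, default_model):
        profile, truth = simulate_profile(default_model, seed=0)
        corrected = correct_baseline(profile)
        areas = integrate_regions(corrected, segment_peaks(corrected))
        assert abs(compute_frp(areas).frp - truth.true_frp) < 0.005


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

class TestCompareFRP:
    def test_identical_groups_p_near_one(self):
        g = [FRPResult(0.5), FRPResult(0.6), FRPResult(0.7)]
        assert compare_frp(g, g).p >= 0.99

    def test_separated_groups_tiny_p(self):
        a = [0.8, 0.8001, 0.7999]
        b = [0.4, 0.4001, 0.3999]
        assert compare_frp(a, b).p < 0.001

    def test_zero_variance_equal_means_convention(self):
        res = compare_frp([0.5, 0.5], [0.5, 0.5])
        assert res.p == 1.0
        assert "zero_variance_equal_means" in res.flags

    def test_matches_reference_implementation(self):
        # frozen from R t.test(x, y, var.equal=TRUE)
        x = [0.81, 0.78, 0.84, 0.75, 0.80, 0.77]
        y = [0.62, 0.58, 0.66, 0.71, 0.60, 0.64]
        res = compare_frp(x, y)
        assert res.t == pytest.approx(6.81947675103411, abs=1e-8)
        assert res.p == pytest.approx(4.62848711180067e-05, abs=1e-12)
        assert res.df == 10

    def test_one_tailed_halves_two_tailed_p(self):
        x = [0.81, 0.78, 0.84, 0.75]
        y = [0.62, 0.58, 0.66, 0.71]
        two = compare_frp(x, y, tails="two")
        one = compare_frp(x, y, tails="one")
        assert one.p == pytest.approx(two.p / 2)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(0)
        reps = 1000
        a = rng.normal(0.7, 0.05, size=(reps, 6))
        b = rng.normal(0.7, 0.05, size=(reps, 6))
        from scipy import stats
        p = stats.ttest_ind(a, b, axis=1).pvalue
        assert 0.036 <= np.mean(p < 0.05) <= 0.064


class TestCorrelatePhenotype:
    def test_exact_linear_relation(self):
        frp = [0.2, 0.4, 0.6, 0.8, 0.9]
        res = correlate_phenotype(frp, [2 * f + 1 for f in frp])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_monotone_nonlinear_relation(self):
        frp = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        res = correlate_phenotype(frp, np.exp(5 * frp))
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.pearson_r < 1.0

    def test_matches_reference_implementation(self):
        # frozen from R cor.test
        x = [0.81, 0.78, 0.84, 0.75, 0.80, 0.77]
        w = [4.1, 3.2, 5.0, 2.8, 4.4, 3.9]
        res = correlate_phenotype(x, w)
        assert res.pearson_r == pytest.approx(0.901671944269071, abs=1e-8)
        assert res.pearson_p == pytest.approx(0.0140272720070017, abs=1e-8)
        assert res.spearman_rho == pytest.approx(0.885714285714286, abs=1e-8)
        # R cor.test(..., method="spearman", exact=FALSE): t approximation
        assert res.spearman_p == pytest.approx(0.0188454810495627, abs=1e-8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_phenotype([0.5, 0.5, 0.5, 0.5], [1, 2, 3, 4])

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="unmatched"):
            correlate_phenotype({"a": 1, "b": 2, "c": 3, "d": 4},
                                {"a": 1, "b": 2, "c": 3, "e": 4})

    def test_cohort_negative_coupling_recovered(self):
        hits = 0
        for seed in range(40):
            _, recs, truth = simulate_cohort(seed=seed)
            frp = {r.mouse_id: truth.per_sample_frp[r.mouse_id] for r in recs}
            t = {r.mouse_id: r.righting_time for r in recs}
            hits += correlate_phenotype(frp, t).pearson_r < 0
        assert hits / 40 >= 0.95


class TestRelativePhenotype:
    def _rec(self, i, geno, stage, w, t):
        return PhenotypeRecord(mouse_id=f"m{i}", genotype=geno, stage=stage,
                               treatment="none", weight=w, righting_time=t)

    def test_manual_oracle_five_records(self):
        recs = [self._rec(1, "control", "late", 4.0, 4.0),
                self._rec(2, "control", "late", 6.0, 6.0),
                self._rec(3, "SMA", "late", 2.5, 20.0),
                self._rec(4, "SMA", "late", 3.0, 25.0),
                self._rec(5, "control", "early", 3.0, 3.0)]
        out = {r.mouse_id: r for r in relative_phenotype(recs)}
        # control means: late (5.0 g, 5.0 s); early (3.0 g, 3.0 s)
        assert out["m1"].relative_weight == pytest.approx(0.8)
        assert out["m3"].relative_weight == pytest.approx(0.5)
        assert out["m3"].relative_righting == pytest.approx(4.0)
        assert out["m5"].relative_weight == pytest.approx(1.0)

    def test_all_equal_weights_give_unit_relatives(self):
        recs = [self._rec(i, g, "late", 5.0, 8.0)
                for i, g in enumerate(["control", "control", "SMA"])]
        assert all(r.relative_weight == 1.0 for r in relative_phenotype(recs))

    def test_empty_control_stratum_rejected(self):
        recs = [self._rec(1, "SMA", "late", 3.0, 20.0)]
        with pytest.raises(ValueError, match="no control"):
            relative_phenotype(recs)

    def test_righting_cap_enforced_on_construction(self):
        with pytest.raises(ValueError, match="30 s"):
            self._rec(1, "control", "late", 5.0, 31.0)


# ---------------------------------------------------------------------------
# Ward.D clustering
# ---------------------------------------------------------------------------

def _brute_force_ward_d(points):
    """Independent oracle: recursive Lance-Williams Ward distance evaluated
    from the definition, greedy merge by exhaustive pair search."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)

    def cluster_dist(a, b):
        # a, b are frozensets of leaf indices; recurse on the merge history
        if len(a) == 1 and len(b) == 1:
            (i,), (j,) = a, b
            return float(np.linalg.norm(pts[i] - pts[j]))
        if len(a) < len(b):
            a, b = b, a
        # split `a` back into the two halves it was merged from
        left, right = history[a]
        na, nb, nl, nr = len(a), len(b), len(left), len(right)
        t = na + nb
        return ((nl + nb) / t * cluster_dist(left, b)
                + (nr + nb) / t * cluster_dist(right, b)
                - nb / t * cluster_dist(left, right))

    history = {}
    active = [frozenset([i]) for i in range(n)]
    merges = []
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                d = cluster_dist(active[i], active[j])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        u = active[i] | active[j]
        history[u] = (active[i], active[j])
        merges.append((active[i], active[j], d))
        active = [c for k, c in enumerate(active) if k not in (i, j)] + [u]
    return merges


class TestClusterMice:
    def test_matches_frozen_reference_tree(self, mouse_table):
        # heights frozen from R: hclust(dist(scale(x)), method="ward.D")
        res = cluster_mice(mouse_table, k=2)
        np.testing.assert_allclose(
            res.linkage[:, 2],
            [0.29713420447945987, 0.39797260385052480, 0.40440026161223308,
             3.12294581668137416, 6.44637340351516031], rtol=1e-12)
        assert res.linkage[:, :2].tolist() == [[0, 1], [2, 3], [4, 5], [7, 8], [6, 9]]
        labels = res.labels
        # R cutree at k=2: {m1, m2} vs {m3..m6}
        assert len(set(labels[:2])) == 1 and len(set(labels[2:])) == 1
        assert labels[0] != labels[2]

    def test_matches_brute_force_oracle(self, mouse_table):
        z = ((mouse_table - mouse_table.mean()) / mouse_table.std(ddof=1)).to_numpy()
        oracle = _brute_force_ward_d(z)
        Z = ward_d_linkage(z)
        np.testing.assert_allclose(Z[:, 2], [m[2] for m in oracle], rtol=1e-10)

    def test_brute_force_oracle_on_random_points(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.normal(size=(6, 3))
            oracle = _brute_force_ward_d(pts)
            Z = ward_d_linkage(pts)
            np.testing.assert_allclose(Z[:, 2], [m[2] for m in oracle], rtol=1e-10)

    def test_standardization_invariance(self, mouse_table):
        res1 = cluster_mice(mouse_table, k=2)
        scaled = mouse_table.copy()
        scaled["relative_weight"] *= 1000.0
        res2 = cluster_mice(scaled, k=2)
        np.testing.assert_allclose(res1.linkage, res2.linkage, rtol=1e-9)
        np.testing.assert_array_equal(res1.labels, res2.labels)

    def test_merge_heights_nondecreasing(self, mouse_table):
        res = cluster_mice(mouse_table, k=2)
        assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()

    def test_well_separated_groups_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.1, size=(4, 3))
        b = rng.normal(10.0, 0.1, size=(4, 3))
        df = pd.DataFrame(np.vstack([a, b]),
                          columns=["frp", "relative_weight", "relative_righting"])
        labels = cluster_mice(df, k=2).labels
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_missing_values_rejected_with_mouse_ids(self, mouse_table):
        bad = mouse_table.copy()
        bad.loc["m3", "frp"] = np.nan
        with pytest.raises(ValueError, match="m3"):
            cluster_mice(bad)
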