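"""Genotype probabilities, LOD scans, thresholds, intervals, grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fluxqtl.scan import (
    MarkerMap,
    QTLInterval,
    ScanResult,
    SegregantCross,
    find_peaks,
    genotype_probabilities,
    group_fqtls,
    haldane,
    inverse_haldane,
    lod_from_variance,
    lod_support_interval,
    merge_models,
    permutation_threshold,
    read_cross,
    scan_hk,
    scan_np,
    variance_explained,
    write_cross,
)


def _cross(cms, geno_rows, phenos=None, bps=None, chrom="1"):
    markers = [f"m{i}" for i in range(1, len(cms) + 1)]
    mk = MarkerMap(pd.DataFrame({
        "marker": markers, "chrom": chrom, "cm": cms,
        "bp": bps if bps is not None else [int(c * 3000) + 1 for c in cms]}))
    inds = [f"i{k}" for k in range(len(geno_rows))]
    geno = pd.DataFrame(geno_rows, index=inds, columns=markers, dtype=float)
    ph = pd.DataFrame(phenos if phenos is not None else {"y": np.zeros(len(inds))},
                      index=inds)
    return SegregantCross(mk, geno, ph)


class TestMapFunction:
    @given(st.floats(0.01, 300.0))
    def test_haldane_round_trip(self, d):
        assert inverse_haldane(haldane(d)) == pytest.approx(d, rel=1e-9)

    def test_limits(self):
        assert haldane(0.0) == 0.0
        assert haldane(1e9) == pytest.approx(0.5)


class TestGenotypeProbabilities:
    def test_observed_marker_zero_error_is_certain(self):
        cross = _cross([0.0, 10.0], [[1, 0], [0, 1]])
        probs = genotype_probabilities(cross, error_rate=0.0)
        at_markers = ~probs.positions["is_pseudo"].to_numpy()
        assert set(np.unique(probs.prob_a[:, at_markers])) <= {0.0, 1.0}

    def test_midway_pseudomarker_two_point_value(self):
        cross = _cross([0.0, 10.0], [[1, 1]])
        probs = genotype_probabilities(cross, step_cm=2.5, error_rate=0.0)
        mid = probs.positions.index[probs.positions["cm"] == 5.0][0]
        r = haldane(5.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r ** 2)
        assert probs.prob_a[0, mid] == pytest.approx(expected, abs=1e-12)
        assert probs.prob_a[0, mid] > 0.9

    def test_fully_missing_individual_uninformative(self):
        cross = _cross([0.0, 10.0, 20.0], [[np.nan, np.nan, np.nan], [1, 1, 1]])
        probs = genotype_probabilities(cross, error_rate=0.0)
        assert np.allclose(probs.prob_a[0], 0.5)
        at_markers = ~probs.positions["is_pseudo"].to_numpy()
        assert np.allclose(probs.prob_a[1, at_markers], 1.0)
        assert probs.prob_a[1].min() > 0.99  # pseudomarkers nearly certain

    def test_missing_interior_marker_smoothed(self):
        cross = _cross([0.0, 5.0, 10.0], [[1, np.nan, 1]])
        probs = genotype_probabilities(cross, error_rate=0.0)
        j = probs.positions.index[probs.positions["marker"] == "m2"][0]
        assert 0.99 < probs.prob_a[0, j] < 1.0

    def test_bad_step_rejected(self, tiny_cross):
        with pytest.raises(ValueError, match="step"):
            genotype_probabilities(tiny_cross, step_cm=0.0)


class TestScanHK:
    def test_hand_computed_lod(self):
        cross = _cross([0.0, 10.0], [[1, 1], [1, 1], [0, 0], [0, 0]],
                       phenos={"y": [0.0, 0.1, 0.9, 1.0]})
        probs = genotype_probabilities(cross, error_rate=0.0)
        res = scan_hk(probs, cross.phenotypes["y"])
        # RSS0 = 0.82, RSS1 = 0.01 at either marker
        assert res.lod[0] == pytest.approx(2 * np.log10(82.0), abs=1e-9)

    def test_equals_marker_regression_closed_form(self):
        rng = np.random.default_rng(5)
        n = 60
        g = rng.integers(0, 2, n).astype(float)
        y = 0.8 * g + rng.normal(size=n)
        cross = _cross([0.0], [[v] for v in g], phenos={"y": y})
        probs = genotype_probabilities(cross, error_rate=0.0)
        res = scan_hk(probs, cross.phenotypes["y"])
        r2 = stats.pearsonr(g, y).statistic ** 2
        expected = 0.5 * n * np.log10(1.0 / (1.0 - r2))
        assert res.lod[0] == pytest.approx(expected, abs=1e-9)

    def test_constant_phenotype_zero_lod(self):
        cross = _cross([0.0, 10.0], [[1, 1], [0, 0], [1, 0]],
                       phenos={"y": [3.0, 3.0, 3.0]})
        probs = genotype_probabilities(cross)
        with pytest.warns(UserWarning, match="zero phenotypic variance"):
            res = scan_hk(probs, cross.phenotypes["y"])
        assert np.all(res.lod == 0.0)

    def test_missing_phenotypes_dropped(self):
        cross = _cross([0.0], [[1], [1], [0], [0], [1]],
                       phenos={"y": [1.0, 1.1, 0.1, 0.0, np.nan]})
        probs = genotype_probabilities(cross, error_rate=0.0)
        assert scan_hk(probs, cross.phenotypes["y"]).n_used == 4


class TestScanNP:
    def test_equals_kruskal_wallis_at_informative_marker(self):
        rng = np.random.default_rng(9)
        g = np.repeat([1.0, 0.0], 12)
        y = rng.normal(size=24) + 0.9 * g
        cross = _cross([0.0], [[v] for v in g], phenos={"y": y})
        probs = genotype_probabilities(cross, error_rate=0.0)
        res = scan_np(probs, cross.phenotypes["y"])
        H = stats.kruskal(y[g == 1], y[g == 0]).statistic
        assert res.lod[0] == pytest.approx(H / (2 * np.log(10)), abs=1e-9)

    def test_tied_phenotypes_match_kruskal(self):
        g = np.repeat([1.0, 0.0], 8)
        y = np.array([1, 1, 2, 3, 3, 3, 4, 5, 1, 2, 2, 2, 3, 4, 4, 5], float)
        cross = _cross([0.0], [[v] for v in g], phenos={"y": y})
        probs = genotype_probabilities(cross, error_rate=0.0)
        res = scan_np(probs, cross.phenotypes["y"])
        H = stats.kruskal(y[g == 1], y[g == 0]).statistic
        assert res.lod[0] == pytest.approx(H / (2 * np.log(10)), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, 30).astype(float)
        y = rng.normal(size=30) + g
        cross = _cross([0.0, 20.0], np.column_stack([g, g]).tolist(),
                       phenos={"y": y})
        probs = genotype_probabilities(cross, error_rate=0.0)
        lod_raw = scan_np(probs, cross.phenotypes["y"]).lod
        lod_exp = scan_np(probs, pd.Series(np.exp(y), index=cross.individuals,
                                           name="y")).lod
        assert np.allclose(lod_raw, lod_exp, atol=1e-12)


@pytest.fixture(scope="module")
def null_setup():
    rng = np.random.default_rng(17)
    n, markers_per_chrom = 100, 21
    rows = []
    tables = []
    for chrom in "1234":
        cms = np.linspace(0, 100, markers_per_chrom)
        tables.append(pd.DataFrame({
            "marker": [f"c{chrom}m{j}" for j in range(markers_per_chrom)],
            "chrom": chrom, "cm": cms,
            "bp": (cms * 3000).astype(int) + 1}))
    mk = MarkerMap(pd.concat(tables, ignore_index=True))
    geno = np.empty((n, len(mk.table)))
    col = 0
    for chrom in "1234":
        cms = np.linspace(0, 100, markers_per_chrom)
        g = rng.integers(0, 2, n).astype(float)
        for j in range(markers_per_chrom):
            if j > 0:
                flip = rng.random(n) < haldane(cms[j] - cms[j - 1])
                g = np.where(flip, 1 - g, g)
            geno[:, col] = g
            col += 1
    genod = pd.DataFrame(geno, index=[f"i{k}" for k in range(n)],
                         columns=mk.table["marker"])
    y = pd.Series(rng.normal(size=n), index=genod.index, name="y")
    cross = SegregantCross(mk, genod, y.to_frame())
    probs = genotype_probabilities(cross, error_rate=0.0)
    return probs, y

    def test_alpha_zero_gives_maximum(self, null_setup):
        probs, y = null_setup
        t0 = permutation_threshold(probs, y, n_perm=200, alpha=0.0, seed=1)
        t5 = permutation_threshold(probs, y, n_perm=200, alpha=0.05, seed=1)
        assert t0 >= t5

    def test_monotone_in_alpha(self, null_setup):
        probs, y = null_setup
        ts = [permutation_threshold(probs, y, n_perm=300, alpha=a, seed=2)
              for a in (0.01, 0.05, 0.2, 0.5)]
        assert all(a >= b for a, b in zip(ts, ts[1:]))

    def test_null_threshold_in_published_range(self, null_setup):
        """Dense-map backcross-like null thresholds sit around 2-3 LOD."""
        probs, y = null_setup
        thr = permutation_threshold(probs, y, n_perm=1000, alpha=0.05, seed=3)
        assert 1.8 < thr < 3.5

    def test_reproducible_given_seed(self, null_setup):
        probs, y = null_setup
        a = permutation_threshold(probs, y, n_perm=200, alpha=0.05, seed=7)
        b = permutation_threshold(probs, y, n_perm=200, alpha=0.05, seed=7)
        assert a == b


class TestSupportInterval:
    def _scan(self, cms, lods, chrom="1"):
        pos = pd.DataFrame({"chrom": chrom, "cm": cms,
                            "is_pseudo": False, "marker": ""})
        return ScanResult("t", "hk", pos, np.asarray(lods, float))

    def _map(self, cms, chrom="1"):
        return MarkerMap(pd.DataFrame({
            "marker": [f"m{i}" for i in range(len(cms))], "chrom": chrom,
            "cm": cms, "bp": [int(c) * 1000 + 1 for c in cms]}))

    def test_single_spike_spans_flanking_markers(self):
        scan = self._scan([0, 10, 20, 30, 40], [0.1, 0.2, 5.0, 0.2, 0.1])
        mk = self._map([0, 10, 20, 30, 40])
        iv = lod_support_interval(scan, ("1", 20.0, 5.0), mk)
        assert (iv.start_bp, iv.end_bp) == (20001, 20001)
        assert iv.peak_cm == 20.0

    def test_plateau_at_drop_boundary_included(self):
        scan = self._scan([0, 10, 20, 30, 40], [0.1, 4.0, 5.0, 4.0, 0.1])
        mk = self._map([0, 10, 20, 30, 40])
        iv = lod_support_interval(scan, ("1", 20.0, 5.0), mk, drop=1.0)
        assert (iv.start_bp, iv.end_bp) == (10001, 30001)

    def test_peak_below_threshold_gives_no_interval(self):
        scan = self._scan([0, 10, 20], [0.1, 2.0, 0.1])
        mk = self._map([0, 10, 20])
        assert lod_support_interval(scan, ("1", 10.0, 2.0), mk,
                                    threshold=3.0) is None

    def test_pseudomarker_ends_snap_to_flanking_markers(self):
        cms = [0.0, 5.0, 10.0, 15.0, 20.0]
        scan = self._scan(cms, [0.0, 4.2, 5.0, 4.2, 0.0])
        mk = self._map([0.0, 10.0, 20.0])  # only 3 physical markers
        iv = lod_support_interval(scan, ("1", 10.0, 5.0), mk, drop=1.0)
        assert (iv.start_bp, iv.end_bp) == (1, 20001)


class TestVarianceExplained:
    @pytest.mark.parametrize("lod,n,expected", [
        (4.63, 125, 0.157), (4.71, 125, 0.159), (0.0, 125, 0.0),
    ])
    def test_reference_values(self, lod, n, expected):
        assert variance_explained(lod, n) == pytest.approx(expected, abs=5e-4)

    @given(st.floats(0.0, 12.0), st.integers(50, 500))
    def test_round_trip(self, lod, n):
        assert lod_from_variance(variance_explained(lod, n), n) == pytest.approx(
            lod, abs=1e-12)


def _mk_scan(trait, cms, lods, threshold, model, chrom="1"):
    pos = pd.DataFrame({"chrom": chrom, "cm": cms, "is_pseudo": False,
                        "marker": ""})
    return ScanResult(trait, model, pos, np.asarray(lods, float),
                      threshold=threshold)


class TestMergeModels:
    def _pair(self, lods_hk, lods_np, thr=2.0):
        cms = [0.0, 10.0, 20.0, 30.0, 40.0]
        mk = MarkerMap(pd.DataFrame({
            "marker": [f"m{i}" for i in range(5)], "chrom": "1", "cm": cms,
            "bp": [int(c) * 1000 + 1 for c in cms]}))
        hk = _mk_scan("t", cms, lods_hk, thr, "hk")
        np_ = _mk_scan("t", cms, lods_np, thr, "np")
        return hk, np_, mk

    def test_same_locus_keeps_higher_lod(self):
        hk, np_, mk = self._pair([0, 4.0, 0, 0, 0], [0, 4.2, 0, 0, 0])
        (sel,) = merge_models(hk, np_, mk)
        assert sel.model == "np" and sel.peak_lod == 4.2

    def test_disjoint_peaks_both_kept(self):
        hk, np_, mk = self._pair([4.0, 0, 0, 0, 0], [0, 0, 0, 0, 4.5])
        out = merge_models(hk, np_, mk)
        assert {(iv.model, iv.peak_lod) for iv in out} == {("hk", 4.0), ("np", 4.5)}

    def test_identical_scans_idempotent(self):
        hk, np_, mk = self._pair([0, 0, 5.0, 0, 0], [0, 0, 5.0, 0, 0])
        (sel,) = merge_models(hk, np_, mk)
        assert sel.peak_lod == 5.0

    def test_mismatched_maps_rejected(self):
        hk, _, mk = self._pair([0, 4, 0, 0, 0], [0, 4, 0, 0, 0])
        other = _mk_scan("t", [0.0, 50.0], [0, 4], 2.0, "np")
        with pytest.raises(ValueError, match="different maps"):
            merge_models(hk, other, mk)


class TestGroupFqtls:
    def _iv(self, trait, cm, lod, chrom="1"):
        return QTLInterval(trait, chrom, int(cm * 1000), int(cm * 1000) + 5000,
                           cm, lod, "hk")

    def test_nearby_peaks_share_group(self):
        groups = group_fqtls([self._iv("a", 20.0, 4.0), self._iv("b", 24.0, 3.0)])
        assert len(groups) == 1
        assert groups[0].traits == ["a", "b"]
        assert groups[0].max_lod == 4.0
        assert groups[0].name == "chr1@20.0"

    def test_distant_peaks_split(self):
        groups = group_fqtls([self._iv("a", 20.0, 4.0), self._iv("b", 35.0, 3.0)])
        assert len(groups) == 2

    def test_union_borders(self):
        g = group_fqtls([self._iv("a", 20.0, 4.0), self._iv("b", 24.0, 5.0)])[0]
        assert g.start_bp == 20000 and g.end_bp == 29000
        assert g.name == "chr1@24.0"

    def test_grouping_idempotent(self):
        ivs = [self._iv("a", 10.0, 2.5), self._iv("b", 12.0, 3.0),
               self._iv("c", 40.0, 4.0, chrom="2")]
        once = group_fqtls(ivs)
        again = group_fqtls([m for g in once for m in g.members])
        assert [(g.name, g.max_lod) for g in once] == \
               [(g.name, g.max_lod) for g in again]


class TestCrossIO:
    def test_round_trip(self, tiny_cross, tmp_path):
        p = tmp_path / "cross.csv"
        write_cross(tiny_cross, p)
        back = read_cross(p)
        pd.testing.assert_frame_equal(back.genotypes, tiny_cross.genotypes)
        pd.testing.assert_frame_equal(back.phenotypes, tiny_cross.phenotypes)
        pd.testing.assert_frame_equal(back.markers.table, tiny_cross.markers.table,
                                      check_dtype=False)

    def test_missing_genotypes_round_trip(self, tiny_cross, tmp_path):
        tiny_cross.genotypes.iloc[0, 2] = np.nan
        p = tmp_path / "cross.csv"
        write_cross(tiny_cross, p)
        back = read_cross(p)
        assert np.isnan(back.genotypes.iloc[0, 2])
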