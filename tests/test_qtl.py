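"""Genetic-map machinery and Haley-Knott interval mapping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiallele.qtl import (
    GeneticMap,
    LODCurve,
    build_map,
    estimate_rf,
    find_peaks_and_classify,
    genotype_probabilities,
    haldane_cM,
    haldane_inv,
    hk_lod,
    hk_scan,
    permutation_threshold,
)
from epiallele.io import GenomicInterval
from epiallele.simulate import SimulationConfig, simulate_annotation, simulate_population


class TestHaldane:
    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=0.499))
    def test_round_trip(self, r):
        assert haldane_inv(haldane_cM(r)) == pytest.approx(r, rel=1e-9)

    def test_known_distance(self):
        assert haldane_cM(0.125) == pytest.approx(-50 * np.log(0.75), rel=1e-12)


class TestEstimateRF:
    def test_identical_vectors(self):
        g = np.array([0, 1, 0, 1, 1] * 4, dtype=float)
        R, r = estimate_rf(g, g)
        assert R == 0.0 and r == 0.0

    def test_selfed_ril_correction(self):
        g1 = np.zeros(100)
        g2 = np.zeros(100)
        g2[:20] = 1  # 20 discordant of 100
        R, r = estimate_rf(g1, g2)
        assert R == pytest.approx(0.2)
        assert r == pytest.approx(0.2 / (2 * 0.8))

    def test_unlinked_caps_at_half(self):
        g1 = np.array([0, 1] * 20, dtype=float)
        g2 = np.array([1, 0] * 20, dtype=float)
        _, r = estimate_rf(g1, g2)
        assert r == 0.5

    def test_no_complete_pairs_errors(self):
        g = np.full(20, np.nan)
        with pytest.raises(ValueError):
            estimate_rf(g, g)


@pytest.fixture(scope="module")
def population():
    cfg = SimulationConfig(n_lines=150)
    rng = np.random.default_rng(11)
    genes, het, markers, classes = simulate_annotation(cfg, rng)
    geno, h, bks = simulate_population(cfg, markers, rng)
    mpos = pd.DataFrame(
        [(m.id, m.interval.chrom, m.interval.midpoint) for m in markers],
        columns=["marker", "chrom", "bp"],
    )
    return cfg, genes, het, markers, geno.astype(float), mpos


class TestBuildMap:
    def test_independent_markers_kept(self, population):
        _, _, _, markers, geno, mpos = population
        gmap = build_map(geno, mpos)
        assert len(gmap.markers) == len(markers)
        for chrom, sub in gmap.markers.groupby("chrom"):
            assert sub["cM"].iloc[0] == 0.0
            assert (np.diff(sub["cM"]) >= 0).all()

    def test_duplicated_marker_rejected(self, population):
        _, _, _, _, geno, mpos = population
        geno = geno.copy()
        mpos = mpos.copy()
        # duplicate a Chr1 marker onto Chr2 (stepped in later by bp order)
        geno["dup"] = geno["m000"]
        mpos = pd.concat(
            [mpos, pd.DataFrame([("dup", "Chr2", 2_999_999)],
                                columns=["marker", "chrom", "bp"])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="rejected"):
            gmap = build_map(geno, mpos)
        assert "dup" not in set(gmap.markers["marker"])
        assert "m000" in set(gmap.markers["marker"])

    def test_adjacent_spacing_haldane(self):
        """r = 0.125 between adjacent markers gives 14.38 cM spacing."""
        rng = np.random.default_rng(3)
        n = 4000  # large so the empirical R is essentially exact
        g1 = rng.integers(0, 2, n).astype(float)
        flip = rng.random(n) < 0.2  # R = 0.2 -> r = 0.125
        g2 = np.where(flip, 1 - g1, g1)
        geno = pd.DataFrame({"a": g1, "b": g2})
        mpos = pd.DataFrame([("a", "Chr1", 100), ("b", "Chr1", 10_000)],
                            columns=["marker", "chrom", "bp"])
        gmap = build_map(geno, mpos)
        expected = -50 * np.log(1 - 2 * 0.125)
        assert gmap.markers["cM"].iloc[1] == pytest.approx(expected, rel=0.08)


class TestGenotypeProb:
    def test_at_typed_marker(self):
        p = genotype_probabilities(np.array([0.0, 10.0]), np.array([1.0, 0.0]),
                                   np.array([0.0, 10.0]))
        assert p[0] == pytest.approx(1.0) and p[1] == pytest.approx(0.0)

    def test_midpoint_between_discordant_flanks(self):
        p = genotype_probabilities(np.array([0.0, 10.0]), np.array([1.0, 0.0]),
                                   np.array([5.0]))
        assert p[0] == pytest.approx(0.5)

    def test_midpoint_between_concordant_ddm1_flanks(self):
        p = genotype_probabilities(np.array([0.0, 10.0]), np.array([1.0, 1.0]),
                                   np.array([5.0]))
        assert p[0] > 0.9

    def test_missing_flank_uses_single_informative(self):
        p = genotype_probabilities(np.array([0.0, 10.0]), np.array([np.nan, 1.0]),
                                   np.array([9.0]))
        # close to the informative right flank
        assert p[0] > 0.9


class TestHKScan:
    def test_worked_fixture_matches_direct_least_squares(self):
        """LOD at a marker equals (n/2) log10(RSS0/RSS1) from explicit OLS."""
        x = np.array([0, 0, 1, 1, 0, 1, 0, 1], dtype=float)
        y = np.array([0.3, 0.1, 0.9, 1.2, 0.2, 0.8, 0.4, 1.1])
        n = len(y)
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(((y - X @ beta) ** 2).sum())
        rss0 = float(((y - y.mean()) ** 2).sum())
        expected = (n / 2) * np.log10(rss0 / rss1)
        assert hk_lod(x, y) == pytest.approx(expected, rel=1e-10)

    def test_perfect_signal_caps_at_marker(self, population):
        _, _, _, _, geno, mpos = population
        gmap = build_map(geno, mpos)
        marker = "m025"
        y = geno[marker].to_numpy(dtype=float)
        curve = hk_scan(gmap, geno, y, trait="perfect")
        mrow = gmap.markers[gmap.markers["marker"] == marker].iloc[0]
        assert curve.lod.max() >= 49.0
        # the grid point nearest the marker sits at the global maximum (cap)
        sel = (curve.grid["chrom"] == mrow["chrom"]).to_numpy()
        local = np.abs(curve.grid.loc[sel, "cM"] - mrow["cM"]).idxmin()
        assert curve.lod[local] == pytest.approx(curve.lod.max())

    def test_grid_marker_consistency(self, population):
        """Scan LOD at a marker's exact position equals the single-marker
        regression LOD."""
        _, _, _, _, geno, mpos = population
        gmap = build_map(geno, mpos)
        rng = np.random.default_rng(0)
        y = 0.5 * geno["m030"].to_numpy(dtype=float) + rng.normal(size=len(geno))
        row = gmap.markers[gmap.markers["marker"] == "m030"].iloc[0]
        sub = gmap.markers[gmap.markers["chrom"] == row["chrom"]]
        states = geno[sub["marker"].tolist()].to_numpy(dtype=float)
        probs = np.array([
            genotype_probabilities(sub["cM"].to_numpy(), states[i],
                                   np.array([row["cM"]]))[0]
            for i in range(len(geno))
        ])
        # at a typed marker the conditional probability is the genotype itself
        assert np.allclose(probs, geno["m030"].to_numpy(dtype=float))
        assert hk_lod(probs, y) == pytest.approx(
            hk_lod(geno["m030"].to_numpy(dtype=float), y)
        )

    def test_constant_phenotype_zero_curve(self, population):
        _, _, _, _, geno, mpos = population
        gmap = build_map(geno, mpos)
        with pytest.warns(UserWarning, match="constant"):
            curve = hk_scan(gmap, geno, np.full(len(geno), 1.0))
        assert (curve.lod == 0).all()


class TestPermutationThreshold:
    def test_deterministic_given_seed(self, population):
        _, _, _, _, geno, mpos = population
        gmap = build_map(geno, mpos)
        rng = np.random.default_rng(8)
        y = rng.normal(size=len(geno))
        t1 = permutation_threshold(gmap, geno, y, n_perm=120, seed=5)
        t2 = permutation_threshold(gmap, geno, y, n_perm=120, seed=5)
        assert t1 == t2

    def test_alpha_one_gives_minimum(self, population):
        _, _, _, _, geno, mpos = population
        gmap = build_map(geno, mpos)
        rng = np.random.default_rng(9)
        y = rng.normal(size=len(geno))
        t = permutation_threshold(gmap, geno, y, n_perm=120, alpha=1.0, seed=5)
        t_low = permutation_threshold(gmap, geno, y, n_perm=120, alpha=0.05, seed=5)
        assert t <= t_low

    def test_null_threshold_in_sane_band(self, population):
        """A null trait over 150 lines yields a genome-wide threshold in the
        2-4 LOD range typical of these designs."""
        _, _, _, _, geno, mpos = population
        gmap = build_map(geno, mpos)
        rng = np.random.default_rng(10)
        y = rng.normal(size=len(geno))
        t = permutation_threshold(gmap, geno, y, n_perm=200, seed=3)
        assert 2.0 <= t <= 4.0


class TestScanAllGenes:
    def test_shared_trans_qtl_recovered_across_genes(self, population):
        """40 genes driven by one pericentromeric marker: nearly all recover
        a hit, mostly in the heterochromatin compartment, and the
        hits-per-gene histogram is consistent with the hit table."""
        from epiallele.qtl import scan_all_genes

        cfg, genes, het, markers, geno, mpos = population
        gmap = build_map(geno, mpos)
        qm = next(
            m.id for m in markers
            if m.interval.chrom == "Chr1"
            and het[0].start <= m.interval.midpoint < het[0].end
        )
        rng = np.random.default_rng(12)
        x = geno[qm].to_numpy()
        driven = [f"d{i}" for i in range(40)]
        nulls = [f"n{i}" for i in range(10)]
        pheno = pd.DataFrame(
            {g: 1.3 * x + rng.normal(size=len(x)) for g in driven}
            | {g: rng.normal(size=len(x)) for g in nulls}
        ).T
        pheno.columns = geno.index
        table, summary = scan_all_genes(gmap, geno, pheno, threshold=3.0,
                                        het_intervals=het)
        driven_hits = table[table["trait"].isin(driven)]
        assert driven_hits["trait"].nunique() >= 36  # >= 90% of the 40
        assert (driven_hits["compartment"] == "heterochromatin").mean() >= 0.8
        assert sum(k * v for k, v in summary["hits_per_gene_hist"].items()) == len(table)
        assert summary["n_genes_with_hit"] == table["trait"].nunique()

    def test_constant_phenotypes_skipped(self, population):
        from epiallele.qtl import scan_all_genes

        _, _, het, _, geno, mpos = population
        gmap = build_map(geno, mpos)
        pheno = pd.DataFrame({"flat": np.ones(len(geno))}).T
        pheno.columns = geno.index
        table, summary = scan_all_genes(gmap, geno, pheno, threshold=3.0)
        assert summary["n_genes_scanned"] == 0
        assert table.empty


class TestPeaks:
    def _curve(self, lod):
        grid = pd.DataFrame(
            {"chrom": "Chr1", "cM": np.arange(len(lod), dtype=float),
             "bp": (np.arange(len(lod)) * 10_000).astype(np.int64)}
        )
        return LODCurve("t", grid, np.asarray(lod, dtype=float))

    def test_subthreshold_curve_no_hits(self):
        curve = self._curve(np.linspace(0, 2.4, 30))
        assert find_peaks_and_classify(curve, 3.0) == []

    def test_single_peak_with_support(self):
        lod = np.concatenate([np.linspace(0, 6, 10), np.linspace(6, 0, 10)[1:]])
        hits = find_peaks_and_classify(self._curve(lod), 3.0)
        assert len(hits) == 1
        h = hits[0]
        assert h.lod == pytest.approx(6.0)
        assert h.support_cM[0] <= h.peak_cM <= h.support_cM[1]

    def test_twin_peaks_need_deep_valley(self):
        lod = np.array([0, 5, 4.5, 5, 0], dtype=float)  # shallow valley: one peak
        assert len(find_peaks_and_classify(self._curve(lod), 3.0)) == 1
        lod = np.array([0, 5, 1, 5, 0], dtype=float)  # deep valley: two peaks
        assert len(find_peaks_and_classify(self._curve(lod), 3.0)) == 2

    def test_cis_trans_and_compartment(self):
        lod = np.concatenate([np.zeros(5), [6.0], np.zeros(5)])
        curve = self._curve(lod)
        het = [GenomicInterval("Chr1", 40_000, 80_000)]
        hits = find_peaks_and_classify(curve, 3.0, gene_locus=("Chr4", 50_000),
                                       het_intervals=het)
        assert hits[0].relation == "trans"
        assert hits[0].compartment == "heterochromatin"
        hits = find_peaks_and_classify(curve, 3.0, gene_locus=("Chr1", 60_000),
                                       het_intervals=het)
        assert hits[0].relation == "cis"
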