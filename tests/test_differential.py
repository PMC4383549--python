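"""Sliding-window counting, G-test, BH-FDR, dynamic sites and peaks."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from chromadelta.core_io import Coverage, GenomeTable, GenomicInterval
from chromadelta.differential import (
    bh_fdr,
    call_dynamic_sites,
    call_peaks_simple,
    count_windows,
    g_test,
    hotspot_clusters,
    window_stats,
)
from chromadelta.differential import DynamicSite
from conftest import make_readset

GI = GenomicInterval


def brute_force_window_count(position: int, length: int, w: int, s: int) -> int:
    """Enumerate every window [k*s, k*s+w), k >= 0, containing the read."""
    return sum(
        1 for k in range((length - 1) // s + 1)
        if k * s <= position < k * s + w
    )


class TestCountWindows:
    def test_single_read_window_membership(self):
        """A midpoint lands in every window containing it: ceil(w/s) windows
        for interior positions, fewer near the chromosome start."""
        genome = GenomeTable({"chr1": 5000})
        for pos in (100, 1000):
            rs = [make_readset("a", "r1", {"chr1": [pos]}),
                  make_readset("b", "r1", {"chr1": []})]
            counts = count_windows(rs, genome, 200, 20)
            assert counts["count_c1"].sum() == brute_force_window_count(pos, 5000, 200, 20)
        assert brute_force_window_count(1000, 5000, 200, 20) == 10  # == ceil(w/s)
        assert brute_force_window_count(100, 5000, 200, 20) == 6    # start-clipped

    def test_no_reads_all_zero(self):
        genome = GenomeTable({"chr1": 1000})
        rs = [make_readset("a", "r1", {"chr1": []}),
              make_readset("b", "r1", {"chr1": []})]
        counts = count_windows(rs, genome, 200, 20)
        assert counts["count_c1"].sum() == 0
        assert counts["count_c2"].sum() == 0

    def test_replicates_pool_within_condition(self):
        genome = GenomeTable({"chr1": 1000})
        rng = np.random.default_rng(0)
        reps = [make_readset("a", f"r{i}", {"chr1": rng.integers(0, 1000, 50)})
                for i in range(3)]
        singles = [count_windows([r, make_readset("b", "r1", {"chr1": []})],
                                 genome, 200, 20)["count_c1"] for r in reps]
        pooled = count_windows(
            reps + [make_readset("b", "r1", {"chr1": []})], genome, 200, 20)
        assert (pooled["count_c1"] == sum(singles)).all()

    def test_invalid_grid_rejected(self):
        genome = GenomeTable({"chr1": 1000})
        rs = [make_readset("a", "r1", {"chr1": []}),
              make_readset("b", "r1", {"chr1": []})]
        with pytest.raises(ValueError):
            count_windows(rs, genome, 0, 20)


class TestGTest:
    def test_balanced_counts_give_zero(self):
        g, p, lfc = g_test(10, 10, 100, 100)
        assert g == 0.0
        assert p == 1.0
        assert lfc == 0.0

    def test_extreme_split_closed_form(self):
        """a=0, b=20 at equal library sizes: G = 2*20*ln2 exactly."""
        g, p, _ = g_test(0, 20, 1000, 1000)
        assert g == pytest.approx(2 * 20 * np.log(2), abs=1e-12)
        assert p == pytest.approx(1.3978e-7, rel=1e-3)

    def test_swap_symmetry(self):
        g1, p1, l1 = g_test(7, 19, 500, 700)
        g2, p2, l2 = g_test(19, 7, 700, 500)
        assert g1 == pytest.approx(g2)
        assert p1 == pytest.approx(p2)
        assert l1 == pytest.approx(-l2)

    def test_exhaustive_oracle_all_counts_to_50(self):
        """G equals the generic 2*sum O ln(O/E) over the 2-cell layout for
        all 0 <= a,b <= 50, and the chi2(1) p matches numerical integration
        of the density."""
        n1, n2 = 900.0, 1100.0
        a = np.repeat(np.arange(51), 51).astype(float)
        b = np.tile(np.arange(51), 51).astype(float)
        g, p, _ = g_test(a, b, n1, n2)
        # independent oracle: literal 2 * sum O*ln(O/E) with 0 ln 0 = 0
        total = a + b
        ea, eb = total * n1 / (n1 + n2), total * n2 / (n1 + n2)
        g_oracle = np.zeros_like(g)
        for i in range(len(a)):
            acc = 0.0
            for o, e in ((a[i], ea[i]), (b[i], eb[i])):
                if o > 0:
                    acc += o * np.log(o / e)
            g_oracle[i] = 2 * acc
        assert np.max(np.abs(g - g_oracle)) < 1e-10
        # p oracle by integrating the chi-square density on distinct G values
        chi2_pdf = lambda x: stats.chi2.pdf(x, 1)
        for gv, pv in list({round(float(gv), 12): (float(gv), float(pv))
                            for gv, pv in zip(g, p)}.values())[::7]:
            if gv == 0.0:
                assert pv == 1.0
                continue
            tail, _ = integrate.quad(chi2_pdf, gv, np.inf, limit=500,
                                     epsabs=1e-12, epsrel=1e-12)
            assert pv == pytest.approx(tail, abs=1e-8)

    def test_agrees_with_pearson_chisquare_for_large_counts(self):
        g, _, _ = g_test(5000, 5200, 1e6, 1e6)
        expected = (5000 + 5200) / 2
        pearson = (5000 - expected) ** 2 / expected + (5200 - expected) ** 2 / expected
        assert g == pytest.approx(pearson, rel=0.01)

    def test_invalid_library_sizes(self):
        with pytest.raises(ValueError):
            g_test(1, 2, 0, 10)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200) ** 2
        q = bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert q == pytest.approx(q_sm)
        perm = rng.permutation(200)
        assert bh_fdr(p[perm]) == pytest.approx(q[perm])


def _stats_frame(rows, n1=10_000, n2=10_000):
    df = pd.DataFrame(rows)
    df.attrs["conditions"] = ["c1", "c2"]
    df.attrs["library_sizes"] = {"c1": n1, "c2": n2}
    return df


def _window_row(chrom, start, end, a, b):
    g, p, lfc = g_test(a, b, 10_000, 10_000)
    return dict(chrom=chrom, start=start, end=end, count_c1=a, count_c2=b,
                G=g, p=p, q=np.nan, log2fc=lfc,
                direction=int(np.sign(b - a)), tested=True)


class TestCallDynamicSites:
    def test_no_significant_windows_empty(self):
        df = _stats_frame([_window_row("chr1", 0, 200, 30, 31)])
        assert call_dynamic_sites(df) == []

    def test_directional_partition(self):
        """3 overlapping strong up-windows and 1 distant strong down-window
        yield exactly one up site (their per-base union) and one down site."""
        rows = [
            _window_row("chr1", 0, 200, 5, 300),
            _window_row("chr1", 100, 300, 5, 300),
            _window_row("chr1", 200, 400, 5, 300),
            _window_row("chr1", 5000, 5200, 300, 5),
        ]
        df = _stats_frame(rows)
        sites = call_dynamic_sites(df, q_threshold=0.025, screen_p=1e-3)
        assert len(sites) == 2
        up = next(s for s in sites if s.direction == 1)
        down = next(s for s in sites if s.direction == -1)
        # brute-force per-base union of the up windows
        raster = np.zeros(6000, dtype=bool)
        for r in rows[:3]:
            raster[r["start"]:r["end"]] = True
        assert (up.interval.start, up.interval.end) == (
            raster.argmax(), len(raster) - raster[::-1].argmax())
        assert (down.interval.start, down.interval.end) == (5000, 5200)
        assert up.n_windows == 3 and down.n_windows == 1

    def test_order_invariance(self):
        rows = [
            _window_row("chr1", 0, 200, 5, 300),
            _window_row("chr1", 100, 300, 5, 300),
            _window_row("chr2", 0, 200, 300, 5),
        ]
        a = call_dynamic_sites(_stats_frame(rows))
        b = call_dynamic_sites(_stats_frame(rows[::-1]))
        assert a == b

    def test_sites_covered_by_significant_windows(self):
        """No site extends beyond the union of its screened windows."""
        rows = [
            _window_row("chr1", 0, 200, 5, 300),
            _window_row("chr1", 400, 600, 4, 280),
        ]
        sites = call_dynamic_sites(_stats_frame(rows))
        spans = {(s.interval.start, s.interval.end) for s in sites}
        assert spans == {(0, 200), (400, 600)}


class TestHotspots:
    def test_dense_cluster_found_by_poisson_tail(self):
        genome = GenomeTable({"chr1": 10_000_000})
        sites = [DynamicSite(GI("chr1", 50_000 + i * 5000, 50_200 + i * 5000),
                             1, 1e-4, 1.0, 1) for i in range(10)]
        sites += [DynamicSite(GI("chr1", 3_000_000 + i * 900_000,
                                 3_000_200 + i * 900_000), 1, 1e-4, 1.0, 1)
                  for i in range(7)]
        clusters = hotspot_clusters(sites, genome, window_bp=1_000_000)
        assert len(clusters) == 1
        assert clusters[0].n_sites == 10
        # direct Poisson tail at the genome-wide rate
        lam = 17 / 10
        assert clusters[0].p == pytest.approx(stats.poisson.sf(9, lam))

    def test_single_site_no_cluster(self):
        genome = GenomeTable({"chr1": 2_000_000})
        sites = [DynamicSite(GI("chr1", 100, 300), 1, 1e-4, 1.0, 1)]
        assert hotspot_clusters(sites, genome) == []

    def test_null_calibration_of_tile_pvalues(self):
        """Uniform sites: fraction of tiles flagged at p<0.05 stays near
        or below nominal (simulation oracle)."""
        rng = np.random.default_rng(11)
        genome = GenomeTable({"chr1": 50_000_000})
        n_tiles = 50
        flagged = 0
        total = 0
        for _ in range(20):
            pos = np.sort(rng.integers(0, 50_000_000 - 200, 150))
            sites = [DynamicSite(GI("chr1", int(p), int(p) + 200), 1, 1e-4, 1.0, 1)
                     for p in pos]
            lam = len(sites) / n_tiles
            counts = np.bincount(pos // 1_000_000, minlength=n_tiles)
            p_vals = stats.poisson.sf(counts - 1, lam)
            flagged += int(((p_vals < 0.05) & (counts >= 2)).sum())
            total += n_tiles
        assert flagged / total <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


class TestCallPeaksSimple:
    def _coverage(self, segments):
        return Coverage({"chr1": tuple(np.array(x) for x in zip(*segments))})

    def test_flat_below_threshold_no_peaks(self):
        cov = self._coverage([(0, 1000, 1.0)])
        assert call_peaks_simple(cov, threshold=5.0) == []

    def test_nearby_plateaus_merge(self):
        cov = self._coverage([(0, 100, 9.0), (200, 300, 9.0)])
        peaks = call_peaks_simple(cov, threshold=5.0, merge_gap=140)
        assert [(p.start, p.end) for p in peaks] == [(0, 300)]

    def test_wide_plateau_removed(self):
        cov = self._coverage([(0, 6000, 9.0)])
        assert call_peaks_simple(cov, threshold=5.0) == []

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            call_peaks_simple(self._coverage([(0, 10, 1.0)]), 0.0)


class TestWindowStatsIntegration:
    def test_min_count_marks_untested_and_shrinks_fdr_denominator(self):
        genome = GenomeTable({"chr1": 2000})
        rng = np.random.default_rng(5)
        rs = [make_readset("a", "r1", {"chr1": rng.integers(0, 2000, 120)}),
              make_readset("b", "r1", {"chr1": rng.integers(0, 2000, 120)})]
        counts = count_windows(rs, genome, 200, 200)
        out = window_stats(counts, min_count=20)
        untested = out[~out["tested"]]
        assert (untested["count_c1"] + untested["count_c2"] < 20).all()
        assert untested["q"].isna().all()
        tested = out[out["tested"]]
        assert tested["q"].to_numpy() == pytest.approx(bh_fdr(tested["p"]))
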