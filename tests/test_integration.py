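"""Promoter classes, padded intersection, gene coupling, QN, paired DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromadelta.core_io import (
    ExpressionMatrix,
    Gene,
    GenomeTable,
    GenomicInterval,
    GwasLocus,
)
from chromadelta.differential import DynamicSite
from chromadelta.integration import (
    classify_promoter,
    couple_genes,
    format_pct,
    genes_near_loci,
    intersect_dynamic,
    paired_de,
    quantile_normalize,
    quartile_concordance,
    tss_profile,
    tss_signal_test,
)
from conftest import make_readset

GI = GenomicInterval


def site(chrom, start, end, direction=1, log2fc=None):
    return DynamicSite(GI(chrom, start, end), direction, 1e-5,
                       log2fc if log2fc is not None else float(direction), 1)


class TestClassifyPromoter:
    def test_upstream_vs_flank_modes(self, toy_genes):
        # geneA + strand, TSS 10,000: 500 bp upstream -> promoter in both
        upstream = site("chr1", 9_400, 9_600)
        # 500 bp downstream -> distal in upstream mode, promoter in flank
        downstream = site("chr1", 10_400, 10_600)
        for mode, expected in (("upstream1kb", {"up"}), ("flank1kb", {"up", "down"})):
            promoter, distal, _ = classify_promoter(
                [upstream, downstream], toy_genes, mode)
            labels = set()
            if upstream in promoter:
                labels.add("up")
            if downstream in promoter:
                labels.add("down")
            assert labels == expected

    def test_unknown_mode_rejected(self, toy_genes):
        with pytest.raises(ValueError):
            classify_promoter([site("chr1", 0, 100)], toy_genes, "nearby")

    def test_report_percentages(self):
        assert format_pct(12_754, 13_516) == 94
        assert format_pct(7_276, 13_516) == 54
        assert format_pct(9_907, 10_212) == 97


class TestIntersectDynamic:
    def test_padding_bridges_250bp_gap(self):
        chrom = [site("chr1", 1000, 1500, 1)]
        enh = [site("chr1", 1750, 2200, 1)]
        pairs, report = intersect_dynamic(chrom, enh, pad=300)
        assert len(pairs) == 1
        assert bool(pairs.iloc[0]["concordant"])
        # without padding they do not touch
        pairs0, _ = intersect_dynamic(chrom, enh, pad=0)
        assert len(pairs0) == 0

    def test_discordant_pair_counted_but_not_concordant(self):
        pairs, report = intersect_dynamic(
            [site("chr1", 1000, 1500, 1)], [site("chr1", 1400, 1900, -1)], 300)
        assert len(pairs) == 1
        assert report.n_enhancer_sites_overlapped == 1
        assert report.n_concordant == 0

    def test_percentage_full_precision(self):
        """1817 of 2004 concordant enhancer sites -> 90.67% before any
        presentation rounding (published reports truncate to 90.6)."""
        report_pct = 100.0 * 1817 / 2004
        assert round(report_pct, 2) == 90.67
        chrom = [site("chr1", i * 1000, i * 1000 + 100, 1) for i in range(4)]
        enh = [site("chr1", i * 1000, i * 1000 + 100, 1 if i < 3 else -1)
               for i in range(4)]
        _, report = intersect_dynamic(chrom, enh, pad=0)
        assert report.pct_concordant == pytest.approx(75.0)

    def test_each_pair_appears_once(self):
        chrom = [site("chr1", 0, 500, 1), site("chr1", 400, 900, 1)]
        enh = [site("chr1", 200, 700, 1)]
        pairs, report = intersect_dynamic(chrom, enh, pad=0)
        assert len(pairs) == 2
        assert pairs.duplicated(["chromatin_idx", "enhancer_idx"]).sum() == 0
        assert report.n_enhancer_sites_overlapped == 1


class TestCoupleGenes:
    def test_r_squared_consistency(self):
        assert round(0.67 ** 2, 2) == 0.45

    def test_near_perfect_synthetic_coupling(self, toy_genes):
        de = pd.DataFrame({"log2fc": [2.0, -1.0]}, index=["geneA", "geneB"])
        sites = [site("chr1", 9_900, 10_100, 1, 2.0),
                 site("chr1", 10_100, 10_300, 1, 2.2),
                 site("chr1", 49_800, 50_000, -1, -1.1)]
        couplings, r, r2 = couple_genes(sites, de, toy_genes)
        by_gene = {c.gene_id: c for c in couplings}
        assert by_gene["geneA"].n_sites == 2
        assert by_gene["geneA"].mean_site_log2fc == pytest.approx(2.1)
        assert np.isnan(r)  # < 3 coupled genes: correlation undefined

    def test_shuffled_labels_kill_correlation(self):
        rng = np.random.default_rng(8)
        genes = [Gene(f"g{i:03d}", GI("chr1", i * 2000, i * 2000 + 1000, "+"), "+")
                 for i in range(60)]
        folds = rng.normal(0, 1, 60)
        sites = [site("chr1", i * 2000, i * 2000 + 500, int(np.sign(f)) or 1, f)
                 for i, f in enumerate(folds)]
        de = pd.DataFrame({"log2fc": folds}, index=[g.gene_id for g in genes])
        _, r, _ = couple_genes(sites, de, genes)
        assert r == pytest.approx(1.0, abs=1e-9)
        shuffled = de.copy()
        shuffled.index = rng.permutation(shuffled.index)
        _, r_shuf, _ = couple_genes(sites, shuffled, genes)
        assert abs(r_shuf) < 0.35  # MC band ~ 2.6/sqrt(60)


class TestQuartileConcordance:
    def _genes(self, n=16):
        return [Gene(f"g{i:03d}", GI("chr1", i * 2000, i * 2000 + 1000, "+"), "+")
                for i in range(n)]

    def test_all_coupled_all_one(self):
        genes = self._genes()
        folds = np.concatenate([np.linspace(0.5, 4, 8), -np.linspace(0.5, 4, 8)])
        de = pd.DataFrame({"log2fc": folds}, index=[g.gene_id for g in genes])
        sites = [site("chr1", i * 2000, i * 2000 + 500, int(np.sign(f)))
                 for i, f in enumerate(folds)]
        out = quartile_concordance(de, sites, genes)
        assert (out["proportion"] == 1.0).all()
        assert set(out["n_genes"]) == {2}

    def test_no_sites_all_zero(self):
        genes = self._genes()
        folds = np.concatenate([np.linspace(0.5, 4, 8), -np.linspace(0.5, 4, 8)])
        de = pd.DataFrame({"log2fc": folds}, index=[g.gene_id for g in genes])
        out = quartile_concordance(de, [], genes)
        assert (out["proportion"] == 0.0).all()

    def test_too_few_genes_per_direction(self):
        genes = self._genes(4)
        de = pd.DataFrame({"log2fc": [1, 2, 3, -1.0]},
                          index=[g.gene_id for g in genes])
        with pytest.raises(ValueError):
            quartile_concordance(de, [], genes)

    def test_monotone_coupling_gives_nondecreasing_proportions(self):
        """Concordant-site probability grows with |fold| in the simulation,
        so quartile proportions must not decrease."""
        rng = np.random.default_rng(9)
        genes = self._genes(80)
        folds = np.concatenate([rng.uniform(0.2, 4, 40), -rng.uniform(0.2, 4, 40)])
        de = pd.DataFrame({"log2fc": folds}, index=[g.gene_id for g in genes])
        sites = []
        for i, f in enumerate(folds):
            if rng.random() < min(1.0, abs(f) / 4):
                sites.append(site("chr1", i * 2000, i * 2000 + 500,
                                  int(np.sign(f))))
        out = quartile_concordance(de, sites, genes)
        for _, sub in out.groupby("direction"):
            props = sub.sort_values("quartile")["proportion"].to_numpy()
            assert (np.diff(props) >= -0.26).all()  # allow one-gene jitter

    def test_quartile_sizes_balanced(self):
        genes = self._genes(11)
        folds = np.concatenate([np.linspace(0.5, 3, 7), [-1, -2, -3, -4]])
        de = pd.DataFrame({"log2fc": folds}, index=[g.gene_id for g in genes])
        out = quartile_concordance(de, [], genes)
        up_sizes = out[out["direction"] == "up"]["n_genes"].tolist()
        assert sorted(up_sizes) == [1, 2, 2, 2]


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["s1"].tolist() == [2.5, 3.5, 4.5]
        assert out["s2"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_fixed_point_and_idempotence(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)
        rng = np.random.default_rng(10)
        m2 = pd.DataFrame(rng.normal(size=(50, 4)))
        once = quantile_normalize(m2)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_columns_share_sorted_vector(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(40, 5)))
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.sort(out[:, j]) == pytest.approx(ref)

    def test_ties_get_mean_of_reference(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame())


def _expression(values, conditions=("m", "f")):
    n_genes, n_donors = values[conditions[0]].shape
    cols, data = [], []
    for cond in conditions:
        for d in range(n_donors):
            cols.append(f"{cond}:D{d}")
            data.append(values[cond][:, d])
    vals = pd.DataFrame(np.column_stack(data),
                        index=[f"g{i}" for i in range(n_genes)], columns=cols)
    samples = pd.DataFrame({
        "sample": cols,
        "condition": [c.split(":")[0] for c in cols],
        "donor": [c.split(":")[1] for c in cols],
    })
    return ExpressionMatrix(vals, samples)


class TestPairedDe:
    def test_constant_shift_detected_with_exact_fold(self):
        base = np.tile(np.array([[5.0, 6.0, 7.0]]), (3, 1))
        shifted = base + np.array([[2.0], [0.0], [0.0]])
        expr = _expression({"m": base, "f": shifted})
        out = paired_de(expr)
        assert out.loc["g0", "log2fc"] == pytest.approx(2.0)
        assert out.loc["g1", "log2fc"] == 0.0
        assert out.loc["g1", "degenerate"]

    def test_t_statistic_matches_hand_computation(self):
        m = np.array([[1.0, 2.0, 3.0]])
        f = np.array([[1.5, 2.2, 3.9]])
        expr = _expression({"m": m, "f": f})
        out = paired_de(expr)
        d = (f - m)[0]
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert out.loc["g0", "t"] == pytest.approx(t_hand)
        assert out.loc["g0", "p"] == pytest.approx(
            2 * stats.t.sf(abs(t_hand), df=2))

    def test_needs_two_donors(self):
        expr = _expression({"m": np.array([[1.0]]), "f": np.array([[2.0]])})
        with pytest.raises(ValueError):
            paired_de(expr)


class TestTssProfile:
    def test_uniform_coverage_flat_profile(self, toy_genes):
        genome = GenomeTable({"chr1": 100_000, "chr2": 50_000})
        rng = np.random.default_rng(12)
        rs = [make_readset(c, "r1", {
            "chr1": rng.integers(0, 100_000, 30_000),
            "chr2": rng.integers(0, 50_000, 15_000),
        }) for c in ("m", "f")]
        per_gene, profile = tss_profile(rs, toy_genes, genome)
        vals = profile["m"].to_numpy()
        assert vals.std() / vals.mean() < 0.5

    def test_strand_flip_mirrors_profile(self):
        genome = GenomeTable({"chr1": 100_000})
        plus = Gene("p", GI("chr1", 50_000, 60_000, "+"), "+")
        minus = Gene("n", GI("chr1", 40_001, 50_001, "-"), "-")  # TSS 50,000
        skewed = np.arange(50_200, 50_800)  # 3' of the + TSS
        rs = [make_readset("m", "r1", {"chr1": skewed}),
              make_readset("f", "r1", {"chr1": skewed})]
        pg_plus, prof_plus = tss_profile(rs, [plus], genome)
        pg_minus, prof_minus = tss_profile(rs, [minus], genome)
        assert prof_plus["m"].to_numpy() == pytest.approx(
            prof_minus["m"].to_numpy()[::-1])

    def test_promoter_doubling_detected_by_paired_test(self):
        genome = GenomeTable({"chr1": 200_000})
        genes = [Gene(f"g{i}", GI("chr1", 10_000 + i * 8000,
                                  14_000 + i * 8000, "+"), "+")
                 for i in range(20)]
        rng = np.random.default_rng(13)
        base = rng.integers(0, 200_000, 40_000)
        extra = np.concatenate([
            rng.integers(g.tss - 1000, g.tss + 1000, 200) for g in genes
        ])
        rs = [make_readset("m", "r1", {"chr1": base}),
              make_readset("f", "r1", {"chr1": np.concatenate([base, extra])})]
        per_gene, _ = tss_profile(rs, genes, genome)
        t, p = tss_signal_test(per_gene)
        assert p < 0.05 and t > 0


class TestGenesNearLoci:
    def test_flank_boundary(self):
        genes = [Gene("near", GI("chr1", 151_000, 160_000, "+"), "+"),
                 Gene("far", GI("chr1", 252_000, 260_000, "+"), "+")]
        locus = GwasLocus("CAD", "L1", "rs1", "chr1", (100_000, 101_000))
        de = pd.DataFrame({"log2fc": [1.0, 1.0], "significant": [True, False]},
                          index=["near", "far"])
        per_locus, test = genes_near_loci([locus], genes, de, flank=50_000)
        assert per_locus["L1"] == ["near"]

    def test_binomial_upper_tail_matches_pmf_summation(self):
        """132 candidate genes, 19 DE, background fraction 0.1: the reported
        p equals the brute-force sum of binomial pmf terms."""
        genes = [Gene(f"g{i}", GI("chr1", 1000 + 100 * i, 1050 + 100 * i, "+"), "+")
                 for i in range(132)]
        sig = [i < 19 for i in range(132)]
        de = pd.DataFrame({
            "log2fc": np.ones(132 + 868),
            "significant": sig + [False] * 780 + [True] * 88,
        }, index=[f"g{i}" for i in range(132)] + [f"x{i}" for i in range(868)])
        locus = GwasLocus("CAD", "L1", "rs1", "chr1", (5_000, 6_000))
        per_locus, test = genes_near_loci([locus], genes, de, flank=50_000)
        assert test["n_genes"] == 132 and test["n_de"] == 19
        frac = de["significant"].mean()
        brute = sum(stats.binom.pmf(k, 132, frac) for k in range(19, 133))
        assert test["p"] == pytest.approx(brute, rel=1e-9)

    def test_no_genes_near_loci(self):
        genes = [Gene("g", GI("chr2", 0, 100, "+"), "+")]
        locus = GwasLocus("CAD", "L1", "rs1", "chr1", (1000,))
        de = pd.DataFrame({"log2fc": [0.0], "significant": [False]}, index=["g"])
        per_locus, test = genes_near_loci([locus], genes, de)
        assert per_locus["L1"] == []
        assert test["p"] is None
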