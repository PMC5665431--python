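"""Windowed haplotypic F_ST against a brute-force variance-component
oracle, ratio-of-averages behaviour, NJ trees, binning and the
selection-enrichment machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapfine import differentiation as diff
from hapfine import simdata
from hapfine.differentiation import WindowTable


def brute_force_components(counts):
    """Plain-loop haploid variance components (independent oracle)."""
    counts = np.asarray(counts, dtype=float)
    r, u = counts.shape
    n_i = counts.sum(axis=1)
    n = n_i.sum()
    n_c = (n - sum(ni**2 for ni in n_i) / n) / (r - 1)
    num = den = 0.0
    for allele in range(u):
        p = counts[:, allele] / n_i
        p_bar = sum(n_i[i] * p[i] for i in range(r)) / n
        msp = sum(n_i[i] * (p[i] - p_bar) ** 2 for i in range(r)) / (r - 1)
        msg = sum(n_i[i] * p[i] * (1 - p[i]) for i in range(r)) / sum(n_i - 1)
        num += (msp - msg) / n_c
        den += (msp + (n_c - 1) * msg) / n_c
    return num, den


class TestWindowHfst:
    def test_shared_fixed_haplotype_is_undefined(self):
        num, den = diff.window_hfst([[10, 0], [12, 0]])
        assert num == 0 and den == 0

    def test_alternative_fixed_haplotypes_give_one(self):
        num, den = diff.window_hfst([[10, 0], [0, 10]])
        assert num / den == pytest.approx(1.0)

    def test_identical_polymorphic_counts_negative_numerator(self):
        num, den = diff.window_hfst([[10, 10], [10, 10]])
        assert num < 0
        assert num / den <= 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(2, 4), st.integers(2, 6), st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, r, u, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 15, size=(r, u))
        # every population needs >= 2 haplotypes
        counts[:, 0] += np.maximum(0, 2 - counts.sum(axis=1))
        num, den = diff.window_hfst(counts)
        onum, oden = brute_force_components(counts)
        assert num == pytest.approx(onum, abs=1e-10)
        assert den == pytest.approx(oden, abs=1e-10)

    def test_undersized_population_rejected(self):
        with pytest.raises(ValueError):
            diff.window_hfst([[1, 0], [5, 5]])


class TestWindows:
    def test_window_counts_and_trailing_drop(self):
        cfg = simdata.SimConfig(2, [5, 5], 2, 10, [0.05, 0.05], seed=1)
        wt = diff.make_windows(simdata.simulate_haplotypes(cfg))
        assert len(wt) == 4  # floor(10/4) per chromosome
        assert wt.table["snp_end"].max() == 7

    def test_exact_multiple_keeps_all_snps(self):
        cfg = simdata.SimConfig(2, [5, 5], 1, 8, [0.05, 0.05], seed=1)
        wt = diff.make_windows(simdata.simulate_haplotypes(cfg))
        assert len(wt) == 2 and wt.table["snp_end"].max() == 7

    def test_equal_spans_never_removed(self):
        cfg = simdata.SimConfig(2, [5, 5], 1, 40, [0.05, 0.05], seed=1)
        wt = diff.make_windows(simdata.simulate_haplotypes(cfg))
        filtered = diff.filter_outlier_windows(wt)
        assert not filtered.table["removed"].any()

    def test_extreme_span_removed_single_pass(self):
        base = diff.make_windows(simdata.simulate_haplotypes(
            simdata.SimConfig(2, [5, 5], 1, 404, [0.05, 0.05], seed=1)))
        t = base.table.copy()
        jitter = 1 + 0.05 * np.sin(np.arange(len(t)))  # non-zero log SD
        t["bp_span"] = (1000 * jitter).astype(int)
        t["cm_span"] = t["bp_span"] * 1e-6
        t.loc[t.index[-1], ["bp_span", "cm_span"]] = [10**9, 10**9 * 1e-6]
        filtered = diff.filter_outlier_windows(WindowTable(t))
        assert filtered.table["removed"].iloc[-1]
        assert filtered.table["removed"].sum() == 1
        # single-pass contract: statistics come from the pre-filter table,
        # so re-running on the filtered table may remove more windows
        again = diff.filter_outlier_windows(filtered)
        assert again.table["removed"].sum() >= filtered.table["removed"].sum()


class TestPopulationHfst:
    def test_single_window_equals_its_ratio(self):
        t = pd.DataFrame({"numerator": [1.0], "denominator": [2.0],
                          "removed": [False], "monomorphic": [False],
                          "hfst": [0.5]})
        assert diff.population_hfst(WindowTable(t)).hfst == 0.5

    def test_ratio_of_averages_not_average_of_ratios(self):
        t = pd.DataFrame({"numerator": [1.0, 3.0], "denominator": [2.0, 4.0],
                          "removed": [False] * 2, "monomorphic": [False] * 2,
                          "hfst": [0.5, 0.75]})
        res = diff.population_hfst(WindowTable(t))
        assert res.hfst == pytest.approx(4 / 6)
        assert res.hfst != pytest.approx(np.mean([0.5, 0.75]))

    def test_bounded_by_window_extremes_when_denominators_positive(self):
        rng = np.random.default_rng(0)
        den = rng.uniform(0.5, 2.0, 50)
        num = rng.uniform(-0.2, 1.0, 50) * den
        t = pd.DataFrame({"numerator": num, "denominator": den,
                          "removed": False, "monomorphic": False,
                          "hfst": num / den})
        res = diff.population_hfst(WindowTable(t))
        assert t["hfst"].min() <= res.hfst <= t["hfst"].max()

    def test_ratio_of_averages_recovers_balding_nichols_drift(self):
        """On haploid samples drawn directly from the Balding–Nichols
        model, the SNP-level ratio-of-averages estimator recovers the
        drift parameter F within Monte-Carlo scatter; the 4-SNP
        haplotype-allele version of the same data sits strictly between
        0 and the SNP-level value (haplotype alleles drift
        semi-independently across their four sites, diluting
        per-allele differentiation)."""
        f = 0.02
        snp_level, windowed = [], []
        for seed in range(8):
            rng = np.random.default_rng(300 + seed)
            s, n = 1600, 100
            p = rng.uniform(0.05, 0.95, s)
            q = np.stack([simdata.draw_cluster_frequencies(p, f, rng)
                          for _ in range(2)])
            haps = [(rng.random((n, s)) < q[k]).astype(np.uint8)
                    for k in range(2)]
            # SNP level: each SNP a two-allele haploid locus (oracle path
            # uses the plain-loop components)
            num = den = 0.0
            for site in range(0, s, 8):  # subsample sites for speed
                counts = [[int(h[:, site].sum()), n - int(h[:, site].sum())]
                          for h in haps]
                a, b = brute_force_components(counts)
                num += a
                den += b
            snp_level.append(num / den)
            # windowed haplotypic estimate on the same data
            w = 1 << np.arange(3, -1, -1)
            n_win = s // 4
            cts = np.zeros((2, n_win, 16))
            offsets = np.arange(n_win) * 16
            for k, h in enumerate(haps):
                codes = h.reshape(n, n_win, 4) @ w
                cts[k] = np.bincount((codes + offsets[None]).ravel(),
                                     minlength=n_win * 16).reshape(n_win, 16)
            nums, dens = zip(*(diff.window_hfst(cts[:, i]) for i in range(n_win)))
            windowed.append(sum(nums) / sum(dens))
        snp_level = np.asarray(snp_level)
        mc_sd = snp_level.std(ddof=1) / np.sqrt(len(snp_level))
        assert abs(snp_level.mean() - f) < 3 * max(mc_sd, 5e-4)
        assert all(0 < w < s_ for w, s_ in zip(windowed, snp_level))


class TestNeighborJoining:
    def three_taxa(self):
        d = pd.DataFrame([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        return d

    def test_three_taxa_closed_form(self):
        tree = diff.neighbor_joining(self.three_taxa())
        # la = (5+9-10)/2 = 2, lb = 3, lc = 7
        assert "a:2" in tree and "b:3" in tree and "c:7" in tree

    @staticmethod
    def additive_distances():
        # tree: ((a:1,b:2):3,(c:4,d:5):6,e:7) -- additive by construction
        paths = {
            ("a", "b"): 3, ("a", "c"): 14, ("a", "d"): 15, ("a", "e"): 11,
            ("b", "c"): 15, ("b", "d"): 16, ("b", "e"): 12,
            ("c", "d"): 9, ("c", "e"): 17, ("d", "e"): 18,
        }
        taxa = list("abcde")
        d = pd.DataFrame(0.0, index=taxa, columns=taxa)
        for (x, y), v in paths.items():
            d.loc[x, y] = d.loc[y, x] = float(v)
        return d

    def test_recovers_additive_tree_exactly(self):
        import io as _io

        from skbio import TreeNode

        tree = TreeNode.read(_io.StringIO(diff.neighbor_joining(
            self.additive_distances())))
        # pairwise patristic distances must reproduce the input exactly
        d = self.additive_distances()
        for x in d.index:
            for y in d.columns:
                if x != y:
                    assert tree.find(x).distance(tree.find(y)) == \
                        pytest.approx(d.loc[x, y], abs=1e-9)

    def test_agrees_with_skbio_reference_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj

        d = self.additive_distances()
        ours = diff.neighbor_joining(d)
        import io as _io

        from skbio import TreeNode

        t1 = TreeNode.read(_io.StringIO(ours))
        t2 = nj(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        assert t1.compare_rfd(t2) == 0

    def test_taxon_permutation_invariance(self):
        import io as _io

        from skbio import TreeNode

        d = self.additive_distances()
        perm = ["c", "e", "a", "d", "b"]
        t1 = TreeNode.read(_io.StringIO(diff.neighbor_joining(d)))
        t2 = TreeNode.read(_io.StringIO(
            diff.neighbor_joining(d.loc[perm, perm])))
        assert t1.compare_rfd(t2) == 0

    def test_invalid_matrices_rejected(self):
        d = self.three_taxa()
        d.iloc[0, 1] = np.nan
        d.iloc[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            diff.neighbor_joining(d)
        with pytest.raises(ValueError, match="3 taxa"):
            diff.neighbor_joining(self.three_taxa().iloc[:2, :2])


def binnable_table(n, hfst=None, seed=0):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame({
        "chromosome": "chr1", "chrom_index": 0, "window": np.arange(n),
        "bp_start": np.arange(n) * 100 + 1, "bp_end": np.arange(n) * 100 + 90,
        "numerator": 1.0, "denominator": 2.0,
        "hfst": rng.random(n) if hfst is None else np.asarray(hfst, dtype=float),
        "removed": False, "monomorphic": False,
    })
    return WindowTable(t)


class TestBinning:
    def test_forty_windows_make_twenty_pairs(self):
        wt = diff.bin_windows(binnable_table(40), 20)
        sizes = wt.table["bin"].value_counts()
        assert (sizes == 2).all() and len(sizes) == 20

    def test_remainder_spread_one_bin_of_three(self):
        wt = diff.bin_windows(binnable_table(41), 20)
        sizes = wt.table["bin"].value_counts()
        assert sorted(sizes) == [2] * 19 + [3]
        assert sizes[1] == 3  # first bin takes the extra window

    def test_bins_follow_rank_not_value(self):
        base = binnable_table(60)
        monotone = WindowTable(base.table.assign(
            hfst=np.exp(5 * base.table["hfst"])))
        b1 = diff.bin_windows(base, 20).table["bin"]
        b2 = diff.bin_windows(monotone, 20).table["bin"]
        assert (b1 == b2).all()

    def test_bin_one_lowest_bin_twenty_highest(self):
        wt = diff.bin_windows(binnable_table(100), 20)
        t = wt.table
        assert t.loc[t["bin"] == 1, "hfst"].max() <= \
            t.loc[t["bin"] == 20, "hfst"].min()

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            diff.bin_windows(binnable_table(10), 20)


class TestEnrichment:
    def test_threshold_is_multiplicity_adjusted(self):
        wt = diff.bin_windows(binnable_table(400), 20)
        marked = WindowTable(wt.table.assign(selected=False))
        enr = diff.enrichment_by_bin(marked)
        assert enr["threshold"].iloc[0] == pytest.approx(0.01 / 20)
        assert (enr["p_fisher"] == 1.0).all()

    def test_top_bin_enrichment_matches_hypergeometric_tail(self):
        from scipy.stats import hypergeom

        wt = diff.bin_windows(binnable_table(400), 20)
        t = wt.table
        selected = t["bin"] == 20  # all 20 top-bin windows selected
        marked = WindowTable(t.assign(selected=selected))
        enr = diff.enrichment_by_bin(marked).set_index("bin")
        # one-sided Fisher p == hypergeometric upper tail
        expected = hypergeom.sf(19, 400, 20, 20)
        assert enr.loc[20, "p_fisher"] == pytest.approx(expected, rel=1e-6)
        assert enr.loc[20, "p_fisher"] < 5e-4
        assert enr.loc[20, "significant"]

    def test_random_mask_rarely_flags_any_bin(self):
        rng = np.random.default_rng(12)
        false_flags = 0
        for scan in range(200):
            wt = diff.bin_windows(binnable_table(400, seed=scan), 20)
            mask = rng.random(400) < 0.05
            marked = WindowTable(wt.table.assign(selected=mask))
            enr = diff.enrichment_by_bin(marked)
            false_flags += enr["significant"].any()
        assert false_flags <= 10  # <= 5% of 200 scans


class TestGroupTests:
    def test_identical_groups_p_near_one(self):
        vals = np.concatenate([np.arange(30.0), np.arange(30.0)])
        sel = np.array([True] * 30 + [False] * 30)
        p, _ = diff.selected_vs_nonselected_test(vals, sel)
        assert p > 0.9

    def test_exact_small_sample_enumeration(self):
        vals = np.array([1.0, 2, 3, 4, 5, 6])
        sel = np.array([True, True, True, False, False, False])
        p, direction = diff.selected_vs_nonselected_test(vals, sel)
        assert p == pytest.approx(0.1)  # 2 * (1 / C(6,3))
        assert direction == -1

    def test_spearman_perfect_and_null(self):
        rng = np.random.default_rng(9)
        a = rng.random(100)
        rho, _ = diff.rank_correlation(a, np.exp(a))
        assert rho == pytest.approx(1.0)
        rho, _ = diff.rank_correlation(a, -a)
        assert rho == pytest.approx(-1.0)
        small = sum(abs(diff.rank_correlation(a, rng.permutation(a))[0]) < 0.3
                    for _ in range(20))
        assert small >= 19

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            diff.rank_correlation(np.ones(10), np.arange(10.0))


class TestAnnotateLoci:
    def annotated(self):
        wt = diff.bin_windows(binnable_table(100), 20)
        return wt

    def test_single_window_locus_reports_its_bin(self):
        wt = self.annotated()
        t = wt.table
        top = t[t["bin"] == 20].iloc[0]
        loci = pd.DataFrame([["chr1", top["bp_start"] - 1, top["bp_end"], "GENE"]])
        res = diff.annotate_loci(wt, loci)
        assert res.loc[0, "bin"] == 20

    def test_multi_window_locus_takes_max_hfst_bin(self):
        wt = self.annotated()
        t = wt.table.sort_values("bp_start")
        lo = t[t["bin"] == 3].iloc[0]
        hi = t[t["bin"] == 17].iloc[0]
        start = min(lo["bp_start"], hi["bp_start"]) - 1
        end = max(lo["bp_end"], hi["bp_end"])
        res = diff.annotate_loci(wt, pd.DataFrame([["chr1", start, end, "G"]]))
        assert res.loc[0, "bin"] >= 17

    def test_uncovered_chromosome_is_unmapped_not_error(self):
        wt = self.annotated()
        res = diff.annotate_loci(wt, pd.DataFrame([["chrX", 0, 100, "G"]]))
        assert pd.isna(res.loc[0, "bin"])

    def test_malformed_bed_rejected(self):
        with pytest.raises(ValueError, match="4 BED columns"):
            diff.annotate_loci(self.annotated(), pd.DataFrame([["chr1", 0, 5]]))
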