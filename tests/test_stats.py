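"""TE computation, divergence tests, FDR, screens, dominance and grouping."""

import numpy as np
import pandas as pd
import pytest

from uorfbuffer.stats import (
    add_te_columns,
    adjust_fdr,
    assign_gene_classes,
    beta_test,
    compute_rpkm,
    compute_te,
    cv_across_samples,
    dominant_consistency_shuffle,
    estimate_se_log2te,
    filter_expressed_genes,
    find_dominant_uorf,
    fit_se_surface,
    gamma_test,
    group_by_uorf_length,
    high_expression_filter,
    screen_buffered_pairs,
)


class TestRPKMAndTE:
    @pytest.mark.parametrize(
        "count,length,libsize,expected",
        [(10, 1000, 1e6, 10.0), (0, 500, 1e6, 0.0), (1, 100, 1e7, 1.0)],
    )
    def test_rpkm_closed_form(self, count, length, libsize, expected):
        assert compute_rpkm(count, length, libsize) == pytest.approx(expected)

    def test_rpkm_rejects_nonpositive_scaling(self):
        with pytest.raises(ValueError):
            compute_rpkm(1, 0, 1e6)
        with pytest.raises(ValueError):
            compute_rpkm(1, 100, 0)

    @pytest.mark.parametrize(
        "rpf,mrna,expected",
        [(2.0, 1.0, 2.0), (0.5, 0.0, 6.0), (0.0, 3.0, 0.0)],
    )
    def test_te_with_pseudocount_rescue(self, rpf, mrna, expected):
        # 0 mRNA with positive signal: (0.5+0.1)/(0+0.1) = 6
        assert compute_te(rpf, mrna) == pytest.approx(expected)

    def test_te_undefined_when_both_zero(self):
        assert np.isnan(compute_te(0.0, 0.0))


class TestWaldTests:
    def test_equal_tes_give_null_result(self):
        res = beta_test(1.5, 0.3, 1.5, 0.4)
        assert res["log2_beta"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_pythagorean_se_propagation(self):
        res = beta_test(0.0, 3.0, 1.0, 4.0)
        assert res["se_log2_beta"].iloc[0] == pytest.approx(5.0)

    def test_wald_p_at_critical_z(self):
        res = beta_test(0.0, 1.0, 1.959964, 1.0)
        # se = sqrt(2), z = 1.959964/sqrt(2); use direct z instead:
        res = beta_test(0.0, 0.6, 1.959964 * 0.6 * np.sqrt(2), 0.6)
        assert res["p"].iloc[0] == pytest.approx(0.05, abs=1e-6)

    def test_gamma_null_and_four_term_se(self):
        res = gamma_test(1.0, 1.0, 1.0, 1.0, 2.0, 1.0, 2.0, 1.0)
        assert res["log2_gamma"].iloc[0] == 0.0
        assert res["se_log2_gamma"].iloc[0] == pytest.approx(2.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_gamma_sign_convention_buffered_cds(self):
        # uORF TE doubles between species, CDS unchanged -> log2 gamma = -1
        res = gamma_test(0.0, 0.5, 1.0, 0.5, 0.7, 0.5, 0.7, 0.5)
        assert res["log2_gamma"].iloc[0] == pytest.approx(-1.0)
        assert res["beta_u_gt_1"].iloc[0]
        assert not res["gamma_gt_1"].iloc[0]

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            beta_test(0.0, 0.0, 1.0, 1.0)


class TestFDR:
    def test_bh_step_up_hand_computed(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_inputs(self):
        assert adjust_fdr([0.3]) == pytest.approx([0.3])
        assert adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_monotone_in_rank_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(200)
        assert np.allclose(adjust_fdr(p[perm]), q[perm])
        assert (q >= p - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestScreen:
    @staticmethod
    def _frames(rows):
        bu = pd.DataFrame(
            [{"pair_id": r[0], "log2_beta": r[1], "q": r[2]} for r in rows]
        )
        bc = pd.DataFrame(
            [{"pair_id": r[0], "log2_beta": r[3], "q": r[4]} for r in rows]
        )
        g = pd.DataFrame(
            [{"pair_id": r[0], "log2_gamma": r[5], "q": r[6]} for r in rows]
        )
        return bu, bc, g

    def test_textbook_pass_and_fail(self):
        rows = [
            ("hit", 2.0, 0.001, 0.01, 0.9, -1.99, 0.001),
            ("null", 0.0, 0.9, 0.0, 0.9, 0.0, 0.9),
            ("cds_moved", 2.0, 0.001, 1.0, 0.001, -1.0, 0.001),
        ]
        sel, counts = screen_buffered_pairs(*self._frames(rows))
        assert sel["pair_id"].tolist() == ["hit"]
        assert counts["all_three"] == 1
        assert counts["uorf_shifted"] == 2

    def test_unmatched_pairs_reported(self):
        bu, bc, g = self._frames([("a", 2.0, 0.001, 0.0, 0.9, -2.0, 0.001)])
        bc = bc[bc["pair_id"] != "a"]
        with pytest.raises(ValueError, match="a"):
            screen_buffered_pairs(bu, bc, g)


class TestDominance:
    def test_argmax_and_tie_rules(self):
        te = pd.Series({"u1": 0.5, "u2": 2.0, "u3": 1.0})
        assert find_dominant_uorf(te) == "u2"
        tie = pd.Series({"u1": 1.0, "u2": 1.0})
        starts = pd.Series({"u1": 200, "u2": 120})
        assert find_dominant_uorf(tie, starts) == "u2"  # 5'-most wins
        assert find_dominant_uorf(pd.Series({"u1": 3.0})) == "u1"
        assert find_dominant_uorf(pd.Series({"u1": np.nan})) is None

    def test_maximal_consistency_beats_null(self):
        genes, samples = 30, 6
        rows = []
        for gi in range(genes):
            for s in range(samples):
                rows.append({"gene_id": f"g{gi}", "uorf_id": "uA", "sample": f"s{s}", "te": 10.0})
                rows.append({"gene_id": f"g{gi}", "uorf_id": "uB", "sample": f"s{s}", "te": 0.01})
        res = dominant_consistency_shuffle(
            pd.DataFrame(rows), min_translated_samples=3, n_shuffles=200, seed=1
        )
        assert res["observed"] == genes
        assert res["null_mean"] < genes / 2

    def test_iid_null_mean_matches_analytic_rate(self):
        # k uORFs, s samples, iid TEs: P(consistent) = k^(1-s)
        rng = np.random.default_rng(0)
        genes, k, s = 300, 2, 3
        rows = [
            {"gene_id": f"g{gi}", "uorf_id": f"u{ui}", "sample": f"s{si}",
             "te": float(rng.uniform(0.2, 5.0))}
            for gi in range(genes) for ui in range(k) for si in range(s)
        ]
        res = dominant_consistency_shuffle(
            pd.DataFrame(rows), min_translated_samples=1, n_shuffles=300, seed=4
        )
        expected = genes * k ** (1 - s)  # 75
        assert res["null_mean"] == pytest.approx(expected, rel=0.15)
        assert res["null_lo"] <= expected <= res["null_hi"]

    def test_shuffle_null_reproducible(self):
        rows = [
            {"gene_id": "g", "uorf_id": f"u{ui}", "sample": f"s{si}", "te": ui + si}
            for ui in range(3) for si in range(4)
        ]
        df = pd.DataFrame(rows)
        a = dominant_consistency_shuffle(df, min_translated_samples=1, n_shuffles=150, seed=8)
        b = dominant_consistency_shuffle(df, min_translated_samples=1, n_shuffles=150, seed=8)
        assert (a["null_lo"], a["null_hi"]) == (b["null_lo"], b["null_hi"])


class TestClassesAndGrouping:
    def test_class_assignment_hierarchy(self):
        flags = pd.DataFrame(
            [
                # class I: conserved + dominant in both
                dict(gene_id="g1", uorf_id="a", conserved=True, translated_sp1=True,
                     translated_sp2=True, dominant_sp1=True, dominant_sp2=True),
                # class II: conserved + translated both, dominant in neither
                dict(gene_id="g2", uorf_id="b", conserved=True, translated_sp1=True,
                     translated_sp2=True, dominant_sp1=False, dominant_sp2=False),
                # class III: uORF not conserved
                dict(gene_id="g3", uorf_id="c", conserved=False, translated_sp1=True,
                     translated_sp2=True, dominant_sp1=True, dominant_sp2=True),
                # class III: no uORF
                dict(gene_id="g4", uorf_id=None, conserved=False, translated_sp1=False,
                     translated_sp2=False, dominant_sp1=False, dominant_sp2=False),
            ]
        )
        labels = assign_gene_classes(flags)
        assert labels.to_dict() == {"g1": "I", "g2": "II", "g3": "III", "g4": "III"}

    def test_length_grouping_with_median_tie_to_short(self):
        lens = pd.Series({"gA": 0.0, "gB": 30.0, "gC": 300.0})
        assert group_by_uorf_length(lens).to_dict() == {
            "gA": "No", "gB": "short", "gC": "long",
        }
        equal = pd.Series({"g1": 60.0, "g2": 60.0})
        assert set(group_by_uorf_length(equal)) == {"short"}
        assert group_by_uorf_length(pd.Series(dtype=float)).empty

    def test_cv_across_samples_closed_forms_and_power(self):
        rng = np.random.default_rng(11)
        n = 250
        # uORF-bearing genes generated with half the TE dispersion
        with_u = 1.0 + 0.1 * rng.standard_normal((n, 8))
        without = 1.0 + 0.2 * rng.standard_normal((n, 8))
        te = pd.DataFrame(
            np.vstack([with_u, without]),
            index=[f"g{i}" for i in range(2 * n)],
        )
        group = pd.Series([True] * n + [False] * n, index=te.index)
        res, summary = cv_across_samples(te, group)
        assert summary["p"] < 0.05
        assert summary["median_cv_with"] < summary["median_cv_without"]
        # closed forms: constant TE -> CV 0; TE (1,3) -> CV sqrt(2)/2
        small = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 3.0, np.nan], [2.0, 2.0, 2.0], [1.0, 3.0, 2.0]],
            index=["a", "b", "c", "d"],
        )
        res2, _ = cv_across_samples(
            small, pd.Series([True, True, False, False], index=list("abcd"))
        )
        assert res2.loc["a", "cv"] == pytest.approx(0.0)
        assert res2.loc["b", "cv"] == pytest.approx(np.sqrt(2) / 2)


class TestFilters:
    @staticmethod
    def _te_table():
        rng = np.random.default_rng(3)
        rows = []
        for gi in range(40):
            for sp in ("sp1", "sp2"):
                rows.append(
                    dict(feature_id=f"g{gi}_cds", gene_id=f"g{gi}", feature_type="CDS",
                         species=sp, rpkm_mrna=float(rng.uniform(0.01, 30)),
                         rpkm_rpf=float(rng.uniform(0.01, 30)))
                )
        return pd.DataFrame(rows)

    def test_expressed_gene_filter_deterministic(self):
        tab = self._te_table()
        got = filter_expressed_genes(tab, rpkm_thresh=0.1)
        expected = {
            g for g, sub in tab.groupby("gene_id")
            if (sub.groupby("species")["rpkm_mrna"].max() > 0.1).all()
        }
        assert got == expected
        assert filter_expressed_genes(tab, rpkm_thresh=0.1) == got

    def test_high_expression_filter_halves_feature_set(self):
        tab = self._te_table()
        kept = high_expression_filter(tab)
        n_genes = tab["gene_id"].nunique()
        kept_genes = kept["gene_id"].nunique()
        # both-medians cut keeps at most ~half per species
        assert 0 < kept_genes <= n_genes // 2 + 1


class TestSEEstimation:
    @staticmethod
    def _replicated(n_rep, mrna, rpf):
        rows = []
        for r in range(1, n_rep + 1):
            rows.append(
                dict(feature_id="f", gene_id="g", species="sp1", sample="s1",
                     replicate=r, mrna_count=mrna, rpf_count=rpf, len_nt=300,
                     mrna_libsize=1e7, rpf_libsize=1e7)
            )
        return pd.DataFrame(rows)

    def test_requires_replication(self):
        with pytest.raises(ValueError):
            estimate_se_log2te(self._replicated(2, 10, 10).drop(columns="replicate"))
        with pytest.raises(ValueError):
            estimate_se_log2te(self._replicated(1, 10, 10))

    def test_se_shrinks_toward_poisson_floor_with_counts(self):
        small = estimate_se_log2te(self._replicated(2, 10, 10), dispersion=0.0)
        big = estimate_se_log2te(self._replicated(2, 10_000, 10_000), dispersion=0.0)
        assert big["se_log2te"].iloc[0] < small["se_log2te"].iloc[0]
        floor = (1 / np.log(2)) * np.sqrt(2 / 20_000)
        assert big["se_log2te"].iloc[0] == pytest.approx(floor)

    def test_all_zero_feature_flagged(self):
        out = estimate_se_log2te(self._replicated(3, 0, 0), dispersion=0.0)
        assert out["flag_zero"].iloc[0]
        assert np.isnan(out["log2te"].iloc[0])

    def test_se_matches_delta_method_on_nb_counts(self):
        # 1000 NB features with known dispersion: the estimated SEs must
        # track the analytic delta-method value computed from the
        # generating parameters
        rng = np.random.default_rng(17)
        phi, n_rep = 0.05, 4
        rows = []
        mus = rng.uniform(50, 2000, size=1000)
        for i, mu in enumerate(mus):
            for r in range(1, n_rep + 1):
                m = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu))
                p_ = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu))
                rows.append(
                    dict(feature_id=f"f{i}", gene_id=f"g{i}", species="sp1",
                         sample="s1", replicate=r, mrna_count=int(m),
                         rpf_count=int(p_), len_nt=500, mrna_libsize=1e7,
                         rpf_libsize=1e7)
                )
        est = estimate_se_log2te(pd.DataFrame(rows))
        mu_tot = n_rep * mus
        analytic = (1 / np.log(2)) * np.sqrt(2 / mu_tot + 2 * phi / n_rep)
        est = est.set_index("feature_id").loc[[f"f{i}" for i in range(1000)]]
        ratio = est["se_log2te"].to_numpy() / analytic
        assert abs(np.median(ratio) - 1) < 0.2


class TestSESurface:
    @staticmethod
    def _train(se_fn, n=400, seed=0):
        rng = np.random.default_rng(seed)
        count = rng.uniform(10, 10_000, n)
        log2te = rng.uniform(-3, 3, n)
        return pd.DataFrame(
            {"mean_count": count, "log2te": log2te, "se_log2te": se_fn(count, log2te)}
        )

    def test_constant_surface_recovered(self):
        surf = fit_se_surface(self._train(lambda c, t: np.full_like(c, 0.37)))
        pred = surf.predict([50, 500, 5000], [-2.0, 0.0, 2.0])
        assert pred == pytest.approx([0.37] * 3, rel=0.02)

    def test_inverse_sqrt_count_law_recovered(self):
        surf = fit_se_surface(self._train(lambda c, t: 3.0 / np.sqrt(c)))
        counts = np.array([50.0, 200.0, 1000.0, 5000.0])
        pred = surf.predict(counts, np.zeros(4))
        assert np.allclose(pred, 3.0 / np.sqrt(counts), rtol=0.10)

    def test_extrapolation_clipped_and_flagged(self):
        surf = fit_se_surface(self._train(lambda c, t: 3.0 / np.sqrt(c)))
        inside, flag_in = surf.predict([100.0], [0.0], return_clipped=True)
        below, flag_out = surf.predict([1.0], [0.0], return_clipped=True)
        assert not flag_in[0] and flag_out[0]
        boundary = surf.predict([10.0], [0.0])
        assert below[0] == pytest.approx(boundary[0], rel=1e-6)

    def test_degenerate_training_rejected(self):
        bad = self._train(lambda c, t: np.full_like(c, 1.0))
        bad["mean_count"] = 100.0
        with pytest.raises(ValueError):
            fit_se_surface(bad)
        with pytest.raises(ValueError):
            fit_se_surface(bad.head(10))
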