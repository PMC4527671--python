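"""Reference-gene stability, relative quantification, and DE calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radspan.qpcr import (
    CtTable,
    call_de,
    collapse_technical,
    consensus_ranking,
    fold_change_contrast,
    relative_expression,
    stability_bestkeeper,
    stability_delta_ct,
    stability_genorm,
    stability_normfinder,
)


def long_format(triplets):
    rows = []
    for gene, sample, cts in triplets:
        for t, ct in enumerate(cts, 1):
            rows.append({"gene": gene, "sample_id": sample, "ct": ct, "tech_rep": t})
    return pd.DataFrame(rows)


class TestCollapseTechnical:
    @pytest.mark.parametrize("cts,mean,sd,flagged", [
        ((20.0, 20.0, 20.0), 20.0, 0.0, False),
        ((19.8, 20.0, 20.2), 20.0, 0.2, False),
        ((19.0, 20.0, 21.5), 20.1667, 1.2583, True),
    ])
    def test_triplicate_summaries(self, cts, mean, sd, flagged):
        wide, qc = collapse_technical(long_format([("g", "s", cts)]))
        assert wide.at["g", "s"] == pytest.approx(mean, abs=1e-4)
        row = qc.iloc[0]
        assert row["sd_ct"] == pytest.approx(sd, abs=1e-4)
        assert bool(row["flagged"]) is flagged

    def test_missing_reaction_flagged_not_imputed(self):
        raw = long_format([("g1", "s1", (20.0,)), ("g1", "s2", (21.0,)),
                           ("g2", "s1", (22.0,))])
        wide, qc = collapse_technical(raw)
        assert np.isnan(wide.at["g2", "s2"])
        gap = qc[(qc["gene"] == "g2") & (qc["sample_id"] == "s2")]
        assert bool(gap["flagged"].iloc[0])


class TestDeltaCtMethod:
    def test_constant_offset_pair_scores_zero(self):
        ct = pd.DataFrame({"s1": [20.0, 23.0], "s2": [21.0, 24.0], "s3": [19.5, 22.5]},
                          index=["g1", "g2"])
        scores = stability_delta_ct(ct, ["g1", "g2"])
        assert scores["g1"] == pytest.approx(0.0)
        assert scores["g2"] == pytest.approx(0.0)

    def test_matches_pairwise_sd_oracle(self, toy_ct_matrix):
        scores = stability_delta_ct(toy_ct_matrix, list(toy_ct_matrix.index))
        for g in toy_ct_matrix.index:
            sds = [float(np.std(toy_ct_matrix.loc[g] - toy_ct_matrix.loc[h], ddof=1))
                   for h in toy_ct_matrix.index if h != g]
            assert scores[g] == pytest.approx(np.mean(sds))


class TestBestKeeper:
    def test_constant_gene_best(self, toy_ct_matrix):
        ct = toy_ct_matrix.copy()
        ct.loc["gFlat"] = 21.0
        report = stability_bestkeeper(ct, list(ct.index))
        assert report.loc["gFlat", "sd"] == 0.0
        assert report["sd"].idxmin() == "gFlat"

    def test_sd_matches_hand_computation(self, toy_ct_matrix):
        report = stability_bestkeeper(toy_ct_matrix, list(toy_ct_matrix.index))
        for g in toy_ct_matrix.index:
            assert report.loc[g, "sd"] == pytest.approx(
                float(toy_ct_matrix.loc[g].std(ddof=1)))


class TestNormFinder:
    def test_single_group_equals_centred_sd_oracle(self, toy_ct_matrix, equal_efficiencies):
        scores = stability_normfinder(toy_ct_matrix, list(toy_ct_matrix.index),
                                      equal_efficiencies)
        x = -toy_ct_matrix * 1.0  # log2 expression at E=2
        z = x - x.mean(axis=0)
        for g in toy_ct_matrix.index:
            assert scores[g] == pytest.approx(float(z.loc[g].std(ddof=1)))

    def test_two_group_decomposition_oracle(self, equal_efficiencies):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(6)]
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=samples)
        ct = pd.DataFrame(rng.normal(22, 0.5, size=(3, 6)), index=["gA", "gB", "gC"],
                          columns=samples)
        ct.loc["gC", groups == "b"] += 2.0  # planted inter-group shift
        scores = stability_normfinder(ct, ["gA", "gB", "gC"], equal_efficiencies, groups)
        # independent recomputation of the decomposition
        x = -ct
        z = x - x.mean(axis=0)
        for g in ct.index:
            means, variances, sizes = [], [], []
            for lab in ("a", "b"):
                vals = z.loc[g, groups == lab]
                means.append(vals.mean())
                variances.append(vals.var(ddof=1))
                sizes.append(len(vals))
            between = max(0.0, np.var(means, ddof=1) - np.mean(np.array(variances) / np.array(sizes)))
            assert scores[g] == pytest.approx(math.sqrt(between + np.mean(variances)))
        assert scores.idxmax() == "gC"

    def test_group_with_single_sample_rejected(self, toy_ct_matrix, equal_efficiencies):
        groups = pd.Series(["a", "a", "a", "b"], index=toy_ct_matrix.columns)
        with pytest.raises(ValueError):
            stability_normfinder(toy_ct_matrix, list(toy_ct_matrix.index),
                                 equal_efficiencies, groups)


class TestGeNorm:
    def test_proportional_genes_have_zero_pairwise_variation(self, equal_efficiencies):
        ct = pd.DataFrame({"s1": [20.0, 22.0, 25.0], "s2": [21.0, 23.0, 24.0],
                           "s3": [19.0, 21.0, 26.0]}, index=["gA", "gB", "gC"])
        m, ranking = stability_genorm(ct, ["gA", "gB", "gC"], equal_efficiencies)
        # gA and gB differ by a constant Ct: their log-ratio SD is 0, so each
        # gene's M equals its SD against gC alone / mean over partners
        diff_sd = float((ct.loc["gA"] - ct.loc["gC"]).std(ddof=1))
        assert m["gA"] == pytest.approx(diff_sd / 2)
        assert set(ranking[:2]) == {"gA", "gB"}

    def test_m_values_match_spreadsheet_oracle(self, toy_ct_matrix, equal_efficiencies):
        m, _ = stability_genorm(toy_ct_matrix, list(toy_ct_matrix.index), equal_efficiencies)
        log2q = {}
        for g in toy_ct_matrix.index:
            cts = toy_ct_matrix.loc[g]
            log2q[g] = (cts.min() - cts) * 1.0  # log2(E)=1
        for g in toy_ct_matrix.index:
            vs = [float((pd.Series(log2q[g]) - pd.Series(log2q[h])).std(ddof=1))
                  for h in toy_ct_matrix.index if h != g]
            assert m[g] == pytest.approx(np.mean(vs))

    def test_fewer_than_three_candidates_rejected(self, toy_ct_matrix, equal_efficiencies):
        with pytest.raises(ValueError):
            stability_genorm(toy_ct_matrix, ["gA", "gB"], equal_efficiencies)


class TestConsensus:
    def test_agreeing_methods_preserve_order(self, equal_efficiencies):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(8)]
        ct = pd.DataFrame({s: [20.0, 21.0, 22.0] for s in samples},
                          index=["gA", "gB", "gC"])
        ct.loc["gB"] += rng.normal(0, 0.3, size=8)
        ct.loc["gC"] += rng.normal(0, 1.5, size=8)
        report = consensus_ranking(ct, ["gA", "gB", "gC"], equal_efficiencies)
        assert list(report.consensus.sort_values().index) == ["gA", "gB", "gC"]

    def test_method_order_invariance_and_tie_break(self, toy_ct_matrix, equal_efficiencies):
        report = consensus_ranking(toy_ct_matrix, ["gC", "gA", "gB"], equal_efficiencies)
        report2 = consensus_ranking(toy_ct_matrix, ["gA", "gB", "gC"], equal_efficiencies)
        pd.testing.assert_series_equal(report.consensus, report2.consensus)
        assert report.selected == report2.selected


def make_table(ct, eff, refs, groups=None, bio_reps=None):
    meta = pd.DataFrame({
        "group": groups or ["g"] * ct.shape[1],
        "bio_rep": bio_reps or list(range(1, ct.shape[1] + 1)),
    }, index=ct.columns)
    return CtTable(ct=ct, sample_meta=meta, efficiencies=eff, reference_genes=refs,
                   min_efficiency=1.8)


class TestRelativeExpression:
    def test_target_at_geometric_mean_of_refs(self):
        ct = pd.DataFrame({"s1": [20.0, 18.0, 22.0]}, index=["t", "r1", "r2"])
        eff = pd.Series({"t": 2.0, "r1": 2.0, "r2": 2.0})
        assert relative_expression(make_table(ct, eff, ["r1", "r2"]), "t", "s1") == \
            pytest.approx(1.0, abs=1e-10)

    def test_one_cycle_below_geometric_mean_doubles(self):
        ct = pd.DataFrame({"s1": [19.0, 18.0, 22.0]}, index=["t", "r1", "r2"])
        eff = pd.Series({"t": 2.0, "r1": 2.0, "r2": 2.0})
        assert relative_expression(make_table(ct, eff, ["r1", "r2"]), "t", "s1") == \
            pytest.approx(2.0, abs=1e-10)

    def test_mixed_efficiencies(self):
        ct = pd.DataFrame({"s1": [20.0, 20.0]}, index=["t", "r"])
        eff = pd.Series({"t": 1.9, "r": 2.0})
        assert relative_expression(make_table(ct, eff, ["r"]), "t", "s1") == \
            pytest.approx((2.0 / 1.9) ** 20, abs=1e-9)

    @given(st.floats(-3, 3))
    def test_shifting_target_ct_scales_by_efficiency_power(self, c):
        ct = pd.DataFrame({"s1": [20.0, 19.0]}, index=["t", "r"])
        eff = pd.Series({"t": 2.0, "r": 2.0})
        r0 = relative_expression(make_table(ct, eff, ["r"]), "t", "s1")
        ct2 = ct.copy()
        ct2.at["t", "s1"] += c
        r1 = relative_expression(make_table(ct2, eff, ["r"]), "t", "s1")
        assert r1 == pytest.approx(r0 * 2.0 ** (-c), rel=1e-9)

    def test_global_shift_with_equal_efficiencies_is_invariant(self):
        ct = pd.DataFrame({"s1": [20.0, 18.0, 22.0]}, index=["t", "r1", "r2"])
        eff = pd.Series({"t": 2.0, "r1": 2.0, "r2": 2.0})
        r0 = relative_expression(make_table(ct, eff, ["r1", "r2"]), "t", "s1")
        r1 = relative_expression(make_table(ct + 3.0, eff, ["r1", "r2"]), "t", "s1")
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_classical_ddct_identity_single_reference(self):
        ct = pd.DataFrame({"s1": [24.0, 20.5]}, index=["t", "r"])
        eff = pd.Series({"t": 2.0, "r": 2.0})
        assert relative_expression(make_table(ct, eff, ["r"]), "t", "s1") == \
            pytest.approx(2.0 ** (-(24.0 - 20.5)))

    def test_missing_reference_value_rejected(self):
        ct = pd.DataFrame({"s1": [20.0, np.nan]}, index=["t", "r"])
        eff = pd.Series({"t": 2.0, "r": 2.0})
        with pytest.raises(ValueError):
            make_table(ct, eff, ["r"])


class TestFoldChange:
    def paired_table(self, r_exp, r_ctl):
        # encode desired relative expressions as target Ct at E=2 with a
        # constant reference: R = 2^(ref - ct)
        ref_ct = 20.0
        exp_ct = [ref_ct - math.log2(r) for r in r_exp]
        ctl_ct = [ref_ct - math.log2(r) for r in r_ctl]
        samples = [f"e{i}" for i in range(len(r_exp))] + [f"c{i}" for i in range(len(r_ctl))]
        ct = pd.DataFrame(
            {s: [v, ref_ct] for s, v in zip(samples, exp_ct + ctl_ct)}, index=["t", "r"])
        eff = pd.Series({"t": 2.0, "r": 2.0})
        groups = ["exp"] * len(r_exp) + ["ctl"] * len(r_ctl)
        reps = list(range(1, len(r_exp) + 1)) + list(range(1, len(r_ctl) + 1))
        return make_table(ct, eff, ["r"], groups=groups, bio_reps=reps)

    def test_identical_groups_unity(self):
        table = self.paired_table([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        c = fold_change_contrast(table, "t", "exp", "ctl")
        assert np.allclose(c.log2_fc, 0.0)
        assert c.mean_log2_fc == 0.0

    def test_replicate_wise_fold_changes(self):
        table = self.paired_table([2.0, 4.0, 2.0], [1.0, 1.0, 1.0])
        c = fold_change_contrast(table, "t", "exp", "ctl")
        assert np.allclose(np.sort(c.log2_fc), [1.0, 1.0, 2.0])
        assert c.mean_log2_fc == pytest.approx(4.0 / 3.0)

    def test_all_pairs_mode(self):
        table = self.paired_table([2.0, 4.0], [1.0, 2.0])
        c = fold_change_contrast(table, "t", "exp", "ctl", pairing="all_pairs")
        assert len(c.log2_fc) == 4
        assert c.mean_log2_fc == pytest.approx(np.mean([1.0, 0.0, 2.0, 1.0]))

    def test_unequal_replicates_rejected_for_index_pairing(self):
        table = self.paired_table([2.0, 4.0, 2.0], [1.0, 1.0, 1.0])
        meta = table.sample_meta.drop(index=["c2"])
        table2 = CtTable(ct=table.ct[meta.index], sample_meta=meta,
                         efficiencies=table.efficiencies, reference_genes=["r"],
                         min_efficiency=1.8)
        with pytest.raises(ValueError):
            fold_change_contrast(table2, "t", "exp", "ctl")


class TestCallDE:
    def contrast(self, mean, sd, p):
        from radspan.qpcr import ExpressionContrast
        return ExpressionContrast(
            gene="g", exposed_group="e", control_group="c",
            r_exposed=np.array([1.0]), r_control=np.array([1.0]),
            log2_fc=np.array([mean]), mean_log2_fc=mean, sd_log2_fc=sd, p_value=p)

    def test_fold_filter(self):
        assert call_de([self.contrast(0.5, 0.01, 0.001)])[0].de is False

    def test_all_filters_pass(self):
        assert call_de([self.contrast(1.5, 0.045, 0.01)])[0].de is True

    def test_toy_table_counts(self):
        specs = [(1.5, 0.03, 0.01, True),    # passes everything
                 (2.5, 0.05, 0.2, False),    # p too large
                 (0.9, 0.01, 0.001, False),  # |log2FC| < 1
                 (-1.4, 0.05, 0.01, True),   # down-regulation, rel SD 0.036
                 (1.2, 0.5, 0.01, False),    # rel SD 0.42, too variable
                 (3.0, 0.1, 0.04, True)]     # rel SD 0.033
        contrasts = call_de([self.contrast(m, s, p) for m, s, p, _ in specs])
        assert [c.de for c in contrasts] == [want for _, _, _, want in specs]
        assert sum(c.de for c in contrasts) == 3

    def test_threshold_configurable(self):
        c = self.contrast(1.5, 0.5, 0.01)
        assert call_de([c], rel_sd_threshold=0.05)[0].de is False
        assert call_de([c], rel_sd_threshold=0.5)[0].de is True
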