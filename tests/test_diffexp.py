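"""Contrast statistics: cell-means model, BH machinery, pattern labels.

The t-test route is checked against a brute-force oracle that works
directly from sums of squares, with no fitted model object.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hyperomir import diffexp, synthetic
from hyperomir.diffexp import (
    bh_adjust,
    bh_p_cutoff,
    classify_patterns,
    contrast_test,
    fit_two_factor_model,
    run_contrasts,
    select_significant,
    signed_fold_change,
)


def brute_force_contrast(matrix, design, num_cell, den_cell):
    """Independent oracle: pooled-variance t from explicit sums of squares."""
    groups = {
        (tp, tr): sub["sample_id"].tolist()
        for (tp, tr), sub in design.groupby(["timepoint", "treatment"])
    }
    n_total = len(design)
    k = len(groups)
    out = []
    for probe in matrix.index:
        sse = 0.0
        for samples in groups.values():
            x = matrix.loc[probe, samples].to_numpy()
            sse += np.sum((x - x.mean()) ** 2)
        df = n_total - k
        s2 = sse / df
        num = matrix.loc[probe, groups[num_cell]].to_numpy()
        den = matrix.loc[probe, groups[den_cell]].to_numpy()
        diff = num.mean() - den.mean()
        se = np.sqrt(s2 * (1 / len(num) + 1 / len(den)))
        t = diff / se
        out.append((diff, 2 * stats.t.sf(abs(t), df)))
    return out


class TestCellMeansFit:
    def test_pooled_variance_is_df_weighted_mean_of_cell_variances(self, design, small_matrix):
        fit = fit_two_factor_model(small_matrix, design)
        groups = design.groupby(["timepoint", "treatment"])["sample_id"].apply(list)
        for probe in small_matrix.index[:10]:
            num = sum(
                (len(s) - 1) * np.var(small_matrix.loc[probe, s].to_numpy(), ddof=1)
                for s in groups
            )
            expected = num / (len(design) - len(groups))
            assert fit.s2[probe] == pytest.approx(expected, rel=1e-12)
        assert fit.df_resid == 12 - 5

    def test_noise_free_input_flagged_degenerate(self, design):
        cell_value = {("P1", "RA"): 1.0, ("P14", "RA"): 2.0, ("P29", "RA"): 3.0,
                      ("P14", "O2"): 4.0, ("P29", "O2"): 5.0}
        row = [cell_value[(tp, tr)] for tp, tr in zip(design.timepoint, design.treatment)]
        matrix = pd.DataFrame([row], index=["p0"], columns=design["sample_id"].tolist())
        fit = fit_two_factor_model(matrix, design)
        assert fit.s2["p0"] == 0.0 and fit.degenerate["p0"]
        assert fit.means.loc["p0", "P14:O2"] == 4.0
        res = contrast_test(fit, "B")
        assert np.isnan(res.loc["p0", "p_raw"]) and res.loc["p0", "degenerate"]

    def test_single_replicate_cell_rejected(self, small_matrix, design):
        bad = design.drop(design.index[design.sample_id == "P1_RA_2"])
        with pytest.raises(ValueError, match=">=2"):
            fit_two_factor_model(small_matrix, bad)


class TestContrastTest:
    def test_matches_brute_force_oracle(self, design, small_matrix):
        fit = fit_two_factor_model(small_matrix, design)
        for group, (num, den) in diffexp.CONTRASTS.items():
            res = contrast_test(fit, group)
            oracle = brute_force_contrast(small_matrix, design, num, den)
            for probe, (diff, p) in zip(small_matrix.index, oracle):
                assert res.loc[probe, "log2_diff"] == pytest.approx(diff, abs=1e-10)
                assert res.loc[probe, "p_raw"] == pytest.approx(p, abs=1e-10)

    def test_equal_cell_means_give_p_one(self, design):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.3, size=len(design))
        # enforce exactly equal P14-O2 and P14-RA cell means, noise elsewhere
        matrix = pd.DataFrame([noise], index=["p0"], columns=design["sample_id"].tolist())
        for tp, tr in (("P14", "O2"), ("P14", "RA")):
            cols = design.loc[(design.timepoint == tp) & (design.treatment == tr), "sample_id"]
            matrix[cols] = matrix[cols].sub(matrix[cols].mean(axis=1), axis=0)
        fit = fit_two_factor_model(matrix, design)
        res = contrast_test(fit, "B")
        assert res.loc["p0", "log2_diff"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["p0", "p_raw"] == pytest.approx(1.0)

    def test_planted_diff_two_at_sd_quarter_is_detected(self, design):
        """Exact fixture: diff 2.0, pooled sd 0.25, reps (2,3) -> p < 1e-4.

        Cell values are mean +- fixed offsets chosen so each cell's
        sample variance is exactly 0.0625, making the closed-form t
        (t = 2 / (0.25 * sqrt(1/2 + 1/3)), df = 7) the oracle.
        """
        offsets = {2: np.array([0.25 / np.sqrt(2), -0.25 / np.sqrt(2)]),
                   3: np.array([-0.25, 0.0, 0.25])}
        cell_mean = {("P14", "O2"): 2.0}  # numerator of contrast B; others 0
        values = []
        for (tp, tr), sub in design.groupby(["timepoint", "treatment"], sort=False):
            mu = cell_mean.get((tp, tr), 0.0)
            values.extend(zip(sub["sample_id"], mu + offsets[len(sub)]))
        row = pd.Series(dict(values))[design["sample_id"]]
        matrix = pd.DataFrame([row.to_numpy()], index=["p0"], columns=design["sample_id"])
        fit = fit_two_factor_model(matrix, design)
        res = contrast_test(fit, "B")
        se = 0.25 * np.sqrt(1 / 2 + 1 / 3)
        expected_p = 2 * stats.t.sf(2.0 / se, 7)
        assert res.loc["p0", "p_raw"] == pytest.approx(expected_p, rel=1e-10)
        assert res.loc["p0", "p_raw"] < 1e-4


class TestSignedFoldChange:
    @pytest.mark.parametrize("log2_diff, expected", [
        (1.0, 2.0), (-1.0, -2.0), (0.0, 1.0), (2.0, 4.0), (-3.0, -8.0),
    ])
    def test_reciprocal_negative_convention(self, log2_diff, expected):
        assert signed_fold_change(log2_diff) == expected

    def test_magnitude_never_below_one(self, rng):
        fc = signed_fold_change(rng.normal(0, 3, size=1000))
        assert (np.abs(fc) >= 1).all()


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("p, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.03], [0.03]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_hand_computed_step_up_values(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 200))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert bh_adjust(p) == pytest.approx(q_sm, rel=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(1e-6, 1, size=500)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_cutoff_step_up_enumeration(self):
        assert bh_p_cutoff([0.001, 0.01, 0.02, 0.2, 0.5], 0.05) == 0.02

    def test_cutoff_zero_when_nothing_passes(self):
        assert bh_p_cutoff([0.9, 0.8, 0.95], 0.05) == 0.0

    def test_cutoff_selection_equivalence_on_random_vectors(self, rng):
        """Selecting p <= cutoff equals selecting BH q <= fdr."""
        for _ in range(100):
            p = rng.uniform(1e-5, 1, size=rng.integers(2, 300)) ** 2
            fdr = rng.uniform(0.01, 0.2)
            cutoff = bh_p_cutoff(p, fdr)
            by_cutoff = p <= cutoff if cutoff > 0 else np.zeros_like(p, bool)
            by_q = bh_adjust(p) <= fdr
            assert (by_cutoff == by_q).all()


class TestSelectSignificant:
    @pytest.fixture
    def results(self):
        frame = pd.DataFrame({
            "probe_id": ["p1", "p2", "p3", "p4"],
            "group": ["B"] * 4,
            "log2_diff": [2.3, 0.58, 2.0, -2.0],
            "signed_fc": [5.0, 1.5, 4.0, -4.0],
            "p_raw": [0.001, 0.0001, 0.002, 0.001],
            "q_bh": [0.2, 0.001, 0.01, 0.01],
            "degenerate": [False] * 4,
        }).set_index(["probe_id", "group"])
        return frame

    def test_fails_fdr_gate(self, results):
        sig = select_significant(results, 2.0, 0.05)
        assert "p1" not in sig["B"]  # fc 5 but q 0.2

    def test_fails_fold_change_gate(self, results):
        sig = select_significant(results, 2.0, 0.05)
        assert "p2" not in sig["B"]  # q tiny but fc 1.5

    def test_signs_assigned(self, results):
        sig = select_significant(results, 2.0, 0.05)
        assert sig["B"] == {"p3": "up", "p4": "down"}

    def test_monotone_in_both_thresholds(self, design):
        matrix, _ = synthetic.generate_mrna_matrix(design, 300, 15, 2.0, 0.3, seed=8)
        results = run_contrasts(matrix, design)
        base = select_significant(results, 2.0, 0.05)
        stricter_fc = select_significant(results, 4.0, 0.05)
        stricter_fdr = select_significant(results, 2.0, 0.01)
        for group in base:
            assert set(stricter_fc[group]) <= set(base[group])
            assert set(stricter_fdr[group]) <= set(base[group])


class TestPatternClassification:
    @pytest.mark.parametrize("sig, platform, expected", [
        ({"A": {"x": "up"}, "B": {}, "C": {}}, "mRNA", "1"),
        ({"A": {"x": "down"}, "B": {}, "C": {}}, "mRNA", "2"),
        ({"A": {}, "B": {"x": "up"}, "C": {}}, "mRNA", "3"),
        ({"A": {}, "B": {"x": "down"}, "C": {}}, "mRNA", "4"),
        ({"A": {}, "B": {"x": "up"}, "C": {"x": "up"}}, "mRNA", "5"),
        ({"A": {}, "B": {"x": "down"}, "C": {"x": "down"}}, "mRNA", "6"),
        ({"A": {}, "B": {}, "C": {"x": "up"}}, "mRNA", "7"),
        ({"A": {}, "B": {}, "C": {"x": "down"}}, "mRNA", "8"),
        ({"A": {}, "B": {"x": "up"}, "C": {"x": "down"}}, "mRNA", "discordant"),
        ({"A": {"x": "down"}, "B": {}, "C": {}}, "miRNA", "1"),
        ({"A": {"x": "up"}, "B": {}, "C": {}}, "miRNA", "2"),
        ({"A": {}, "B": {"x": "up"}, "C": {"x": "up"}}, "miRNA", "5"),
        ({"A": {}, "B": {}, "C": {"x": "up"}}, "miRNA", "6"),
        ({"A": {}, "B": {}, "C": {"x": "down"}}, "miRNA", "discordant"),
    ])
    def test_label_table(self, sig, platform, expected):
        assert classify_patterns(sig, platform)["x"] == expected

    def test_every_significant_probe_gets_exactly_one_label(self, design):
        matrix, _ = synthetic.generate_mrna_matrix(design, 500, 20, 2.5, 0.25, seed=2,
                                                   n_shared_bc=10)
        results = run_contrasts(matrix, design)
        sig = select_significant(results, 2.0, 0.05)
        labels = classify_patterns(sig, "mRNA")
        union = set().union(*sig.values())
        assert set(labels) == union

    def test_unknown_platform_rejected(self):
        with pytest.raises(ValueError, match="platform"):
            classify_patterns({}, "protein")


def test_null_pvalues_uniform_smoke(design):
    """Single-seed null: contrast p-values look uniform (KS at alpha 0.01)."""
    matrix, _ = synthetic.generate_mrna_matrix(design, 2000, 0, 0.0, 1.0, seed=3)
    results = run_contrasts(matrix, design)
    for group in ("A", "B", "C"):
        p = results.xs(group, level="group")["p_raw"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01
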