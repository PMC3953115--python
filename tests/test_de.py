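"""Differential-expression screens: the t statistics against independent
oracles, Bonferroni/BH behaviour, the fold-change boundary, and recovery of
planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from nsclcmir.cohort import CohortDesign, default_truth, generate_mrna_arrays
from nsclcmir.de import (bonferroni, fold_change_filter, mirna_de_screen,
                         mrna_de_screen, one_sample_t, welch_t)
from nsclcmir.errors import UndefinedStatisticError

from conftest import make_matrix


class TestOneSampleT:
    def test_symmetric_values_give_t0_p1(self):
        t, p = one_sample_t([-0.5, -0.25, 0.25, 0.5])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_is_an_error(self):
        with pytest.raises(UndefinedStatisticError, match="zero variance"):
            one_sample_t([0.5, 0.5, 0.5, 0.5])

    def test_too_few_values_is_an_error(self):
        with pytest.raises(UndefinedStatisticError):
            one_sample_t([0.5, np.nan])

    def test_matches_scipy_to_1e12(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            v = rng.normal(0.1, 0.3, size=rng.integers(3, 20))
            t, p = one_sample_t(v)
            ref = stats.ttest_1samp(v, 0.0)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_example_vector_against_t_cdf(self):
        v = np.array([0.2, 0.4, 0.3, 0.5, 0.1])
        t, p = one_sample_t(v)
        expected_p = 2 * stats.t.sf(abs(t), df=4)
        assert p == pytest.approx(expected_p, abs=1e-12)


class TestWelchT:
    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            a = rng.normal(0, 1, size=rng.integers(3, 15))
            b = rng.normal(0.5, 2, size=rng.integers(3, 15))
            t, p = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], m=5)[0] == pytest.approx(0.05)
        assert bonferroni([0.5], m=10)[0] == 1.0  # capped

    def test_vector_matches_statsmodels(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=40)
        ours = bonferroni(p)
        ref = multipletests(p, method="bonferroni")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-15)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=100)
        assert np.all(bonferroni(p, m=150) >= p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])
        with pytest.raises(ValueError, match="smaller"):
            bonferroni([0.1, 0.2], m=1)


class TestFoldChangeFilter:
    @pytest.mark.parametrize("mean,passes", [
        (0.301, True),      # log10(2): exactly 2-fold passes
        (0.3, False),       # boundary is strict
        (-0.3, False),
        (-0.35, True),
        (0.0, False),
    ])
    def test_strict_boundary(self, mean, passes):
        assert fold_change_filter(mean) is passes

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fold_change_filter(np.nan)


class TestMrnaScreen:
    def test_planted_recovery_and_null_rejection(self):
        design = CohortDesign(seed=1)
        truth = default_truth(design)
        x = generate_mrna_arrays(design, truth)
        res = mrna_de_screen(x)
        hits = res[res["de"]]
        flagged = set(zip(hits["feature"], hits["group"]))
        # all 50 planted genes flagged in their planted subtype (seed 1)
        assert all((g, s) in flagged for g, s, _ in truth.de_genes)
        planted = {g for g, _, _ in truth.de_genes}
        null_flags = hits[~hits["feature"].isin(planted)]
        assert len(null_flags) == 0

    def test_t_pass_without_fold_change_is_not_de(self):
        # strong but small effect: tiny sd, mean 0.2 < 0.3
        rng = np.random.default_rng(5)
        values = np.vstack([
            0.2 + rng.normal(0, 0.01, size=12),
            rng.normal(0, 0.01, size=12),
        ])
        x = make_matrix(values, "SSSSSSAAAAAA")
        res = mrna_de_screen(x)
        g0 = res[res["feature"] == "g0"]
        assert g0["passes_t"].any()
        assert not g0["de"].any()

    def test_result_invariant_to_sample_and_gene_order(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 0.2, size=(8, 10))
        x = make_matrix(values, "SSSSSAAAAA")
        res = mrna_de_screen(x).set_index(["feature", "group"]).sort_index()
        perm_g = rng.permutation(8)
        perm_s = rng.permutation(10)
        x2 = make_matrix(values[np.ix_(perm_g, perm_s)],
                         np.array(list("SSSSSAAAAA"))[perm_s],
                         genes=[f"g{i}" for i in perm_g])
        res2 = mrna_de_screen(x2).set_index(["feature", "group"]).sort_index()
        pd.testing.assert_frame_equal(res, res2, check_like=True)

    def test_two_sample_contrast_mode(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 0.1, size=(5, 12))
        values[0, :6] += 1.0  # up in SCC
        x = make_matrix(values, "SSSSSSAAAAAA")
        res = mrna_de_screen(x, contrast="two-sample")
        assert res["group"].iloc[0] == "S_vs_A"
        assert res.loc[res["feature"] == "g0", "de"].iloc[0]


def relquant_frame(delta_cts, detected=None):
    """Build a minimal relative-quant frame for the miRNA screen."""
    rows = []
    for assay, per_patient in delta_cts.items():
        for patient, dct in per_patient.items():
            det = True if detected is None else detected[assay][patient]
            rows.append({"assay": assay, "patient_id": patient,
                         "delta_ct": dct if det else np.nan,
                         "rel_expr": 2.0 ** -dct if det else np.nan,
                         "ddct": np.nan, "rel_expr_paired": np.nan,
                         "detected": det})
    return pd.DataFrame(rows)


class TestMirnaScreen:
    def test_detection_rule_excludes_sub_80pct(self):
        # 19 patients, detected in 15 -> 78.9% < 80%: excluded
        patients = [f"P{i}" for i in range(19)]
        subtypes = {p: ("SCC" if i < 10 else "AD") for i, p in enumerate(patients)}
        dcts = {"m1": {p: float(i) for i, p in enumerate(patients)}}
        det = {"m1": {p: i >= 4 for i, p in enumerate(patients)}}
        res = mirna_de_screen(relquant_frame(dcts, det), subtypes)
        assert len(res) == 0 or "m1" not in set(res["feature"])

    def test_exactly_80pct_is_kept(self):
        patients = [f"P{i}" for i in range(20)]
        subtypes = {p: ("SCC" if i < 10 else "AD") for i, p in enumerate(patients)}
        rng = np.random.default_rng(8)
        dcts = {"m1": {p: float(rng.normal()) for p in patients}}
        det = {"m1": {p: i >= 4 for i, p in enumerate(patients)}}  # 16/20
        res = mirna_de_screen(relquant_frame(dcts, det), subtypes)
        assert set(res["feature"]) == {"m1"}

    def test_identical_groups_not_de(self):
        patients = [f"P{i}" for i in range(12)]
        subtypes = {p: ("SCC" if i % 2 else "AD") for i, p in enumerate(patients)}
        rng = np.random.default_rng(9)
        dcts = {"m1": {p: float(rng.normal(5, 0.5)) for p in patients}}
        res = mirna_de_screen(relquant_frame(dcts), subtypes)
        assert not res["de"].any()

    def test_planted_mirna_flagged_with_direction(self):
        patients = [f"P{i}" for i in range(20)]
        subtypes = {p: ("SCC" if i < 10 else "AD") for i, p in enumerate(patients)}
        rng = np.random.default_rng(10)
        dcts = {
            # up in SCC: dCt lower by 2 in SCC
            "hot": {p: float(rng.normal(0 if subtypes[p] == "SCC" else 2, 0.3))
                    for p in patients},
            "null": {p: float(rng.normal(1, 0.3)) for p in patients},
        }
        res = mirna_de_screen(relquant_frame(dcts), subtypes)
        hot = res[res["feature"] == "hot"].iloc[0]
        assert hot["de"] and hot["group"] == "SCC"
        assert not res[res["feature"] == "null"]["de"].any()

    def test_bh_qvalues_monotone_in_sorted_p(self):
        patients = [f"P{i}" for i in range(16)]
        subtypes = {p: ("SCC" if i < 8 else "AD") for i, p in enumerate(patients)}
        rng = np.random.default_rng(11)
        dcts = {f"m{j}": {p: float(rng.normal(0.2 * j * (subtypes[p] == "SCC"),
                                              0.5))
                          for p in patients} for j in range(8)}
        res = mirna_de_screen(relquant_frame(dcts), subtypes)
        srt = res.sort_values("p_raw")
        assert (np.diff(srt["p_adj"]) >= -1e-12).all()
        assert (res["p_adj"] >= res["p_raw"] - 1e-12).all()

    def test_nothing_detected_warns_and_returns_empty(self):
        patients = ["P0", "P1", "P2", "P3"]
        subtypes = {p: ("SCC" if i < 2 else "AD") for i, p in enumerate(patients)}
        det = {"m1": {p: False for p in patients}}
        dcts = {"m1": {p: 1.0 for p in patients}}
        with pytest.warns(UserWarning, match="detection"):
            res = mirna_de_screen(relquant_frame(dcts, det), subtypes)
        assert len(res) == 0
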