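import numpy as np
import pandas as pd
import pytest

from mirsig import (
    ClinicalScores,
    compare_small_rna_fractions,
    correlate_clinical,
    flag_outlier_patient,
    spearman_rho,
)
from mirsig.array_io import SampleSheet
from mirsig.errors import UndefinedCorrelationError, ValidationError
from oracles import oracle_spearman


class TestSpearman:
    def test_perfect_concordance(self):
        rho, _p = spearman_rho([1, 2, 3, 5, 8], [10, 20, 21, 40, 41])
        assert rho == pytest.approx(1.0)

    def test_perfect_discordance(self):
        rho, p = spearman_rho([1, 2, 3, 4, 5], [9, 7, 5, 3, 1])
        assert rho == pytest.approx(-1.0)
        # only 2 of 120 permutations reach |rho| = 1
        assert p == pytest.approx(2 / 120)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_tie_case_matches_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [10.0, 9.0, 12.0, 11.0, 11.0]
        rho, p = spearman_rho(x, y)
        rho_o, p_o = oracle_spearman(x, y)
        assert rho == pytest.approx(rho_o)
        assert p == pytest.approx(p_o)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v ** 3])
    def test_invariant_under_monotone_transforms(self, transform):
        rng = np.random.default_rng(17)
        x = rng.normal(size=8)
        y = 0.5 * x + rng.normal(size=8)
        rho, p = spearman_rho(x, y)
        rho_t, p_t = spearman_rho(transform(x), transform(y))
        assert rho == pytest.approx(rho_t)
        assert p == pytest.approx(p_t)

    def test_exact_and_t_approximation_agree_loosely(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            _rho, p_exact = spearman_rho(x, y, exact_max_n=9)
            _rho, p_approx = spearman_rho(x, y, exact_max_n=0)
            assert abs(p_exact - p_approx) < 0.05


class TestClinicalScores:
    def test_range_validation(self):
        with pytest.raises(ValidationError):
            ClinicalScores("S", fiq_total=120.0, mfi_gf=10, mfi_pf=10,
                           mfi_mf=10, mfi_ra=10, mfi_rm=10)
        ClinicalScores("S", 74.11, 18.64, 17.64, 14.27, 15.0, 13.0)


def patient_sheet(n_fm=11, n_ctrl=10, rng=None):
    rng = rng or np.random.default_rng(31)
    samples = [f"FM{i}" for i in range(n_fm)] + [f"C{i}" for i in range(n_ctrl)]
    df = pd.DataFrame({
        "sample_id": samples,
        "group": ["FM"] * n_fm + ["control"] * n_ctrl,
        "FIQ": rng.uniform(40, 95, len(samples)),
        "GF": rng.uniform(10, 20, len(samples)),
        "PF": rng.uniform(10, 20, len(samples)),
        "MF": rng.uniform(8, 19, len(samples)),
        "RA": rng.uniform(5, 20, len(samples)),
        "RM": rng.uniform(5, 20, len(samples)),
    })
    return SampleSheet(df)


class TestCorrelateClinical:
    def test_six_scores_times_k_mirnas(self):
        rng = np.random.default_rng(4)
        sheet = patient_sheet(rng=rng)
        expr = pd.DataFrame(rng.uniform(1, 50, (3, 21)),
                            index=["a", "b", "c"],
                            columns=sheet.sample_ids)
        results = correlate_clinical(expr, sheet)
        assert len(results) == 6 * 3
        assert all(r.n == 11 for r in results)  # patients only, complete

    def test_pairwise_deletion_reports_cell_n(self):
        rng = np.random.default_rng(4)
        sheet = patient_sheet(rng=rng)
        expr = pd.DataFrame(rng.uniform(1, 50, (1, 21)), index=["a"],
                            columns=sheet.sample_ids)
        expr.loc["a", ["FM0", "FM1"]] = np.nan
        results = correlate_clinical(expr, sheet)
        assert all(r.n == 9 for r in results)

    def test_implanted_monotone_association_recovered(self):
        sheet = patient_sheet()
        mf = sheet.clinical().loc[[s for s in sheet.samples_in_group("FM")], "MF"]
        expr = pd.DataFrame(
            {s: [float(np.exp(-0.3 * mf[s]))] if s in mf.index else [1.0]
             for s in sheet.sample_ids}, index=["a"])
        results = {r.score_name: r for r in correlate_clinical(expr, sheet)}
        assert results["MF"].rho == pytest.approx(-1.0)
        assert results["MF"].p_value < 0.05

    def test_too_few_pairs_flagged(self):
        sheet = patient_sheet()
        expr = pd.DataFrame(np.full((1, 21), 5.0), index=["a"],
                            columns=sheet.sample_ids)
        expr.loc["a", [f"FM{i}" for i in range(9)]] = np.nan
        results = correlate_clinical(expr, sheet)
        assert all(not r.computable and r.n == 2 for r in results)


class TestSmallRnaFractions:
    def test_identical_groups(self):
        frac = {"FM0": 0.15, "FM1": 0.14, "FM2": 0.16,
                "C0": 0.15, "C1": 0.14, "C2": 0.16}
        groups = {s: ("FM" if s.startswith("FM") else "control")
                  for s in frac}
        out = compare_small_rna_fractions(frac, groups)
        assert out["fm_mean"] == pytest.approx(out["control_mean"])
        assert out["p_value"] > 0.9

    def test_generator_level_fractions_recovered(self, default_cohort):
        sheet = default_cohort.sample_sheet
        out = compare_small_rna_fractions(sheet.small_rna_fractions(),
                                          sheet.groups)
        # group means within 3 standard errors of the generating means
        assert abs(out["control_mean"] - 0.140) < 3 * 0.034 / np.sqrt(10)
        assert abs(out["fm_mean"] - 0.161) < 3 * 0.102 / np.sqrt(11)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            compare_small_rna_fractions({"A": 1.2, "B": 0.5},
                                        {"A": "FM", "B": "control"})


class TestOutlierPatient:
    def build(self, case_levels, control_levels, mf_scores):
        n_fm, n_ctrl = len(mf_scores), len(control_levels[0])
        samples = ([f"FM{i}" for i in range(n_fm)]
                   + [f"C{i}" for i in range(n_ctrl)])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": samples,
            "group": ["FM"] * n_fm + ["control"] * n_ctrl,
            "MF": list(mf_scores) + [5.0] * n_ctrl,
        }))
        ids = [f"m{k}" for k in range(len(case_levels))]
        expr = pd.DataFrame(
            np.hstack([np.asarray(case_levels, float),
                       np.asarray(control_levels, float)]),
            index=ids, columns=samples)
        return expr, sheet, ids

    def test_near_control_patient_flagged(self):
        # patient FM2 has the lowest mental-fatigue score and near-control
        # levels for 4 of 5 signature miRNAs
        case = [[1.0, 1.2, 9.0, 1.1], [2.0, 2.1, 18.0, 2.2],
                [1.5, 1.4, 12.0, 1.6], [3.0, 3.2, 30.0, 2.9],
                [2.0, 2.2, 1.9, 2.1]]
        ctrl = [[10.0, 12.0], [20.0, 22.0], [15.0, 14.0],
                [28.0, 33.0], [20.0, 21.0]]
        mf = [15.0, 14.0, 8.0, 16.0]
        expr, sheet, ids = self.build(case, ctrl, mf)
        report = flag_outlier_patient(expr, sheet, ids)
        assert report["flagged_sample"] == "FM2"
        assert report["score_value"] == 8.0
        assert report["n_highest_in_fm"] >= 4
        assert report["n_exceed_control_min"] >= 1

    def test_identical_cases_zero_exceedances(self):
        case = [[2.0, 2.0, 2.0]] * 3
        ctrl = [[5.0, 6.0]] * 3
        expr, sheet, ids = self.build(case, ctrl, [10.0, 12.0, 14.0])
        report = flag_outlier_patient(expr, sheet, ids)
        assert report["flagged_sample"] == "FM0"  # unique argmin
        assert report["n_exceed_control_min"] == 0

    def test_score_tie_breaks_by_sample_id(self):
        case = [[1.0, 2.0, 3.0]]
        ctrl = [[4.0]]
        expr, sheet, ids = self.build(case, ctrl, [9.0, 9.0, 12.0])
        report = flag_outlier_patient(expr, sheet, ids)
        assert report["flagged_sample"] == "FM0"
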