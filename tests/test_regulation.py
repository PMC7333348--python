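"""ANOVA/Tukey statistics and the stability-selection regulation calls."""

import math

import numpy as np
import pytest
from scipy import stats

from phosphokin import regulation
from phosphokin.core import ImputationModel
from phosphokin.regulation import (
    RegulationParams,
    anova_tukey,
    condition_direction,
    protein_regulation,
    stability_select,
    studentized_range_sf,
)

from conftest import matrix_from_array

LOG_FC = math.log2(1.75)


class TestStudentizedRange:
    @pytest.mark.parametrize("k,df", [(3, 6), (6, 18), (6, 10), (4, 30)])
    def test_matches_scipy_distribution(self, k, df):
        qs = np.array([0.5, 1.5, 2.5, 3.5, 4.5, 6.0])
        mine = studentized_range_sf(qs, k, df)
        ref = stats.studentized_range.sf(qs, k, df)
        assert np.max(np.abs(mine - ref)) < 1e-9

    def test_critical_value_matches_scipy_ppf(self):
        assert regulation._q_crit(0.05, 6, 18) == pytest.approx(
            stats.studentized_range.ppf(0.95, 6, 18), abs=1e-6
        )


class TestAnovaTukey:
    def test_constant_equal_groups_give_p_one(self):
        vals = {c: [5.0, 5.0, 5.0] for c in (0, 15, 30)}
        p, pairs = anova_tukey(vals)
        assert p == 1.0
        assert all(pr.log2_fc == 0.0 for pr in pairs)

    def test_textbook_oneway_anova(self):
        """Balanced 3x3 fixture against a hand-computed F statistic."""
        vals = {0: [1.0, 2.0, 3.0], 15: [4.0, 5.0, 6.0], 30: [7.0, 8.0, 9.0]}
        # group means 2, 5, 8; grand 5; SSB = 3*(9+0+9) = 54, dfb = 2
        # SSW = 6 * 1 = 6, dfw = 6 -> F = 27 / 1 = 27
        p, _ = anova_tukey(vals)
        assert p == pytest.approx(float(stats.f.sf(27.0, 2, 6)))
        assert p == pytest.approx(
            stats.f_oneway(*[vals[c] for c in sorted(vals)]).pvalue
        )

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(8)
        vals = {c: list(rng.normal(m, 0.5, 4)) for c, m in [(0, 10), (15, 11), (30, 10.2)]}
        _, pairs = anova_tukey(vals)
        data = np.concatenate([vals[c] for c in sorted(vals)])
        groups = np.concatenate([[c] * 4 for c in sorted(vals)])
        ref = pairwise_tukeyhsd(data, groups)
        assert np.allclose([pr.tukey_p for pr in pairs], ref.pvalues, atol=1e-8)
        assert np.allclose([pr.log2_fc for pr in pairs], ref.meandiffs, atol=1e-12)

    def test_tukey_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 0.4, 5) for m in (20.0, 20.5, 22.0, 21.0)]
        vals = {c: list(g) for c, g in zip((0, 15, 30, 120), groups)}
        _, pairs = anova_tukey(vals)
        ref = stats.tukey_hsd(*groups)
        for pr in pairs:
            i = (0, 15, 30, 120).index(pr.pair[0])
            j = (0, 15, 30, 120).index(pr.pair[1])
            assert pr.tukey_p == pytest.approx(float(ref.pvalue[i, j]), abs=1e-8)

    def test_too_few_conditions_error(self):
        with pytest.raises(ValueError):
            anova_tukey({0: [1.0, 2.0], 15: [1.0]})


def _flat_site(level=20.0, n_reps=4, n_conds=6):
    return np.full((1, n_reps, n_conds), level)


def _step_site(base=20.0, high=23.0, sd=0.2, seed=0, n_reps=4):
    rng = np.random.default_rng(seed)
    arr = rng.normal(base, sd, (1, n_reps, 6))
    arr[0, :, 4:] += high - base
    return arr


class TestStabilitySelect:
    def test_no_missing_is_deterministic(self):
        arr = np.concatenate([_step_site(seed=1), _flat_site() + 0.01], axis=0)
        m = matrix_from_array(arr)
        res = stability_select(m, RegulationParams(n_iter=10, base_seed=0),
                               model=ImputationModel(q05=15, sigma=2, seed=0))
        for call in res.calls:
            assert call.stability_fraction in (0.0, 1.0)
        res2 = stability_select(m, RegulationParams(n_iter=10, base_seed=99),
                                model=ImputationModel(q05=15, sigma=2, seed=99))
        assert [c.regulated for c in res.calls] == [c.regulated for c in res2.calls]

    def test_engineered_step_site_is_regulated(self):
        """log2 FC = 3 at 300/600 s vs sd 0.2 passes every criterion."""
        m = matrix_from_array(_step_site(seed=2))
        res = stability_select(m, RegulationParams(n_iter=5, base_seed=0),
                               model=ImputationModel(q05=15, sigma=2, seed=0))
        call = res.calls[0]
        assert call.regulated
        assert abs(call.best_pair.log2_fc) >= LOG_FC
        assert call.best_pair.tukey_p <= 0.05

    def test_null_type_one_error(self):
        """i.i.d. null sites are called regulated at most ~alpha of the time."""
        rng = np.random.default_rng(5)
        arr = rng.normal(20, 0.3, (500, 4, 6))
        m = matrix_from_array(arr)
        res = stability_select(m, RegulationParams(n_iter=1, base_seed=0),
                               model=ImputationModel(q05=19, sigma=0.5, seed=0))
        frac = np.mean([c.regulated for c in res.calls])
        se = math.sqrt(0.05 * 0.95 / 500)
        assert frac <= 0.05 + 2 * se

    def test_monotone_in_fc_and_frac_thresholds(self):
        rng = np.random.default_rng(6)
        arr = rng.normal(20, 0.5, (60, 4, 6))
        arr[:20, :, 3:] += rng.uniform(0.5, 1.5, (20, 1, 3))
        arr[rng.random(arr.shape) < 0.15] = np.nan
        m = matrix_from_array(arr)
        model = ImputationModel(q05=18.5, sigma=1.0, seed=0)
        reg_sets = []
        for fc_min in (1.2, 1.75, 2.5):
            res = stability_select(
                m, RegulationParams(n_iter=20, base_seed=0,
                                    log2_fc_min=math.log2(fc_min)), model=model)
            reg_sets.append(set(res.regulated_ids))
        assert reg_sets[2] <= reg_sets[1] <= reg_sets[0]
        fracs = []
        for frac_min in (0.5, 0.9, 1.0):
            res = stability_select(
                m, RegulationParams(n_iter=20, base_seed=0, frac_min=frac_min),
                model=model)
            fracs.append(set(res.regulated_ids))
        assert fracs[2] <= fracs[1] <= fracs[0]

    def test_pair_needs_more_than_two_observed_points(self):
        """A strong effect seen in only 2 observed replicates cannot qualify."""
        arr = _step_site(seed=3)
        arr[0, 2:, 4:] = np.nan  # high conditions observed in 2 reps only
        m = matrix_from_array(arr)
        res = stability_select(m, RegulationParams(n_iter=10, base_seed=0),
                               model=ImputationModel(q05=15, sigma=2, seed=0))
        assert not res.calls[0].regulated

    def test_n_iter_validation(self):
        m = matrix_from_array(_flat_site())
        with pytest.raises(ValueError):
            stability_select(m, RegulationParams(n_iter=0))


class TestConditionDirection:
    def test_step_up_site_directions(self):
        m = matrix_from_array(_step_site(seed=4))
        res = stability_select(m, RegulationParams(n_iter=5, base_seed=0),
                               model=ImputationModel(q05=15, sigma=2, seed=0))
        df = condition_direction(res)
        assert df.loc[res.site_ids[0], 300] == "up"
        assert df.loc[res.site_ids[0], 600] == "up"
        assert df.loc[res.site_ids[0], 15] == "none"

    def test_flat_site_is_none_everywhere(self):
        rng = np.random.default_rng(7)
        m = matrix_from_array(rng.normal(20, 0.2, (1, 4, 6)))
        res = stability_select(m, RegulationParams(n_iter=5, base_seed=0),
                               model=ImputationModel(q05=15, sigma=2, seed=0))
        assert (condition_direction(res).iloc[0] == "none").all()

    def test_sign_antisymmetry(self):
        """Negating deviations from baseline swaps up and down labels."""
        arr = _step_site(seed=8)
        m_up = matrix_from_array(arr)
        m_down = matrix_from_array(2 * 20.0 - arr)
        model = ImputationModel(q05=15, sigma=2, seed=0)
        d_up = condition_direction(
            stability_select(m_up, RegulationParams(n_iter=5), model=model))
        d_down = condition_direction(
            stability_select(m_down, RegulationParams(n_iter=5), model=model))
        swap = {"up": "down", "down": "up", "none": "none"}
        assert (d_up.map(lambda x: swap[x]).to_numpy() == d_down.to_numpy()).all()


class TestProteinRegulation:
    def test_single_unique_peptide_excluded(self):
        rng = np.random.default_rng(12)
        arr = np.stack([_step_site(seed=9)[0], rng.normal(20, 0.3, (4, 6))])
        m = matrix_from_array(arr)
        m.site_meta["unique_peptides"] = [1, 5]
        res = protein_regulation(m, RegulationParams.protein_defaults(
            n_iter=5, base_seed=0))
        assert res.site_ids == [m.site_meta.index[1]]

    def test_fourfold_step_is_regulated(self):
        """A 4x abundance step (log2 FC = 2 >= 1) is called regulated."""
        arr = _step_site(base=23.0, high=25.0, sd=0.15, seed=10)
        m = matrix_from_array(arr)
        m.site_meta["unique_peptides"] = [8]
        res = protein_regulation(m, RegulationParams.protein_defaults(
            n_iter=5, base_seed=0))
        assert res.calls[0].regulated
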