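"""Normalization, filters and imputation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosphokin import preprocess
from phosphokin.core import ImputationModel, SiteRecord

from conftest import make_design, matrix_from_array


def _record(site_id="s1_M1", pep=0.001, contaminant=False, reverse=False,
            loc=(0.9,), residues=("S",), intensity=None):
    return SiteRecord(
        site_id=site_id,
        protein_ids=["P1"],
        gene_name="G",
        positions=list(range(1, len(residues) + 1)),
        residues=list(residues),
        multiplicity=1,
        localization_prob={chr(ord("A") + i): p for i, p in enumerate(loc)},
        pep=pep,
        is_contaminant=contaminant,
        is_reverse=reverse,
        raw_intensity=intensity or {},
    )


class TestIrtNormalize:
    def _raw(self, values, runs):
        """Run-level matrix with given log2 values."""
        design = make_design(reps=["A"], conds=[0, 15], n_tech=1)
        data = pd.DataFrame([values], index=["s1_M1"], columns=runs)
        m = matrix_from_array(np.zeros((1, 1, 2)), site_ids=["s1_M1"])
        return m.replace(data=data, design=design, stage="raw")

    def test_identical_irt_leaves_matrix_unchanged(self):
        design = make_design(reps=["A"], conds=[0, 15], n_tech=1)
        runs = design.runs
        irt = pd.DataFrame(
            [{"run_id": r, "peptide": f"p{i}", "intensity": 1000.0 * (i + 1)}
             for r in runs for i in range(3)]
        )
        m = self._raw([12.0, 13.0], runs)
        out = preprocess.irt_normalize(m, irt)
        assert np.allclose(out.data.to_numpy(), m.data.to_numpy())
        assert np.allclose(out.irt_offsets.to_numpy(), 0.0)

    def test_fourfold_bias_gives_offset_two(self):
        """iRT at 4x in run B vs run A -> offsets differ by 2 log2 units."""
        design = make_design(reps=["A"], conds=[0, 15], n_tech=1)
        a, b = design.runs
        irt = pd.DataFrame(
            [{"run_id": a, "peptide": "p1", "intensity": 1000.0},
             {"run_id": b, "peptide": "p1", "intensity": 4000.0}]
        )
        m = self._raw([12.0, 14.0], [a, b])
        out = preprocess.irt_normalize(m, irt)
        off = out.irt_offsets
        assert off[b] - off[a] == pytest.approx(2.0)
        assert out.data.iloc[0, 0] == pytest.approx(out.data.iloc[0, 1])

    def test_offset_recovery_from_simulated_biases(self):
        """Recovered offsets match the simulated per-run biases within 0.05."""
        rng = np.random.default_rng(4)
        design = make_design(n_tech=3)
        runs = design.runs
        true_off = rng.normal(0, 0.5, len(runs))
        base = rng.uniform(18, 24, 11)
        rows = []
        for j, r in enumerate(runs):
            for p in range(11):
                rows.append({"run_id": r, "peptide": f"iRT{p}",
                             "intensity": 2.0 ** (base[p] + true_off[j]
                                                  + rng.normal(0, 0.02))})
        irt = pd.DataFrame(rows)
        off = preprocess.irt_offsets(irt, runs)
        centered = true_off - true_off.mean()
        assert np.max(np.abs(off.to_numpy() - centered)) < 0.05

    def test_run_without_irt_gets_zero_offset(self):
        design = make_design(reps=["A"], conds=[0, 15], n_tech=1)
        a, b = design.runs
        irt = pd.DataFrame([{"run_id": a, "peptide": "p1", "intensity": 1000.0}])
        off = preprocess.irt_offsets(irt, [a, b])
        assert off[b] == 0.0


class TestQualityFilter:
    def test_pep_threshold_direction(self):
        recs = [_record("a_M1", pep=0.02), _record("b_M1", pep=0.005)]
        kept = preprocess.quality_filter(recs)
        assert [r.site_id for r in kept] == ["b_M1"]

    def test_counts_on_mixed_fixture(self):
        recs = (
            [_record(f"c{i}_M1", contaminant=True) for i in range(3)]
            + [_record(f"p{i}_M1", pep=0.02) for i in range(2)]
            + [_record(f"k{i}_M1") for i in range(5)]
        )
        kept = preprocess.quality_filter(recs)
        assert len(kept) == 5
        assert preprocess.quality_filter(kept) == kept  # idempotent


class TestLocalizationFilter:
    @pytest.mark.parametrize(
        "probs,kept,cls",
        [((0.60, 0.80), True, 1), ((0.60, 0.70), False, 2), ((0.75,), True, 2),
         ((0.2,), False, 4), ((0.4,), False, 3)],
    )
    def test_threshold_and_classes(self, probs, kept, cls):
        rec = _record(loc=probs)
        out = preprocess.localization_filter([rec])
        assert (len(out) == 1) is kept
        assert rec.loc_class == cls


class TestCrossFilter:
    def _channel_pair(self):
        mt = matrix_from_array(np.zeros((3, 2, 2)), conds=[0, 15],
                               reps=["A", "B"], site_ids=["t1", "t2", "t3"])
        mp = matrix_from_array(np.zeros((3, 2, 2)), conds=[0, 15],
                               reps=["A", "B"], site_ids=["p1", "p2", "p3"])
        # t1/p1 share a pY key; t2 is a TiO2-only pY; p2 is a stray pS; p3 pY
        mt.site_meta["residue_class"] = ["Y", "Y", "ST"]
        mt.site_meta["site_key"] = ["K1", "K2", "K3"]
        mp.site_meta["residue_class"] = ["Y", "ST", "Y"]
        mp.site_meta["site_key"] = ["K1", "K4", "K5"]
        return mt, mp

    def test_residue_routing(self):
        mt, mp = self._channel_pair()
        out_t, out_p = preprocess.enrichment_cross_filter(mt, mp)
        assert list(out_p.sites) == ["p1", "p3"]  # pS removed from pY-IP
        assert "t1" not in out_t.sites  # pY quantified in pY-IP leaves TiO2
        assert "t2" in out_t.sites  # pY never in pY-IP stays
        assert "t3" in out_t.sites  # pS untouched


class TestTechAverage:
    def test_mean_and_all_missing(self):
        design = make_design(reps=["A"], conds=[0], n_tech=3)
        data = pd.DataFrame([[10.0, 12.0, np.nan]], index=["s1_M1"],
                            columns=design.runs)
        m = matrix_from_array(np.zeros((1, 1, 1)), reps=["A"], conds=[0], site_ids=["s1_M1"])
        m = m.replace(data=data, design=design, stage="irt_normalized")
        out = preprocess.average_tech_replicates(m)
        assert out.data.iloc[0, 0] == pytest.approx(11.0)
        data.iloc[0] = np.nan
        out = preprocess.average_tech_replicates(
            m.replace(data=data, stage="irt_normalized"))
        assert np.isnan(out.data.iloc[0, 0])

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(0)
        design = make_design(reps=["A", "B"], conds=[0, 15, 30], n_tech=3)
        vals = rng.normal(20, 2, (5, len(design.runs)))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        data = pd.DataFrame(vals, index=[f"s{i}_M1" for i in range(5)],
                            columns=design.runs)
        m = matrix_from_array(np.zeros((5, 2, 3)), reps=["A", "B"], conds=[0, 15, 30], site_ids=[f"s{i}_M1" for i in range(5)])
        m = m.replace(data=data, design=design, stage="irt_normalized")
        out = preprocess.average_tech_replicates(m)
        for i in range(5):
            for rep in ["A", "B"]:
                for c in [0, 15, 30]:
                    cols = [r for r in design.runs if r.startswith(f"{rep}_") and f"_{c}s_" in r]
                    expected = np.nanmean(vals[i, [design.runs.index(x) for x in cols]]) \
                        if not np.all(np.isnan(vals[i, [design.runs.index(x) for x in cols]])) else np.nan
                    got = out.data.loc[f"s{i}_M1", (rep, c)]
                    assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)


class TestMissingnessFilter:
    def _pattern_matrix(self, pattern, n_reps=4, n_conds=6):
        arr = np.full((1, n_reps, n_conds), np.nan)
        for c, n in pattern.items():
            arr[0, :n, c] = 20.0
        return matrix_from_array(arr)

    @pytest.mark.parametrize(
        "pattern,kept",
        [({0: 3, 1: 2, 5: 2}, True), ({0: 3, 1: 1, 2: 1, 3: 1}, False)],
    )
    def test_stated_patterns(self, pattern, kept):
        m = self._pattern_matrix(pattern)
        out = preprocess.missingness_filter(m)
        assert (out.n_sites == 1) is kept

    def test_exhaustive_enumeration_oracle(self):
        """Agrees with brute-force counting over all 4-reps x 6-conds patterns."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = rng.integers(0, 5, 6)  # observed reps per condition
            arr = np.full((1, 4, 6), np.nan)
            for c, n in enumerate(counts):
                arr[0, :n, c] = 20.0
            kept = preprocess.missingness_filter(matrix_from_array(arr)).n_sites == 1
            assert kept == (sum(n >= 2 for n in counts) >= 3)


class TestImputation:
    def test_well_covered_condition_untouched(self):
        arr = np.full((1, 4, 6), 20.0)
        arr[0, 2:, 0] = np.nan  # 2 observed at condition 0
        m = matrix_from_array(arr)
        model = ImputationModel(q05=15.0, sigma=2.0, seed=0)
        out = preprocess.impute_missing(m, model)
        assert np.isnan(out.data.loc[:, pd.IndexSlice["C", 0]]).all()
        assert not out.imputed.to_numpy().any()

    def test_single_observed_condition_fills_rest(self):
        arr = np.full((1, 4, 6), 20.0)
        arr[0, 1:, 0] = np.nan  # 1 observed at condition 0
        out = preprocess.impute_missing(
            matrix_from_array(arr), ImputationModel(q05=15.0, sigma=2.0, seed=0))
        assert int(out.imputed.to_numpy().sum()) == 3
        assert out.data.notna().all().all()

    def test_draw_mean_matches_quantile(self):
        """Over 1e4 imputed cells the sample mean sits within 3 SE of q05."""
        S = 2500
        arr = np.full((S, 4, 6), 20.0)
        arr[:, :, 0] = np.nan  # every site: condition 0 fully missing
        model = ImputationModel(q05=14.0, sigma=2.0, c=0.3, seed=42)
        out = preprocess.impute_missing(matrix_from_array(arr), model)
        drawn = out.data.to_numpy().reshape(S, 4, 6)[:, :, 0].ravel()
        se = model.draw_sd / np.sqrt(drawn.size)
        assert abs(drawn.mean() - model.q05) < 3 * se

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(ValueError):
            ImputationModel(q05=15.0, sigma=0.0)

    def test_model_fit_quantile(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(21, 2.5, (200, 4, 6))
        model = preprocess.fit_imputation_model(matrix_from_array(arr))
        obs = arr.ravel()
        assert model.q05 == pytest.approx(np.quantile(obs, 0.05))
        assert model.sigma == pytest.approx(np.std(obs, ddof=1))


class TestReplicateNormalize:
    def test_constant_offset_collapses(self):
        base = np.array([20.0, 21, 22, 21, 20, 19])
        arr = np.stack([[base, base + 1.0]])
        out = preprocess.replicate_normalize(matrix_from_array(arr))
        a = out.data.to_numpy().reshape(1, 2, 6)
        assert np.allclose(a[0, 0], a[0, 1])
        # absolute scale preserved
        assert np.nanmean(a) == pytest.approx(np.nanmean(arr))

    def test_single_replicate_unchanged(self):
        arr = np.array([[[20.0, 21, 22, 21, 20, 19]]])
        out = preprocess.replicate_normalize(matrix_from_array(arr, reps=["A"]))
        assert np.allclose(out.data.to_numpy().ravel(), arr.ravel())

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_between_replicate_variance_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(20, 1, (3, 4, 6)) + rng.normal(0, 1, (3, 4, 1))
        out = preprocess.replicate_normalize(matrix_from_array(arr))
        a = out.data.to_numpy().reshape(3, 4, 6)
        before = np.var(arr, axis=1).sum()
        after = np.var(a, axis=1).sum()
        assert after <= before + 1e-9

    def test_no_cell_transitions_present_to_missing(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(20, 1, (5, 4, 6))
        arr[rng.random(arr.shape) < 0.2] = np.nan
        m = matrix_from_array(arr)
        out = preprocess.replicate_normalize(m)
        assert (m.data.notna() <= out.data.notna()).all().all()
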