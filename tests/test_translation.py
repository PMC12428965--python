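"""Translational ratio, deltaTR and the interaction test."""

import numpy as np
import pandas as pd
import pytest

from translatome.io import (
    NormalizedMatrix,
    collapse_technical_replicates,
    cpm_normalize,
)
from translatome.simulate import SimulationConfig, simulate_experiment
from translatome.translation import (
    TRMatrix,
    delta_tr,
    test_differential_translation as interaction_test,
    tr_normalize_million,
    translational_ratio,
)

NO_STRUCTURE = dict(
    n_transcription_up=0,
    n_transcription_down=0,
    n_translation_up=0,
    n_translation_down=0,
    n_stable_core=0,
    n_modules=0,
    n_translation_modules=0,
)


def _paired_nm(total_values, poly_values, genes, conditions):
    """Build per-condition single-sample CPM matrices plus a sample sheet."""
    rows = []
    total_cols, poly_cols = {}, {}
    for i, cond in enumerate(conditions):
        t_id, p_id = f"{cond}_t", f"{cond}_p"
        total_cols[t_id] = total_values[:, i]
        poly_cols[p_id] = poly_values[:, i]
        rows += [
            [t_id, cond, "total", 1, 1],
            [p_id, cond, "polysome", 1, 1],
        ]
    ss = pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "fraction", "biological_replicate",
                 "technical_replicate"],
    )
    make = lambda cols: NormalizedMatrix(
        pd.DataFrame(cols, index=genes), scale="tpm"
    )
    return make(total_cols), make(poly_cols), ss


class TestTranslationalRatio:
    def test_fourfold_gives_tr_two(self):
        t, p, ss = _paired_nm(
            np.array([[100.0]]), np.array([[400.0]]), ["g"], ["Control"]
        )
        tr = translational_ratio(t, p, ss, pseudocount=0.0)
        assert tr.values.iloc[0, 0] == pytest.approx(2.0)

    def test_equal_fractions_give_zero(self):
        values = np.array([[50.0, 10.0], [7.0, 3.0]])
        t, p, ss = _paired_nm(values, values.copy(), ["a", "b"], ["Control", "Stress"])
        tr = translational_ratio(t, p, ss)
        np.testing.assert_allclose(tr.values.to_numpy(), 0.0, atol=1e-12)

    def test_pseudocount_stabilises_zero_total(self):
        t, p, ss = _paired_nm(
            np.array([[0.0]]), np.array([[7.0]]), ["g"], ["Control"]
        )
        tr = translational_ratio(t, p, ss, pseudocount=0.5)
        assert tr.values.iloc[0, 0] == pytest.approx(np.log2(7.5 / 0.5), abs=1e-4)

    def test_fraction_swap_negates_tr(self):
        rng = np.random.default_rng(6)
        tv, pv = rng.uniform(1, 100, (10, 2)), rng.uniform(1, 100, (10, 2))
        genes = [f"g{i}" for i in range(10)]
        t, p, ss = _paired_nm(tv, pv, genes, ["Control", "Stress"])
        fwd = translational_ratio(t, p, ss)
        # swapping fractions: relabel the sheet
        ss_sw = ss.copy()
        ss_sw["fraction"] = ss_sw["fraction"].map(
            {"total": "polysome", "polysome": "total"}
        )
        rev = translational_ratio(p, t, ss_sw)
        np.testing.assert_allclose(
            fwd.values.to_numpy(), -rev.values.to_numpy(), atol=1e-12
        )

    def test_unpairable_units_rejected(self):
        t, p, ss = _paired_nm(
            np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]), ["g"],
            ["Control", "Stress"],
        )
        ss = ss[~((ss["condition"] == "Stress") & (ss["fraction"] == "polysome"))]
        with pytest.raises(ValueError, match="unpairable|no 'polysome'|Stress"):
            translational_ratio(t, p, ss)

    def test_large_counts_tr_equals_raw_ratio_plus_library_constant(self):
        # with negligible pseudocount, CPM-based TR = raw-count TR +
        # log2(total libsize / poly libsize)
        raw_total = np.array([[4000.0], [8000.0], [2000.0]])
        raw_poly = np.array([[16000.0], [4000.0], [1000.0]])
        lib_t, lib_p = raw_total.sum(), raw_poly.sum()
        t, p, ss = _paired_nm(
            raw_total / lib_t * 1e6, raw_poly / lib_p * 1e6,
            ["a", "b", "c"], ["Control"],
        )
        tr = translational_ratio(t, p, ss, pseudocount=0.0)
        expected = np.log2(raw_poly / raw_total) + np.log2(lib_t / lib_p)
        np.testing.assert_allclose(
            tr.values.to_numpy(), expected, atol=1e-10
        )


class TestDeltaTR:
    def test_difference_and_identity(self):
        tr = TRMatrix(pd.DataFrame({"i": [2.0], "j": [-1.0]}, index=["g"]))
        assert delta_tr(tr, "i", "j")["deltaTR"].iloc[0] == 3.0
        assert delta_tr(tr, "i", "i")["deltaTR"].iloc[0] == 0.0

    def test_antisymmetry_on_random_matrix(self):
        rng = np.random.default_rng(9)
        tr = TRMatrix(
            pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=["u", "v", "w"])
        )
        fwd = delta_tr(tr, "u", "v")["deltaTR"]
        rev = delta_tr(tr, "v", "u")["deltaTR"]
        np.testing.assert_allclose(fwd + rev, 0.0, atol=1e-12)


def _collapsed(cfg):
    total, poly, ss, truth = simulate_experiment(cfg)
    tc, tss = collapse_technical_replicates(total, ss)
    pc, pss = collapse_technical_replicates(poly, ss)
    return tc, pc, pd.concat([tss, pss], ignore_index=True), truth


class TestInteractionTest:
    def test_translation_only_regulation_recovered(self):
        cfg = SimulationConfig(
            seed=21, **{**NO_STRUCTURE, "n_translation_up": 200}
        )
        tc, pc, sheet, truth = _collapsed(cfg)
        res = interaction_test(tc, pc, sheet, "Control", "Stress")
        up = truth.index[truth["program"] == "translation_up"]
        assert res.loc[up, "class"].eq("Up").mean() >= 0.8

    def test_null_interaction_calibrated_under_model(self):
        # independent NB columns, the model's own sampling assumptions
        rng = np.random.default_rng(22)
        phi, G = 0.1, 2000
        base = np.exp(rng.normal(4.5, 1.0, G))
        y = rng.poisson(rng.gamma(1 / phi, base[:, None] * phi, (G, 12)))
        genes = [f"g{i}" for i in range(G)]
        rows, tcols, pcols = [], {}, {}
        k = 0
        for cond in ("Control", "Stress"):
            for rep in (1, 2, 3):
                for frac, store in (("total", tcols), ("polysome", pcols)):
                    sid = f"{cond}_{frac}_b{rep}"
                    store[sid] = y[:, k]
                    rows.append([sid, cond, frac, rep, 1])
                    k += 1
        from translatome.io import CountMatrix

        tc = CountMatrix(pd.DataFrame(tcols, index=genes, dtype=np.int64), "total")
        pc = CountMatrix(pd.DataFrame(pcols, index=genes, dtype=np.int64), "polysome")
        sheet = pd.DataFrame(
            rows, columns=["sample_id", "condition", "fraction",
                           "biological_replicate", "technical_replicate"],
        )
        res = interaction_test(tc, pc, sheet, "Control", "Stress")
        assert 0.03 <= (res["PValue"] < 0.05).mean() <= 0.07

    def test_transcription_only_genes_show_no_delta_tr(self):
        cfg = SimulationConfig(
            seed=23, **{**NO_STRUCTURE, "n_transcription_up": 200}
        )
        tc, pc, sheet, truth = _collapsed(cfg)
        res = interaction_test(tc, pc, sheet, "Control", "Hardening")
        genes = truth.index[truth["program"] == "transcription_up"]
        assert res.loc[genes, "deltaTR"].abs().median() <= 0.2

    def test_model_estimate_agrees_with_plugin_delta_tr(self):
        cfg = SimulationConfig(seed=31, **{**NO_STRUCTURE, "n_translation_up": 100})
        tc, pc, sheet, truth = _collapsed(cfg)
        res = interaction_test(tc, pc, sheet, "Control", "Stress")
        tr = translational_ratio(cpm_normalize(tc), cpm_normalize(pc), sheet)
        plug = delta_tr(tr, "Stress", "Control")["deltaTR"]
        mean_cpm = cpm_normalize(tc).values.mean(axis=1)
        big = mean_cpm[mean_cpm >= 50].index
        diff = (res.loc[big, "deltaTR"] - plug.loc[big]).abs()
        assert diff.median() <= 0.2

    def test_missing_fraction_rejected(self):
        cfg = SimulationConfig(seed=1, **NO_STRUCTURE, n_genes=50)
        tc, pc, sheet, _ = _collapsed(cfg)
        broken = sheet[~((sheet["condition"] == "Stress")
                         & (sheet["fraction"] == "polysome"))]
        with pytest.raises(ValueError, match="polysome"):
            interaction_test(tc, pc, broken, "Control", "Stress")


class TestTrNormalizeMillion:
    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(4)
        tr = TRMatrix(pd.DataFrame(rng.normal(0, 2, (40, 4))))
        nm = tr_normalize_million(tr)
        np.testing.assert_allclose(nm.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_constant_column_splits_evenly(self):
        tr = TRMatrix(pd.DataFrame({"u": [1.5] * 4}))
        nm = tr_normalize_million(tr)
        np.testing.assert_allclose(nm.values["u"], 250000.0)

    def test_rank_order_preserved_within_column(self):
        rng = np.random.default_rng(4)
        tr = TRMatrix(pd.DataFrame(rng.normal(0, 2, (40, 4))))
        nm = tr_normalize_million(tr)
        for col in tr.values.columns:
            a = tr.values[col].rank()
            b = nm.values[col].rank()
            pd.testing.assert_series_equal(a, b)

    def test_efficiency_mode_rejected(self):
        tr = TRMatrix(pd.DataFrame({"u": [1.0]}), mode="efficiency")
        with pytest.raises(ValueError, match="ratio"):
            tr_normalize_million(tr)
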