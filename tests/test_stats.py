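"""Mixed-model inference and the Mann-Whitney error-rate comparison."""

import numpy as np
import pandas as pd
import pytest

from saccadometry.stats import MixedModelSpec, fit_metric_model, mann_whitney_error_rate


def _balanced_data(group_eff=0.0, task_eff=0.1, part_sd=0.0, noise=0.2, seed=0,
                   n_per_group=8, trials=6):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("control", "PD"):
        for i in range(n_per_group):
            pid = f"{g}{i}"
            off = rng.normal(0, part_sd)
            for rt, shift in (("PS_correct", 0.0), ("AS_correct", task_eff)):
                for _ in range(trials):
                    val = 1.0 + (group_eff if g == "PD" else 0.0) + shift + off
                    rows.append((pid, g, rt, val + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["participant_id", "group",
                                       "response_type", "value"])


class TestMixedModel:
    def test_emms_match_cell_means_on_balanced_data(self):
        # with no participant variance the EMMs are the cell means
        df = _balanced_data(group_eff=0.3, task_eff=0.15, part_sd=0.0, seed=2)
        res = fit_metric_model(df, MixedModelSpec("value"))
        cells = df.groupby(["group", "response_type"])["value"].mean()
        for row in res.emms.itertuples(index=False):
            assert row.emm == pytest.approx(cells[(row.group, row.response_type)],
                                            abs=1e-3)

    def test_contrast_estimates_equal_emm_differences(self):
        df = _balanced_data(group_eff=0.25, seed=3)
        res = fit_metric_model(df, MixedModelSpec("value"))
        emm = res.emms.set_index(["group", "response_type"])["emm"]
        row = res.contrasts.set_index("contrast").loc["PS_correct: PD - control"]
        assert row["estimate"] == pytest.approx(
            emm[("PD", "PS_correct")] - emm[("control", "PS_correct")], abs=1e-6
        )
        assert (res.contrasts["p_bonf"] >= res.contrasts["pvalue"] - 1e-12).all()

    def test_participant_constant_response_kills_task_contrasts(self):
        rng = np.random.default_rng(4)
        rows = []
        for g in ("control", "PD"):
            for i in range(6):
                val = rng.normal()
                for rt in ("PS_correct", "AS_correct"):
                    for _ in range(5):
                        rows.append((f"{g}{i}", g, rt, val))
        df = pd.DataFrame(rows, columns=["participant_id", "group",
                                         "response_type", "value"])
        res = fit_metric_model(df, MixedModelSpec("value"))
        within = res.contrasts[res.contrasts["contrast"].str.contains("AS_correct - ")]
        assert np.allclose(within["estimate"], 0.0, atol=1e-6)

    def test_detects_task_effect_with_real_structure(self):
        df = _balanced_data(task_eff=0.15, part_sd=0.2, noise=0.25, seed=5,
                            n_per_group=12, trials=10)
        res = fit_metric_model(df, MixedModelSpec("value"))
        assert res.fixed_effects["response_type"]["pvalue"] < 0.01
        assert res.diagnostics["random_intercept_var"] > 0.01

    def test_sqrt_transform_back_transforms_monotonically(self):
        df = _balanced_data(task_eff=2.0, seed=6)
        df["value"] = (df["value"] + 10.0) ** 2  # positive, right-scaled
        res = fit_metric_model(df, MixedModelSpec("value", transform="sqrt"))
        assert (res.emms["ci_low"] <= res.emms["emm"]).all()
        assert (res.emms["emm"] <= res.emms["ci_high"]).all()
        # EMM ordering on the response scale follows the model scale
        order_model = res.emms.sort_values("emm")["response_type"].tolist()
        assert order_model[-1] == "AS_correct"

    def test_unsupported_family_rejected(self):
        with pytest.raises(NotImplementedError):
            MixedModelSpec("value", family="gamma-identity")


class TestMannWhitney:
    def test_symmetric_null_gives_half_of_pairs(self):
        pd_rates = np.linspace(0.0, 1.0, 25)
        hc_rates = np.concatenate([np.linspace(0.0, 1.0, 25), [0.5]])
        U, p = mann_whitney_error_rate(pd_rates, hc_rates)
        # near-identical groups of 25 and 26: U close to n1*n2/2 = 325
        assert U == pytest.approx(325, abs=13)

    def test_complete_separation(self):
        U, p = mann_whitney_error_rate([0.1, 0.2], [0.3, 0.4])
        assert U == 0.0  # U counts pairs won by the PD sample

    def test_u_statistics_sum_to_n1n2(self):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(size=25), rng.uniform(size=26)
        U_ab, _ = mann_whitney_error_rate(a, b)
        U_ba, _ = mann_whitney_error_rate(b, a)
        assert U_ab + U_ba == pytest.approx(25 * 26)

    def test_null_calibration_by_permutation(self, rng):
        pooled = rng.uniform(size=51)
        rejections = 0
        pvals = []
        for _ in range(400):
            perm = rng.permutation(pooled)
            _, p = mann_whitney_error_rate(perm[:25], perm[25:])
            pvals.append(p)
            rejections += p < 0.05
        assert 0.02 <= rejections / 400 <= 0.09
        assert 0.35 < np.median(pvals) < 0.65

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_error_rate([], [0.1])
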