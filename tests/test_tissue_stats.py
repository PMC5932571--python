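import numpy as np
import pytest

from zebratk import (
    NoiseModel,
    TissuePanel,
    gen_tissue_panel,
    pigmentation_report,
    tissue_anova,
)

WT_TISSUE_MEANS = {"eyes": 1694.0, "brain": 263.0, "trunk": 143.0}


@pytest.fixture()
def wt_panel():
    return gen_tissue_panel(
        WT_TISSUE_MEANS, {"WT": 1.0}, n_pools=3, noise=NoiseModel(cv=0.05, seed=5)
    )


@pytest.fixture()
def pigment_panel():
    # hypo-pigmented lines reduced 10x (brain), 20x (trunk), 50x (eyes)
    return TissuePanel(
        groups={
            **{
                (t, "WT"): gen_tissue_panel(
                    {t: m}, {"WT": 1.0}, 3, NoiseModel(cv=0.05, seed=i)
                ).groups[(t, "WT")]
                for i, (t, m) in enumerate(WT_TISSUE_MEANS.items())
            },
            **{
                (t, "albino"): gen_tissue_panel(
                    {t: m}, {"albino": f}, 3, NoiseModel(cv=0.05, seed=10 + i)
                ).groups[(t, "albino")]
                for i, (t, m, f) in enumerate(
                    [("brain", 263.0, 10.0), ("trunk", 143.0, 20.0), ("eyes", 1694.0, 50.0)]
                )
            },
        }
    )


class TestPanel:
    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            TissuePanel(groups={("whole", "WT"): np.array([1.0, -2.0])})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            TissuePanel(groups={("whole", "WT"): np.array([])})


class TestAnova:
    def test_separated_tissues_highly_significant(self, wt_panel):
        """Eye levels ~6-12x above brain/trunk with 5% within-group CV give
        Tukey-adjusted p < 0.0001 for both eye contrasts at n=3 pools."""
        res = tissue_anova(wt_panel)
        pw = res.pairwise.set_index(["group1", "group2"])
        assert res.p_value < 1e-6
        assert pw.loc[("brain/WT", "eyes/WT"), "p_adj"] < 1e-4
        assert pw.loc[("eyes/WT", "trunk/WT"), "p_adj"] < 1e-4

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(100.0, 5.0, size=4)
        panel = TissuePanel(
            groups={("whole", "WT"): vals, ("whole", "albino"): vals.copy()}
        )
        res = tissue_anova(panel)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert all(res.pairwise["p_adj"] > 0.99)

    def test_single_group_rejected(self, wt_panel):
        with pytest.raises(ValueError):
            tissue_anova(wt_panel, keys=[("eyes", "WT")])

    def test_single_replicate_rejected(self):
        panel = TissuePanel(
            groups={("whole", "WT"): [1.0], ("whole", "albino"): [2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            tissue_anova(panel)

    def test_tukey_adjustment_never_below_unadjusted(self, wt_panel, pigment_panel):
        for panel in (wt_panel, pigment_panel):
            res = tissue_anova(panel)
            assert np.all(
                res.pairwise["p_adj"].to_numpy()
                >= res.pairwise["p_unadj"].to_numpy() - 1e-12
            )


class TestPigmentationReport:
    def test_recovers_generated_fold_reductions(self, pigment_panel):
        report = pigmentation_report(pigment_panel, reference="WT")
        albino = report[report["pigmentation"] == "albino"].set_index("tissue")
        assert albino.loc["brain", "fold_vs_reference"] == pytest.approx(10.0, rel=0.2)
        assert albino.loc["trunk", "fold_vs_reference"] == pytest.approx(20.0, rel=0.2)
        assert albino.loc["eyes", "fold_vs_reference"] == pytest.approx(50.0, rel=0.2)
        assert all(albino["p_adj"] < 0.001)

    def test_identical_groups_give_unit_folds(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(100.0, 5.0, size=3)
        panel = TissuePanel(
            groups={("whole", "WT"): vals, ("whole", "PTU"): vals.copy()}
        )
        report = pigmentation_report(panel)
        assert report["fold_vs_reference"].to_numpy() == pytest.approx(1.0, rel=1e-9)
        assert report.loc[report["pigmentation"] == "PTU", "p_adj"].iloc[0] > 0.99

    def test_report_carries_per_group_n(self, pigment_panel):
        report = pigmentation_report(pigment_panel)
        assert set(report["n"]) == {3}

    def test_fold_table_scale_invariant(self, pigment_panel):
        report = pigmentation_report(pigment_panel)
        scaled = TissuePanel(
            groups={k: 3.7 * v for k, v in pigment_panel.groups.items()}
        )
        report2 = pigmentation_report(scaled)
        np.testing.assert_allclose(
            report["fold_vs_reference"].to_numpy(),
            report2["fold_vs_reference"].to_numpy(),
            rtol=1e-12,
        )

    def test_missing_reference_rejected(self, wt_panel):
        with pytest.raises(ValueError):
            pigmentation_report(wt_panel, reference="albino")
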