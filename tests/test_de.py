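"""Two-step regression screen: design, fits, stepwise selection, recovery."""

import numpy as np
import pytest
from scipy import stats as sps

from toxrank.de import (
    DEParams,
    backward_stepwise,
    build_design,
    de_analysis,
    fit_global,
    fit_global_matrix,
)
from toxrank.io import SampleMeta
from toxrank.simulate import SimulationConfig, simulate_panel


def _samples(timepoints, doses, replicates=2, compound="cpdA"):
    out = []
    for dose in doses:
        for t in timepoints:
            for r in range(1, replicates + 1):
                out.append(
                    SampleMeta(f"{dose}_{t}_{r}", compound, dose, float(t), r)
                )
    return out


FOUR_T = (3.0, 9.0, 12.0, 24.0)
ALL_DOSES = ("control", "low", "middle", "high")


class TestBuildDesign:
    def test_full_design_has_16_columns(self):
        design = build_design(_samples(FOUR_T, ALL_DOSES), max_degree=3)
        assert design.n_coef == 16  # 4 + 3 doses x (1 dummy + 3 interactions)
        assert len(design.group_cols) == 12

    def test_degree_capped_by_timepoints(self):
        design = build_design(_samples((2.0, 24.0), ALL_DOSES), max_degree=3)
        assert design.degree == 1
        assert design.n_coef == 2 + 3 * 2

    def test_missing_dose_group_tolerated(self):
        design = build_design(
            _samples(FOUR_T, ("control", "middle", "high")), max_degree=3
        )
        assert design.n_coef == 4 + 2 * 4
        assert not any(name.startswith("low") for name in design.columns)

    def test_no_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            build_design(_samples(FOUR_T, ("low", "high")), max_degree=3)


class TestFitGlobal:
    def test_constant_response(self):
        design = build_design(_samples(FOUR_T, ALL_DOSES), 3)
        p, fit = fit_global(np.full(design.X.shape[0], 3.14), design)
        assert p == 1.0 and fit["r2"] == 0.0

    def test_exact_design_column(self):
        design = build_design(_samples(FOUR_T, ALL_DOSES), 3)
        y = design.X[:, 5].astype(float)
        p, fit = fit_global(y, design)
        assert p < 1e-12
        assert fit["r2"] == pytest.approx(1.0)

    def test_null_pvalues_uniform(self, rng):
        # 24 samples (control+high, 4 times, 3 reps), 500 pure-noise genes
        samples = _samples(FOUR_T, ("control", "high"), replicates=3)
        design = build_design(samples, 3)
        Y = rng.normal(size=(500, len(samples)))
        p, _ = fit_global_matrix(Y, design)
        assert sps.kstest(p, "uniform").pvalue > 0.01


class TestBackwardStepwise:
    def test_recovers_strong_interaction(self, rng):
        design = build_design(_samples(FOUR_T, ALL_DOSES, replicates=3), 3)
        names = design.columns
        j = names.index("high:time^1")
        sigma = 0.5
        y = 2.0 + 10 * sigma * design.X[:, j] + rng.normal(0, sigma, design.X.shape[0])
        fit = backward_stepwise(y, design, alpha=0.05 / design.n_coef)
        assert 0 in fit.active  # intercept kept
        kept = [names[i] for i in fit.active if i != 0]
        assert "high:time^1" in kept

    def test_null_mostly_intercept_only(self, rng):
        design = build_design(_samples(FOUR_T, ALL_DOSES, replicates=3), 3)
        alpha = 0.05 / design.n_coef
        n_intercept_only = 0
        n_sim = 500
        for _ in range(n_sim):
            y = rng.normal(size=design.X.shape[0])
            fit = backward_stepwise(y, design, alpha)
            n_intercept_only += fit.active == [0]
        assert n_intercept_only / n_sim >= 0.93

    def test_fully_significant_model_unchanged(self, rng):
        # strong signal on every column: nothing should be dropped
        design = build_design(_samples(FOUR_T, ALL_DOSES, replicates=3), 3)
        beta = np.arange(1, design.n_coef + 1) * 5.0
        y = design.X @ beta + rng.normal(0, 0.01, design.X.shape[0])
        fit = backward_stepwise(y, design, alpha=0.05 / design.n_coef)
        assert fit.active == list(range(design.n_coef))
        assert fit.r2 > 0.999


class TestDeAnalysis:
    def test_recovers_responsive_planted_genes(self):
        cfg = SimulationConfig(seed=1)
        panels, truth = simulate_panel(cfg)
        compound = truth.toxic_compounds[0]
        results = de_analysis(panels[compound], compound)
        selected = {r.gene for r in results if r.selected}
        responsive = truth.responsive[compound]
        assert len(selected & responsive) / len(responsive) >= 0.8

    def test_signal_free_compound_controls_fdr(self):
        cfg = SimulationConfig(seed=2, off_target_range=(0, 0))
        panels, truth = simulate_panel(cfg)
        compound = [c for c in panels if c not in truth.toxic_compounds][0]
        results = de_analysis(panels[compound], compound)
        frac = np.mean([r.selected for r in results])
        assert frac <= 2 * DEParams().global_fdr

    def test_shared_time_drift_attributed_to_time_not_treatment(self, rng):
        # identical strong time trend in every dose group: the global step
        # fires (the gene does change over time) but treatment-related
        # coefficients survive only at the stepwise false-positive rate,
        # so drift-only genes are not systematically selected
        from toxrank.io import ExpressionPanel

        samples = _samples(FOUR_T, ALL_DOSES, replicates=3)
        drift = np.array([2.0 * s.time / 24.0 for s in samples])
        n_genes = 60
        values = np.vstack(
            [drift + rng.normal(0, 0.05, len(samples)) for _ in range(n_genes)]
        )
        panel = ExpressionPanel([f"g{i}" for i in range(n_genes)], samples, values)
        results = de_analysis(panel, "cpdA")
        assert all(r.passed_global for r in results)
        assert np.mean([r.has_significant_coef for r in results]) <= 0.15
        assert np.mean([r.selected for r in results]) <= 0.15

    def test_selected_model_r2_bounded_by_full(self, small_sim):
        panels, truth = small_sim
        compound = truth.toxic_compounds[1]
        panel = panels[compound]
        results = de_analysis(panel, compound)
        design = build_design(panel.samples, 3)
        _, r2_full = fit_global_matrix(panel.values, design)
        by_gene = dict(zip(panel.gene_ids, r2_full))
        for r in results:
            if r.passed_global:
                assert r.r2 <= by_gene[r.gene] + 1e-9

    def test_deterministic(self, small_sim):
        panels, truth = small_sim
        compound = truth.toxic_compounds[0]
        a = de_analysis(panels[compound], compound)
        b = de_analysis(panels[compound], compound)
        assert a == b

    def test_few_replicates_warns(self, rng):
        from toxrank.io import ExpressionPanel

        samples = _samples(FOUR_T, ALL_DOSES, replicates=1)
        values = rng.normal(size=(5, len(samples)))
        panel = ExpressionPanel([f"g{i}" for i in range(5)], samples, values)
        with pytest.warns(UserWarning, match="replicates"):
            de_analysis(panel, "cpdA")
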