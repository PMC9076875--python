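"""Synthetic successional-community generator: contracts and ground truth."""

import numpy as np
import pandas as pd
import pytest

from multidiv import (
    GroundTruth,
    SimulationConfig,
    generate_dataset,
    simulate_broken_stick,
    simulate_path_data,
    write_dataset,
)
from multidiv.diversity import shannon_per_plot
from multidiv.io import read_dataset
from multidiv.simulate import ConfigError, _calibrate_composition


class TestConfigValidation:
    def test_breakpoint_outside_range(self):
        with pytest.raises(ConfigError):
            SimulationConfig(age_range=(5, 170), true_breakpoint=200)

    def test_too_few_plots(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_plots=5)

    def test_latent_cov_bounds(self):
        with pytest.raises(ConfigError):
            SimulationConfig(latent_cov_late=1.0)

    def test_unknown_group(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_taxa_per_group={"slime_molds": 10})


class TestDeterminismAndSchema:
    def test_same_seed_identical(self):
        a_tables, a_plots, a_truth = generate_dataset(SimulationConfig(seed=1))
        b_tables, b_plots, b_truth = generate_dataset(SimulationConfig(seed=1))
        for a, b in zip(a_tables, b_tables):
            assert a.data.equals(b.data)
        assert a_plots.data.equals(b_plots.data)
        assert a_truth.to_json() == b_truth.to_json()

    def test_different_seed_differs(self):
        a, _, _ = generate_dataset(SimulationConfig(seed=1))
        b, _, _ = generate_dataset(SimulationConfig(seed=2))
        assert not a[0].data.equals(b[0].data)

    def test_semantics_and_value_contracts(self, default_dataset):
        _, (tables, plots, _) = default_dataset
        for t in tables:
            assert (t.abundance >= 0).all()
            if t.semantics == "count":
                assert np.allclose(t.abundance, np.round(t.abundance))
            if t.semantics == "cover":
                assert (t.abundance.sum(axis=1) <= 100 + 1e-9).all()
        assert plots.n_plots == 110
        # transect spacing respects the field design's 5 m minimum
        spacing = np.diff(plots.coords[:, 0])
        assert (spacing >= 5.0 - 1e-9).all()
        assert np.all(np.diff(plots.ages) >= 0)


class TestDiversityTargets:
    def test_zero_noise_shannon_is_exact_piecewise_function_of_age(self):
        cfg = SimulationConfig(
            seed=3, noise_sd=0.0, latent_cov_late=0.0, temp_effect_late=0.0
        )
        tables, plots, truth = generate_dataset(cfg)
        lo = cfg.age_range[0]
        for t in tables:
            h = shannon_per_plot(t).to_numpy()
            k = t.n_taxa
            base = 0.45 * np.log(k)
            expect = base + cfg.early_slope * (
                np.minimum(plots.ages, cfg.true_breakpoint) - lo
            )
            expect = np.clip(expect, 0.05, np.log(k) - 0.05)
            assert np.allclose(h, expect, atol=1e-7), t.group

    @staticmethod
    def _unimodality_violation(table):
        """Largest rise after / fall before the peak, relative to the peak."""
        rel = table.abundance / table.abundance.sum(axis=1, keepdims=True)
        worst = 0.0
        for j in range(table.n_taxa):
            col = rel[:, j]
            peak = np.argmax(col)
            v = max(
                max(0.0, -np.diff(col[: peak + 1]).min(initial=0.0)),
                max(0.0, np.diff(col[peak:]).max(initial=0.0)),
            )
            worst = max(worst, v / col.max())
        return worst

    @pytest.mark.parametrize("early_slope", [0.0, 0.02])
    def test_niche_curves_near_unimodal(self, early_slope):
        # every taxon's noiseless expected relative abundance has a single
        # maximum along the gradient, up to the small coupling the per-plot
        # evenness calibration introduces (< 2% of the peak height)
        cfg = SimulationConfig(
            seed=4, noise_sd=0.0, early_slope=early_slope, temp_effect_late=0.0
        )
        tables, _, _ = generate_dataset(cfg)
        for t in tables:
            assert self._unimodality_violation(t) < 0.02, t.group

    def test_early_slope_recovered_at_large_n(self):
        cfg = SimulationConfig(n_plots=1000, seed=5, abundance_model="cover")
        tables, plots, _ = generate_dataset(cfg)
        early = plots.ages <= cfg.true_breakpoint
        for t in tables:
            h = shannon_per_plot(t).to_numpy()
            slope = np.polyfit(plots.ages[early], h[early], 1)[0]
            assert abs(slope - cfg.early_slope) < 0.1 * cfg.early_slope, t.group

    def test_latent_residual_correlation_recovered(self):
        # spec oracle: sample correlation of the generator's own residuals
        cfg = SimulationConfig(n_plots=2000, latent_cov_late=0.4, seed=6)
        tables, plots, truth = generate_dataset(cfg)
        late = plots.ages > cfg.true_breakpoint
        groups = list(truth.target_diversity)
        resid = []
        z = (plots.temperature - plots.temperature.mean()) / plots.temperature.std()
        for g in groups:
            h = np.asarray(truth.target_diversity[g])[late]
            X = np.column_stack([np.ones(late.sum()), z[late]])
            coef, *_ = np.linalg.lstsq(X, h, rcond=None)
            resid.append(h - X @ coef)
        C = np.corrcoef(np.vstack(resid))
        iu = np.triu_indices(len(groups), 1)
        assert np.all(np.abs(C[iu] - 0.4) < 0.05)

    def test_calibration_hits_target_entropy(self, rng):
        for _ in range(20):
            v = rng.uniform(0.01, 1.0, 40)
            target = rng.uniform(0.2, np.log(40) - 0.2)
            p = _calibrate_composition(v, target)
            h = -(p[p > 0] * np.log(p[p > 0])).sum()
            assert abs(h - target) < 1e-6


class TestWriteRead:
    def test_round_trip(self, tmp_path, default_dataset):
        cfg, (tables, plots, truth) = default_dataset
        write_dataset((tables, plots, truth), tmp_path)
        t2, p2, tr2 = read_dataset(tmp_path)
        for a, b in zip(tables, t2):
            assert a.group == b.group
            assert a.semantics == b.semantics
            assert np.allclose(a.abundance, b.abundance)
            assert list(a.taxon_ids) == list(b.taxon_ids)
        assert np.allclose(plots.ages, p2.ages)
        assert tr2.to_json() == truth.to_json()

    def test_empty_taxon_columns_preserved(self, tmp_path):
        from multidiv import CommunityTable, PlotFrame

        df = pd.DataFrame(
            {"t1": [1.0, 2.0], "t_empty": [0.0, 0.0]}, index=["plot_001", "plot_002"]
        )
        table = CommunityTable(df, "vascular_plants", "cover")
        meta = pd.DataFrame(
            {
                "gradient_index": [1, 2],
                "age_years": [10.0, 20.0],
                "temperature": [5.0, 6.0],
                "x_m": [0.0, 19.0],
                "y_m": [0.0, 0.0],
            },
            index=pd.Index(["plot_001", "plot_002"], name="plot_id"),
        )
        truth = GroundTruth(60.0, {}, {}, {}, {})
        write_dataset(([table], PlotFrame(meta), truth), tmp_path)
        t2, _, _ = read_dataset(tmp_path)
        assert list(t2[0].taxon_ids) == ["t1", "t_empty"]

    def test_ground_truth_sidecar_reparses(self, tmp_path, default_dataset):
        _, (tables, plots, truth) = default_dataset
        files = write_dataset((tables, plots, truth), tmp_path)
        from multidiv.simulate import read_ground_truth

        tr2 = read_ground_truth(files["ground_truth"])
        assert tr2.true_breakpoint == truth.true_breakpoint
        assert tr2.taxon_optima == truth.taxon_optima


class TestTargetedSimulators:
    def test_broken_stick_mean_structure(self):
        x, y = simulate_broken_stick(n=200, noise_sd=0.0, seed=0)
        early = x <= 60
        assert np.allclose(y[early], 0.15 + 0.01 * x[early])
        assert np.allclose(y[~early], 0.15 + 0.01 * 60)

    def test_path_data_moments(self):
        data, truth = simulate_path_data(n=20000, seed=1)
        sds = data.std(ddof=1)
        assert np.all(np.abs(sds - 1) < 0.05)
        # indirect truth equals sum of products by construction
        for exo, val in truth["indirect"].items():
            acc = sum(truth["a"][exo][g] * truth["b"][g] for g in truth["b"])
            assert val == pytest.approx(acc)

    def test_path_data_invalid_coefficients(self):
        with pytest.raises(ConfigError):
            simulate_path_data(
                n=100,
                a={"time": {"g1": 0.9}, "temperature": {"g1": 0.9}},
                b={"g1": 0.2},
                exo_corr=0.9,
                seed=0,
            )
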