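import dataclasses

import numpy as np
import pandas as pd
import pytest

from cytocycle import (GeneratorConfig, PerturbationSpec, apply_perturbation,
                       inject_noncanonical, simulate_population)
from cytocycle.errors import ConfigurationError, ParameterError
from cytocycle.fcs import read_fcs
from cytocycle.matrix import PHASES
from cytocycle.synthetic import (DEFAULT_OCCUPANCY, export_dataset,
                                 _sigma)


def test_realized_phase_fractions_match_occupancy_within_3_sd():
    """Multinomial draws at the stimulated T-cell occupancy land within
    3 multinomial SDs of the configured fractions."""
    n = 20_000
    ds = simulate_population(GeneratorConfig(n_cells=n, seed=1))
    occ = np.asarray(DEFAULT_OCCUPANCY)
    for phase, p in zip(PHASES, occ):
        realized = (ds.truth_phase == phase).mean()
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(realized - p) <= 3 * sd, (phase, realized, p)


def test_zero_noise_cells_sit_exactly_on_phase_templates():
    """With noise_cv=0 every non-DNA marker equals its phase-template
    location; DNA stays within the 2N..4N interpolation band in S."""
    cfg = GeneratorConfig(n_cells=2000, seed=3, noise_cv=0.0)
    ds = simulate_population(cfg)
    dna_2n = cfg.template("DNA").location("G0G1")
    for j, tpl in enumerate(cfg.templates):
        col = ds.expression.values[:, j]
        for phase in PHASES:
            mask = ds.truth_phase == phase
            if tpl.marker_name == "DNA" and phase == "S":
                assert col[mask].min() >= dna_2n
                assert col[mask].max() <= 2 * dna_2n
            else:
                np.testing.assert_array_equal(col[mask],
                                              tpl.location(phase))


def test_seed_controls_values_but_not_distribution():
    cfg = GeneratorConfig(n_cells=20_000, seed=1)
    a = simulate_population(cfg)
    b = simulate_population(dataclasses.replace(cfg, seed=2))
    c = simulate_population(cfg)
    # identical seed: bit-identical; different seed: different draws
    np.testing.assert_array_equal(a.expression.values, c.expression.values)
    assert not np.array_equal(a.expression.values, b.expression.values)
    # phase fractions agree within sampling error (~4 joint SDs)
    for phase in PHASES:
        fa = (a.truth_phase == phase).mean()
        fb = (b.truth_phase == phase).mean()
        sd = np.sqrt(fa * (1 - fa) / 20_000)
        assert abs(fa - fb) <= 4 * np.sqrt(2) * sd


def test_invalid_configs_are_rejected():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(phase_occupancy=(0.5, 0.5, 0.1, 0.1))
    with pytest.raises(ConfigurationError):
        GeneratorConfig(cell_line_offsets={"L": {"NotAMarker": 2.0}})
    with pytest.raises(ConfigurationError):
        GeneratorConfig(cell_line_offsets={"L": {"Ki67": -1.0}})


class TestInjection:
    def test_zero_fraction_is_identity(self, default_dataset):
        out = inject_noncanonical(default_dataset, "ki67_low_in_s", "S", 0.0,
                                  seed=5)
        np.testing.assert_array_equal(out.expression.values,
                                      default_dataset.expression.values)
        assert out.truth_canonical.all()

    def test_flag_count_within_binomial_sd(self, default_dataset):
        frac = 0.2
        out = inject_noncanonical(default_dataset, "ki67_low_in_s", "S", frac,
                                  seed=5)
        n_s = int((default_dataset.truth_phase == "S").sum())
        flagged = int((~out.truth_canonical).sum())
        sd = np.sqrt(frac * (1 - frac) * n_s)
        assert abs(flagged - frac * n_s) <= 3 * sd
        # only S cells were touched
        assert (out.truth_phase[~out.truth_canonical] == "S").all()

    def test_full_fraction_forces_all_target_cells(self):
        ds = simulate_population(GeneratorConfig(n_cells=5000, seed=7,
                                                 noise_cv=0.0))
        out = inject_noncanonical(ds, "cdt1_after_s", "G2", 1.0, seed=8)
        g2 = out.truth_phase == "G2"
        assert (~out.truth_canonical[g2]).all()
        # forced exactly to the violating location at zero noise
        cdt1 = out.expression.channel("CDT1")
        np.testing.assert_array_equal(cdt1[g2], 150.0)

    def test_errors(self, default_dataset):
        with pytest.raises(ParameterError):
            inject_noncanonical(default_dataset, "ki67_low_in_s", "S", 1.5, 0)
        with pytest.raises(ConfigurationError):
            inject_noncanonical(default_dataset, "nope", "S", 0.1, 0)


class TestPerturbation:
    def test_identity_spec_reproduces_baseline(self):
        cfg = GeneratorConfig(n_cells=4000, seed=9)
        baseline = simulate_population(cfg)
        spec = PerturbationSpec(occupancy_shift=cfg.phase_occupancy,
                                label=cfg.treatment)
        same = apply_perturbation(cfg, spec)
        np.testing.assert_array_equal(baseline.expression.values,
                                      same.expression.values)

    def test_occupancy_pileup_realized(self):
        cfg = GeneratorConfig(n_cells=20_000, seed=10)
        spec = PerturbationSpec(occupancy_shift=(0.90, 0.05, 0.04, 0.01))
        ds = apply_perturbation(cfg, spec)
        frac = (ds.truth_phase == "G0G1").mean()
        assert abs(frac - 0.90) <= 3 * np.sqrt(0.9 * 0.1 / 20_000)

    def test_slippage_cells_exceed_4n_gate_at_predicted_rate(self):
        cfg = GeneratorConfig(n_cells=40_000, seed=11)
        slip_frac = 0.1
        spec = PerturbationSpec(
            occupancy_shift=cfg.phase_occupancy,
            slippage_fraction=slip_frac,
        )
        ds = apply_perturbation(cfg, spec)
        g0 = ds.truth_phase == "G0G1"
        gate = 2.0 * cfg.template("DNA").location("G0G1") * 1.1  # 4N * 1.1
        exceed = (ds.expression.channel("DNA")[g0] > gate).mean()
        # analytic expectation under the lognormal noise model
        from scipy.stats import norm
        s = _sigma(cfg.noise_cv)
        dna_2n = cfg.template("DNA").location("G0G1")
        p_normal = norm.sf((np.log(gate / dna_2n) + s**2 / 2) / s)
        p_slip = norm.sf(
            (np.log(gate / (dna_2n * spec.slippage_dna_factor)) + s**2 / 2) / s
        )
        expected = (1 - slip_frac) * p_normal + slip_frac * p_slip
        sd = np.sqrt(expected * (1 - expected) / g0.sum())
        assert abs(exceed - expected) <= 3 * sd
        # slippage cells keep their G0G1 label but lose canonical status
        assert (ds.truth_phase[~ds.truth_canonical] == "G0G1").all()

    def test_invalid_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            PerturbationSpec(occupancy_shift=(0.25, 0.25, 0.25, 0.25),
                             marker_effects=[("Ki67", frozenset({"S"}), 0.0)])


class TestExport:
    def test_delimited_round_trip_is_exact(self, tmp_path):
        ds = simulate_population(GeneratorConfig(n_cells=200, seed=12))
        export_dataset(ds, tmp_path, "delimited")
        from cytocycle.io import read_delimited_matrix
        back = read_delimited_matrix(tmp_path / "expression.csv")
        assert back.channel_names == ds.expression.channel_names
        np.testing.assert_array_equal(back.values, ds.expression.values)
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert (truth["phase"].to_numpy() == ds.truth_phase).all()

    def test_fcs_round_trip_single_precision(self, tmp_path):
        ds = simulate_population(GeneratorConfig(n_cells=300, seed=13))
        export_dataset(ds, tmp_path, "fcs")
        data, names, _ = read_fcs(tmp_path / "S1.fcs")
        assert names == ds.expression.channel_names
        np.testing.assert_allclose(data, ds.expression.values, rtol=1e-6)

    def test_empty_dataset_and_bad_format_are_errors(self, tmp_path,
                                                     default_dataset):
        empty = default_dataset.copy()
        empty.expression = empty.expression.select_cells(
            np.zeros(empty.n_cells, dtype=bool)
        )
        empty.truth_phase = empty.truth_phase[:0]
        empty.truth_canonical = empty.truth_canonical[:0]
        empty.truth_line = empty.truth_line[:0]
        empty.truth_treatment = empty.truth_treatment[:0]
        with pytest.raises(ParameterError):
            export_dataset(empty, tmp_path / "sub", "delimited")
        assert not (tmp_path / "sub" / "expression.csv").exists()
        with pytest.raises(ParameterError):
            export_dataset(default_dataset, tmp_path, "parquet")
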