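"""Gating hierarchy: RD ranking, gate calibration, per-stage classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from golgiq import (
    FeatureTable,
    GateConfig,
    GolgiGates,
    ValidationError,
    classify_golgi,
    classify_mitotic,
    compute_feature_table,
    fit_golgi_gates,
    gate_apoptotic,
    gate_dna_content,
    gate_singlets_focused,
    rank_features,
    rd_value,
    run_gating,
    sample_population,
)
from golgiq.gating import _vw_midpoint

from conftest import class_preset, render_class_population


def _table(df_dict, index=None):
    df = pd.DataFrame(df_dict, index=index)
    df.index.name = "cell_id"
    df.index = df.index.astype(str)
    return FeatureTable(df, {k: {"unit": "au"} for k in df.columns})


class TestRdValue:
    def test_identical_populations_zero(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert rd_value(v, v) == 0.0

    def test_exact_moments_give_two(self):
        # a: mean 0, sd 1; b: mean 3, sd 0.5 -> RD = 3 / 1.5 = 2
        a = [-1 / math.sqrt(2), 1 / math.sqrt(2)]
        b = [3 - 0.25 * math.sqrt(2), 3 + 0.25 * math.sqrt(2)]
        assert rd_value(a, b) == pytest.approx(2.0, rel=1e-12)

    def test_degenerate_point_masses(self):
        assert rd_value([5.0, 5.0], [5.0, 5.0]) == 0.0
        assert rd_value([5.0, 5.0], [7.0, 7.0]) == math.inf

    def test_matches_sample_moment_formula_on_simulated_gaussians(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(3, 0.5, 10_000)
        expected = (b.mean() - a.mean()) / (a.std(ddof=1) + b.std(ddof=1))
        assert rd_value(a, b) == pytest.approx(expected, rel=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            rd_value([1.0], [2.0, 3.0])


class TestRankFeatures:
    def _labeled_table(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 100
        labels = pd.Series(["a"] * n + ["b"] * n, index=[str(i) for i in range(2 * n)])
        informative = np.concatenate([rng.normal(0, 1, n), rng.normal(4, 1, n)])
        noise = rng.normal(0, 1, 2 * n)
        table = _table(
            {"informative": informative, "noise": noise}, index=[str(i) for i in range(2 * n)]
        )
        return table, labels

    def test_informative_feature_ranks_first(self):
        table, labels = self._labeled_table()
        ranking = rank_features(table, labels)
        assert ranking.entries[0][0] == "informative"
        assert abs(ranking["informative"]) > abs(ranking["noise"])

    def test_label_swap_flips_sign_keeps_order(self):
        table, labels = self._labeled_table()
        fwd = rank_features(table, labels)
        swapped = labels.map({"a": "z_b", "b": "a"})  # alphabetical order reversed
        rev = rank_features(table, swapped)
        assert [e[0] for e in fwd.entries] == [e[0] for e in rev.entries]
        assert fwd["informative"] == pytest.approx(-rev["informative"])

    def test_invalid_cells_excluded_pairwise_and_reported(self):
        table, labels = self._labeled_table()
        table.df.loc["3", "informative"] = np.nan
        ranking = rank_features(table, labels)
        assert ranking.n_excluded["informative"] == 1

    def test_threshold60_features_selected_on_exemplars(self, exemplars, exemplar_table):
        """Feature selection singles out the Threshold-60 area and
        minor-axis-intensity pair for intact-vs-full separation."""
        _, truth = exemplars
        two = truth["golgi_class"][truth["golgi_class"].isin(["intact", "full"])]
        ranking = rank_features(exemplar_table, two)
        top3 = ranking.top(3)
        assert "golgi_t60_area" in top3
        assert "golgi_t60_minor_axis_intensity" in top3


class TestSingletsFocused:
    def test_doublets_fail_singlet_gate(self, gate_config):
        preset = class_preset(golgi="intact", doublet_rate=0.5)
        cells, truth = sample_population(preset, 400, 31)
        table = compute_feature_table(cells)
        flags = gate_singlets_focused(table, gate_config)
        doublets = truth.index[truth["doublet"]]
        singles = truth.index[~truth["doublet"] & ~truth["out_of_focus"]]
        assert (~flags.loc[doublets, "singlet"]).mean() >= 0.90
        assert flags.loc[singles, "singlet"].mean() >= 0.95

    def test_blurred_cells_fail_focus_gate(self, gate_config):
        preset = class_preset(golgi="intact", out_of_focus_rate=0.5)
        cells, truth = sample_population(preset, 400, 32)
        table = compute_feature_table(cells)
        flags = gate_singlets_focused(table, gate_config)
        oof = truth.index[truth["out_of_focus"]]
        sharp = truth.index[~truth["out_of_focus"] & ~truth["doublet"]]
        assert (~flags.loc[oof, "focused"]).mean() >= 0.90
        assert flags.loc[sharp, "focused"].mean() >= 0.95


class TestDnaContent:
    def test_pure_2n_population_is_g1(self):
        cells, _ = render_class_population(300, 41, nucleus="interphase_g1")
        labels = gate_dna_content(compute_feature_table(cells))
        assert (labels == "G1").mean() >= 0.95

    def test_balanced_2n_4n_mixture_recovers_g2m_fraction(self):
        from golgiq.synthcells import GolgiClass, NucleusClass, PopulationPreset

        preset = PopulationPreset(
            "mix5050",
            {
                (GolgiClass.INTACT, NucleusClass.INTERPHASE_G1): 0.5,
                (GolgiClass.INTACT, NucleusClass.INTERPHASE_G2): 0.5,
            },
            doublet_rate=0.0,
            out_of_focus_rate=0.0,
        )
        cells, _ = sample_population(preset, 2000, 42)
        labels = gate_dna_content(compute_feature_table(cells))
        assert (labels == "G2M").mean() * 100 == pytest.approx(50, abs=5)

    def test_constant_intensities_all_g1(self):
        table = _table({"dna_total_intensity": [1000.0] * 60}, index=[str(i) for i in range(60)])
        labels = gate_dna_content(table)
        assert (labels == "G1").all()

    def test_too_few_cells_advises_manual_config(self):
        table = _table({"dna_total_intensity": [1000.0] * 10}, index=[str(i) for i in range(10)])
        with pytest.raises(Exception, match="g1_reference"):
            gate_dna_content(table)


class TestClassifyMitotic:
    @pytest.mark.parametrize(
        "nucleus,expected,min_rate",
        [
            ("metaphase", "metaphase", 0.80),
            ("anaphase", "anaphase", 0.80),
            ("telophase", "telophase", 0.80),
            ("prophase", "prophase", 0.80),
            ("interphase_g2", "none", 0.90),
        ],
    )
    def test_per_class_recovery(self, gate_config, nucleus, expected, min_rate):
        cells, _ = render_class_population(200, 51, golgi="intact", nucleus=nucleus)
        table = compute_feature_table(cells)
        cycle = pd.Series("G2M", index=table.df.index)  # cells already gated G2M
        labels = classify_mitotic(cells, table, cycle, gate_config)
        assert (labels == expected).mean() >= min_rate

    def test_labels_only_within_g2m(self, gate_config):
        cells, _ = render_class_population(60, 52, nucleus="metaphase")
        table = compute_feature_table(cells)
        cycle = pd.Series("G1", index=table.df.index)
        labels = classify_mitotic(cells, table, cycle, gate_config)
        assert (labels == "none").all()


class TestApoptosisGate:
    def test_apoptotic_population_flagged(self, gate_config):
        cells, _ = render_class_population(200, 61, nucleus="apoptotic")
        flags = gate_apoptotic(compute_feature_table(cells), gate_config)
        assert flags.mean() >= 0.85

    def test_healthy_population_mostly_clean(self, gate_config):
        cells, _ = render_class_population(200, 62, nucleus="interphase_g1")
        flags = gate_apoptotic(compute_feature_table(cells), gate_config)
        assert flags.mean() <= 0.05

    def test_infinite_thresholds_flag_all_or_none(self, gate_config):
        import dataclasses

        cells, _ = render_class_population(30, 63, nucleus="interphase_g1")
        table = compute_feature_table(cells)
        all_cfg = dataclasses.replace(
            gate_config,
            apoptosis=dataclasses.replace(
                gate_config.apoptosis, bf_contrast_min=-math.inf, dna_t50_area_max_um2=math.inf
            ),
        )
        none_cfg = dataclasses.replace(
            gate_config,
            apoptosis=dataclasses.replace(
                gate_config.apoptosis, bf_contrast_min=math.inf, dna_t50_area_max_um2=-math.inf
            ),
        )
        assert gate_apoptotic(table, all_cfg).all()
        assert not gate_apoptotic(table, none_cfg).any()


class TestGolgiGateFit:
    def test_resubstitution_accuracy_on_exemplars(self, exemplars, exemplar_table):
        _, truth = exemplars
        gates = fit_golgi_gates(exemplar_table, truth["golgi_class"])
        labels, _ = classify_golgi(exemplar_table, gates)
        assert (labels == truth["golgi_class"]).mean() >= 0.90

    def test_identical_class_distributions_raise_ordering_error(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 1, 120)
        y = rng.normal(10, 2, 120)
        idx = [str(i) for i in range(120)]
        table = _table(
            {"golgi_t60_minor_axis_intensity": x, "golgi_t60_area": y}, index=idx
        )
        labels = pd.Series(["intact", "partial", "full"] * 40, index=idx)
        with pytest.raises(ValidationError, match="not ordered"):
            fit_golgi_gates(table, labels)

    def test_equal_sds_give_arithmetic_midpoint(self):
        # mirrored samples force equal sample SDs per class
        base = np.array([-1.0, 1.0] * 20)
        idx = [str(i) for i in range(120)]
        x = np.concatenate([1 + base, 5 + base, 11 + base])
        y = np.concatenate([4 + base, 12 + base, 25 + base])
        table = _table({"golgi_t60_minor_axis_intensity": x, "golgi_t60_area": y}, index=idx)
        labels = pd.Series(["intact"] * 40 + ["partial"] * 40 + ["full"] * 40, index=idx)
        gates = fit_golgi_gates(table, labels)
        assert gates.intact_max[0] == pytest.approx(3.0)
        assert gates.intact_max[1] == pytest.approx(8.0)
        assert gates.full_min[0] == pytest.approx(8.0)
        assert gates.full_min[1] == pytest.approx(18.5)

    def test_vw_midpoint_degenerate_sds(self):
        assert _vw_midpoint(1.0, 0.0, 5.0, 0.0) == pytest.approx(3.0)


class TestClassifyGolgi:
    def test_origin_is_intact_and_far_corner_is_full(self):
        gates = GolgiGates(intact_max=(2.0, 6.0), full_min=(9.0, 16.0))
        assert gates.classify_point(0.0, 0.0) == "intact"
        assert gates.classify_point(100.0, 100.0) == "full"

    def test_boundary_points_belong_to_lower_region(self):
        gates = GolgiGates(intact_max=(2.0, 6.0), full_min=(9.0, 16.0))
        assert gates.classify_point(2.0, 6.0) == "intact"  # closed below
        assert gates.classify_point(9.0, 16.0) == "partial"  # open above
        up = np.nextafter(2.0, np.inf)
        down = np.nextafter(2.0, -np.inf)
        assert gates.classify_point(up, 0.0) == "partial"
        assert gates.classify_point(down, 0.0) == "intact"

    def test_invalid_coordinates_unassigned_and_tallied(self):
        gates = GolgiGates(intact_max=(2.0, 6.0), full_min=(9.0, 16.0))
        table = _table(
            {
                "golgi_t60_minor_axis_intensity": [1.0, np.nan],
                "golgi_t60_area": [2.0, 3.0],
            },
            index=["a", "b"],
        )
        labels, qc = classify_golgi(table, gates)
        assert labels["a"] == "intact"
        assert labels["b"] == "unassigned"
        assert qc["n_invalid_xy"] == 1

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        x=st.floats(0, 1e6, allow_nan=False),
        y=st.floats(0, 1e6, allow_nan=False),
    )
    def test_partition_every_finite_point_gets_exactly_one_label(self, x, y):
        gates = GolgiGates(intact_max=(2.0, 6.0), full_min=(9.0, 16.0))
        assert gates.classify_point(x, y) in ("intact", "partial", "full")

    def test_polygon_gates_partition_with_nearest_fallback(self):
        gates = GolgiGates(
            polygons={
                "intact": [[0, 0], [2, 0], [2, 6], [0, 6]],
                "partial": [[2, 0], [9, 0], [9, 16], [2, 16]],
                "full": [[9, 0], [40, 0], [40, 200], [9, 200]],
            }
        )
        assert gates.classify_point(1.0, 3.0) == "intact"
        assert gates.classify_point(5.0, 8.0) == "partial"
        assert gates.classify_point(20.0, 50.0) == "full"
        # outside every polygon: nearest region wins, deterministically
        assert gates.classify_point(1.0, 300.0) in ("intact", "partial", "full")


class TestHierarchy:
    def test_golgi_only_on_eligible_and_mitotic_only_in_g2m(self, gate_config):
        preset = class_preset(golgi="partial", doublet_rate=0.3, out_of_focus_rate=0.2)
        cells, _ = sample_population(preset, 300, 71)
        table = compute_feature_table(cells)
        result = run_gating(cells, table, gate_config)
        df = result.df
        ineligible = ~(df["singlet"] & df["focused"])
        assert (df.loc[ineligible, "golgi"] == "unassigned").all()
        assert not df.loc[ineligible, "apoptotic"].any()
        assert (df.loc[df["mitotic"] != "none", "cycle"] == "G2M").all()
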