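"""Model fixtures and spike-rate analysis: selection-network structure,
rate-to-spiking conversion factors, striatal cube fixture, kernel rate
estimation and selection detection."""

import dataclasses

import numpy as np
import pytest

from spinemk import analysis, fixtures
from spinemk.experiments import Experiment, TimeVaryingInput
from spinemk.fixtures import (
    SELECTION_ROSTER,
    SelectionNetworkConfig,
    SnnConversionConfig,
    StructureError,
    build_selection_network,
    build_striatal_like_fixture,
    convert_rate_to_snn,
)
from spinemk.network import (
    FixedValue,
    OneToOne,
    UniformDistribution,
    sample_property,
    validate_network,
)
from spinemk.simulator import EventTrace, build_runtime, run


class TestSelectionNetwork:
    def test_default_build_validates(self, selection_project):
        assert validate_network(selection_project.network,
                                selection_project.components) == []

    def test_channel_count_propagates(self):
        project = build_selection_network(
            SelectionNetworkConfig(n_channels=3))
        assert all(p.size == 3 for p in project.network.populations)

    def test_roster_edge_count(self, selection_project):
        assert len(SELECTION_ROSTER) == 8  # enumerated connection roster
        assert len(selection_project.network.projections) == 8

    def test_missing_weight_entries_are_listed(self):
        cfg = SelectionNetworkConfig()
        del cfg.weights[("GPe", "STN")]
        with pytest.raises(fixtures.ConfigError, match="GPe->STN"):
            build_selection_network(cfg)

    def test_sign_pattern_of_default_table(self):
        cfg = SelectionNetworkConfig()
        inhibitory = {("SD1", "SNr"), ("SD2", "GPe"), ("GPe", "STN")}
        for edge, w in cfg.weights.items():
            if edge in inhibitory:
                assert w < 0
            else:
                assert w > 0


def _steady_snr(project, drive_by_channel, duration=1.0, seed=0):
    """Steady-state output-nucleus activity under constant cortical drive."""
    inputs = tuple(
        TimeVaryingInput("Cortex", "in", ((0.0, u),), indices=(c,))
        for c, u in drive_by_channel.items() if u != 0.0)
    exp = Experiment(
        "probe", project.network.name, duration=duration, dt=1.0,
        inputs=inputs,
        loggers=(dataclasses.replace(
            project.experiments[0].loggers[0]),))
    logs = run(build_runtime(project, exp, master_seed=seed))
    return logs.analog["snr_out"].data[-1]


class TestDisinhibition:
    @pytest.mark.parametrize("table_seed", [1, 2, 3, 4, 5])
    def test_focal_drive_lowers_that_channels_output(self, table_seed):
        # sign-consistent random table: striatal/pallidal inhibitory with
        # unit-scale magnitudes, cortical->STN and STN->* excitatory but
        # weaker, as in the published channel competition architecture
        rng = np.random.default_rng(table_seed)
        weights = {
            ("Cortex", "SD1"): rng.uniform(0.8, 1.2),
            ("Cortex", "SD2"): rng.uniform(0.8, 1.2),
            ("Cortex", "STN"): rng.uniform(0.3, 0.5),
            ("SD1", "SNr"): -rng.uniform(0.8, 1.2),
            ("SD2", "GPe"): -rng.uniform(0.8, 1.2),
            ("STN", "SNr"): rng.uniform(0.3, 0.5),
            ("STN", "GPe"): rng.uniform(0.3, 0.5),
            ("GPe", "STN"): -rng.uniform(0.8, 1.2),
        }
        project = build_selection_network(
            SelectionNetworkConfig(n_channels=2, weights=weights))
        baseline = _steady_snr(project, {})
        driven = _steady_snr(project, {0: 0.4})
        assert driven[0] < baseline[0]  # disinhibition of the driven channel
        assert driven[1] == pytest.approx(baseline[1], abs=1e-9)

    def test_dual_selection_with_equal_inputs(self):
        project = build_selection_network(
            SelectionNetworkConfig(n_channels=3))
        out = _steady_snr(project, {0: 0.6, 1: 0.6}, duration=1.5)
        selected = out < analysis.RATE_MODEL_THRESHOLD
        assert selected[0] and selected[1] and not selected[2]


class TestConversion:
    def test_single_unit_becomes_seven_neurons(self):
        project = build_selection_network(
            SelectionNetworkConfig(n_channels=1))
        snn = convert_rate_to_snn(project, seed=0)
        assert all(p.size == 7 for p in snn.network.populations)

    def test_weights_divided_sevenfold(self):
        cfg = SelectionNetworkConfig(n_channels=1)
        cfg.weights[("Cortex", "SD1")] = 0.7
        snn = convert_rate_to_snn(build_selection_network(cfg), seed=0)
        proj = next(p for p in snn.network.projections
                    if (p.source, p.destination) == ("Cortex", "SD1"))
        w = dict(proj.synapses[0].weight_update.properties)["w"]
        assert w == FixedValue(0.7 / 7.0)

    def test_currents_scaled_tenfold_except_stn_intrinsic(self):
        cfg = SelectionNetworkConfig(n_channels=1)
        cfg.epsilons["GPe"] = -1.5  # becomes intrinsic current +1.5
        cfg.epsilons["STN"] = -0.25
        snn = convert_rate_to_snn(build_selection_network(cfg), seed=0)
        gpe = snn.network.population("GPe").property_dict()["I_offset"]
        stn = snn.network.population("STN").property_dict()["I_offset"]
        assert gpe == FixedValue(15.0)  # 1.5 * 10
        assert stn == FixedValue(0.25)  # exempt from the current scale

    def test_membrane_time_constants_from_stated_uniform_range(self):
        snn = convert_rate_to_snn(build_selection_network(), seed=5)
        tau = snn.network.population("SD1").property_dict()["tau_m"]
        assert isinstance(tau, UniformDistribution)
        assert (tau.minimum, tau.maximum) == (20.0, 30.0)
        sampled = sample_property(tau, 42, seed=0)
        assert sampled.min() >= 20.0 and sampled.max() < 30.0

    def test_synapse_time_constant_is_4ms(self):
        snn = convert_rate_to_snn(build_selection_network(), seed=0)
        for proj in snn.network.projections:
            tau_s = dict(proj.synapses[0].postsynapse.properties)["tau_s"]
            assert tau_s == FixedValue(4.0)

    def test_within_channel_all_to_all_connection_count(self):
        n_channels, m = 3, 7
        snn = convert_rate_to_snn(build_selection_network(
            SelectionNetworkConfig(n_channels=n_channels)), seed=0)
        for proj in snn.network.projections:
            clist = proj.synapses[0].connectivity
            # oracle: direct enumeration of within-channel pairs
            expected = {(c * m + i, c * m + j)
                        for c in range(n_channels)
                        for i in range(m) for j in range(m)}
            assert {t[:2] for t in clist.triplets} == expected

    def test_d2_dopamine_scaled_down(self):
        snn = convert_rate_to_snn(
            build_selection_network(),
            SnnConversionConfig(d2_dopamine_factor=0.8), seed=0)
        d1 = snn.network.population("SD1").property_dict()["da"]
        d2 = snn.network.population("SD2").property_dict()["da"]
        assert d1 == FixedValue(0.2)
        assert d2 == FixedValue(pytest.approx(0.16))

    def test_cortical_input_becomes_regular_spikes(self):
        snn = convert_rate_to_snn(build_selection_network(), seed=0)
        from spinemk.experiments import RegularSpikeInput
        spikes = [s for s in snn.experiments[0].inputs
                  if isinstance(s, RegularSpikeInput)]
        assert spikes, "analog cortical drive must become spike trains"
        # drive level 0.4 maps to 40 Hz under the 0.1 <-> 10 Hz scale
        assert any(s.rate == pytest.approx(40.0) for s in spikes)

    def test_converted_network_validates(self):
        snn = convert_rate_to_snn(build_selection_network(), seed=0)
        assert validate_network(snn.network, snn.components) == []

    def test_seed_determinism_of_sampled_time_constants(self):
        a = convert_rate_to_snn(build_selection_network(), seed=11)
        b = convert_rate_to_snn(build_selection_network(), seed=11)
        ta = a.network.population("GPe").property_dict()["tau_m"]
        tb = b.network.population("GPe").property_dict()["tau_m"]
        assert ta == tb
        assert np.array_equal(sample_property(ta, 42, 0),
                              sample_property(tb, 42, 0))

    def test_non_isomorphic_source_rejected(self):
        project = build_selection_network()
        bad = dataclasses.replace(project)
        net = project.network
        proj0 = net.projections[0]
        from spinemk.network import AllToAll, Projection, Synapse
        bad.network = dataclasses.replace(net, projections=(
            Projection(proj0.source, proj0.destination, (
                dataclasses.replace(proj0.synapses[0],
                                    connectivity=AllToAll()),)),)
            + net.projections[1:])
        with pytest.raises(StructureError):
            convert_rate_to_snn(bad, seed=0)


@pytest.fixture(scope="module")
def striatal():
    return build_striatal_like_fixture(84, 84, 4, seed=7)


class TestStriatalFixture:
    def test_all_coordinates_inside_cube(self, striatal):
        from spinemk.layouts import generate_layout
        for pop in striatal.network.populations:
            coords = generate_layout(striatal.layouts[pop.layout_ref],
                                     pop.size)
            assert ((coords.coordinates >= 0)
                    & (coords.coordinates < 300)).all()

    def test_connections_respect_radius(self, striatal):
        from spinemk.layouts import generate_layout
        coords = {
            pop.name: generate_layout(striatal.layouts[pop.layout_ref],
                                      pop.size).coordinates
            for pop in striatal.network.populations}
        proj = next(p for p in striatal.network.projections
                    if p.destination == "MSN_D1")
        clist = proj.synapses[0].connectivity
        for s, d, delay in clist.triplets:
            dist = np.linalg.norm(coords["FSI"][s] - coords["MSN_D1"][d])
            assert dist <= 100.0
            assert delay == pytest.approx(dist)  # velocity 1 um/ms

    def test_minimum_distance_within_populations(self, striatal):
        from spinemk.layouts import generate_layout
        for pop in striatal.network.populations:
            coords = generate_layout(striatal.layouts[pop.layout_ref],
                                     pop.size)
            assert coords.min_pairwise_distance() >= 10.0

    def test_network_validates(self, striatal):
        assert validate_network(striatal.network, striatal.components) == []


class TestGaussianRate:
    def test_no_spikes_gives_zero_trace(self):
        trace = analysis.gaussian_rate([], 0.1, np.linspace(0, 1, 11))
        assert np.array_equal(trace.values, np.zeros((11, 1)))

    def test_regular_train_recovers_its_rate(self):
        spikes = 0.1 * np.arange(100)  # 10 Hz for 10 s
        trace = analysis.gaussian_rate(spikes, 0.1, np.array([5.0]))
        assert trace.values[0, 0] == pytest.approx(10.0, rel=1e-6)

    def test_linearity_doubling_spikes_doubles_trace(self):
        spikes = np.array([0.2, 0.5, 0.9])
        grid = np.linspace(0, 1.2, 25)
        single = analysis.gaussian_rate(spikes, 0.05, grid)
        doubled = analysis.gaussian_rate(np.repeat(spikes, 2), 0.05, grid)
        assert np.allclose(doubled.values, 2 * single.values)

    def test_integrates_to_spike_count(self):
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(2.0, 4.0, 37))
        grid = np.linspace(-2.0, 8.0, 4001)  # wide grid
        trace = analysis.gaussian_rate(spikes, 0.1, grid)
        integral = np.trapezoid(trace.values[:, 0], grid)
        assert integral == pytest.approx(37.0, abs=1e-3)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            analysis.gaussian_rate([0.0], 0.0, np.array([0.0]))


class TestDetectSelection:
    def test_constant_below_threshold_selected_throughout(self):
        trace = analysis.RateTrace(np.linspace(0, 1, 5), np.full((5, 1), 0.05))
        assert analysis.detect_selection(trace, 0.1).all()

    def test_boundary_is_strict(self):
        trace = analysis.RateTrace(np.linspace(0, 1, 5), np.full((5, 1), 0.1))
        assert not analysis.detect_selection(trace, 0.1).any()

    def test_two_equal_subthreshold_channels_both_selected(self):
        values = np.column_stack([np.full(5, 0.05), np.full(5, 0.05),
                                  np.full(5, 0.2)])
        trace = analysis.RateTrace(np.linspace(0, 1, 5), values)
        selected = analysis.detect_selection(trace, 0.1)
        assert selected[:, 0].all() and selected[:, 1].all()
        assert not selected[:, 2].any()


class TestPlotsAndExport:
    def test_raster_plots_one_mark_per_spike(self):
        events = EventTrace(np.array([0.1, 0.2, 0.3, 0.35]),
                            np.array([0, 1, 0, 2]))
        fig = analysis.plot_raster(events)
        line = fig.axes[0].lines[0]
        assert len(line.get_xdata()) == 4
        assert np.array_equal(line.get_ydata(), [0, 1, 0, 2])

    def test_line_plot_carries_the_trace_data(self):
        trace = analysis.RateTrace(np.linspace(0, 1, 10),
                                   np.random.default_rng(0).random((10, 3)))
        fig = analysis.plot_lines(trace)
        assert len(fig.axes[0].lines) == 3
        assert np.allclose(fig.axes[0].lines[1].get_ydata(),
                           trace.values[:, 1])

    def test_png_and_pdf_outputs(self, tmp_path):
        trace = analysis.RateTrace(np.linspace(0, 1, 10),
                                   np.zeros((10, 1)))
        for ext in ("png", "pdf"):
            path = tmp_path / f"plot.{ext}"
            analysis.plot_lines(trace, out_path=str(path))
            assert path.stat().st_size > 0

    def test_csv_export_shapes(self, small_selection_project, tmp_path):
        exp = dataclasses.replace(
            small_selection_project.experiments[0], duration=0.1)
        logs = run(build_runtime(small_selection_project, exp,
                                 master_seed=0))
        files = analysis.write_csv(logs, str(tmp_path))
        assert sorted(files) == ["sd1_first_two.csv", "snr_out.csv"]
        header = (tmp_path / "snr_out.csv").read_text().splitlines()[0]
        assert header == "time,channel0,channel1"
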