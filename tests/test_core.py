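"""Blueprint serialization, model assembly, and deterministic stepping."""

import numpy as np
import pytest

import snnkit
from snnkit import (
    Blueprint, EdgeSpec, NodeSpec, BlueprintValidationError, ConfigurationError,
    build_model, deserialize_blueprint, serialize_blueprint,
)
from snnkit.core import SimulationClock, _execution_order


class TestBlueprintSerialization:
    def test_round_trip_identity(self, two_pool_blueprint):
        text = serialize_blueprint(two_pool_blueprint)
        again = serialize_blueprint(deserialize_blueprint(text))
        assert text == again

    def test_unknown_field_rejected(self, two_pool_blueprint):
        text = serialize_blueprint(two_pool_blueprint).replace(
            '"version"', '"surprise": 1,\n  "version"')
        with pytest.raises(BlueprintValidationError):
            deserialize_blueprint(text)

    def test_version_mismatch_is_explicit(self, two_pool_blueprint):
        text = serialize_blueprint(two_pool_blueprint).replace('"version": "1"', '"version": "99"')
        with pytest.raises(BlueprintValidationError, match="version"):
            deserialize_blueprint(text)

    def test_malformed_text_reports_location(self):
        with pytest.raises(BlueprintValidationError, match="line"):
            deserialize_blueprint("{not json")


class TestValidation:
    def test_dangling_edge_lists_offenders(self):
        bp = Blueprint(nodes={"a": NodeSpec(kind="lif_pool", params={"n": 2})},
                       edges=[EdgeSpec(source="a", source_port="spikes",
                                       target="ghost", target_port="current")])
        with pytest.raises(BlueprintValidationError, match="ghost"):
            build_model(bp)

    def test_unknown_kind_names_node(self):
        bp = Blueprint(nodes={"mystery": NodeSpec(kind="warp_drive")})
        with pytest.raises(ConfigurationError, match="mystery"):
            build_model(bp)

    def test_port_size_mismatch_rejected(self):
        bp = Blueprint(
            nodes={"a": NodeSpec(kind="lif_pool", params={"n": 4}),
                   "b": NodeSpec(kind="lif_pool", params={"n": 5})},
            edges=[EdgeSpec(source="a", source_port="spikes",
                            target="b", target_port="current")])
        with pytest.raises(BlueprintValidationError):
            build_model(bp)

    def test_external_shape_mismatch_names_port(self, two_pool_blueprint):
        model = build_model(two_pool_blueprint)
        with pytest.raises(BlueprintValidationError, match="current"):
            model.step({("a", "current"): np.zeros(99)})


class TestClock:
    def test_t_is_derived_from_step_index(self):
        clock = SimulationClock(dt=0.1)
        for _ in range(1000):
            clock.advance()
        assert clock.t == 1000 * 0.1  # exact: integer accounting, single product

    def test_dt_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            SimulationClock(dt=0.0)


class TestBuildModel:
    def test_empty_blueprint_steps_as_noop(self):
        model = build_model(Blueprint())
        out = model.step({})
        assert out == {}
        assert model.clock.step_index == 1

    def test_identical_builds_are_bit_identical(self, two_pool_blueprint):
        m1 = build_model(two_pool_blueprint, seed=7)
        m2 = build_model(two_pool_blueprint, seed=7)
        s1, s2 = m1.component("syn"), m2.component("syn")
        assert np.array_equal(s1.W, s2.W)
        assert np.array_equal(s1.delays, s2.delays)

    def test_different_seeds_same_topology_different_weights(self, two_pool_blueprint):
        m1 = build_model(two_pool_blueprint, seed=1)
        m2 = build_model(two_pool_blueprint, seed=2)
        s1, s2 = m1.component("syn"), m2.component("syn")
        assert s1.W.shape == s2.W.shape
        assert not np.array_equal(s1.W, s2.W)

    def test_cartpole_blueprint_population_sizes(self):
        model = build_model(snnkit.cartpole_blueprint(), seed=0)
        assert model.component("e_left").n == 256
        assert model.component("i_left").n == 64
        assert model.component("e_right").n == 256
        assert model.component("i_right").n == 64


class TestStepping:
    def test_zero_input_pool_stays_silent(self):
        bp = Blueprint(nodes={"pool": NodeSpec(kind="lif_pool", params={"n": 8})})
        model = build_model(bp)
        for _ in range(100):
            out = model.step({("pool", "current"): np.zeros(8)})
        assert np.all(out[("pool", "spikes")] == 0)

    def test_determinism_over_thousand_steps(self, two_pool_blueprint):
        rasters = []
        for _ in range(2):
            model = build_model(two_pool_blueprint, seed=3)
            drive_rng = np.random.default_rng(5)
            raster = []
            for _ in range(1000):
                I = drive_rng.uniform(0, 40, size=4)
                out = model.step({("a", "current"): I})
                raster.append(out[("b", "spikes")].copy())
            rasters.append(np.array(raster))
        assert np.array_equal(rasters[0], rasters[1])

    def test_isolation_of_disconnected_components(self):
        bp = Blueprint(nodes={
            "x": NodeSpec(kind="lif_pool", params={"n": 3}),
            "y": NodeSpec(kind="lif_pool", params={"n": 3}),
        })
        trajs = []
        for tweak in (False, True):
            model = build_model(bp, seed=9)
            if tweak:
                model.component("y").params = snnkit.LIFParams(tau_m=3.0)
                model.component("y").reset()
            traj = []
            for k in range(200):
                out = model.step({("x", "current"): np.full(3, 20.0),
                                  ("y", "current"): np.full(3, 5.0)})
                traj.append(out[("x", "spikes")].copy())
            trajs.append(np.array(traj))
        assert np.array_equal(trajs[0], trajs[1])

    def test_cycles_execute_with_one_step_delay(self):
        # mutual ring a -> b -> a still admits a deterministic order
        bp = Blueprint(
            nodes={"a": NodeSpec(kind="lif_pool", params={"n": 2}),
                   "sab": NodeSpec(kind="traced_synapse",
                                   params={"n_pre": 2, "n_post": 2, "density": 1.0}),
                   "b": NodeSpec(kind="lif_pool", params={"n": 2}),
                   "sba": NodeSpec(kind="traced_synapse",
                                   params={"n_pre": 2, "n_post": 2, "density": 1.0})},
            edges=[EdgeSpec(source="a", source_port="spikes", target="sab", target_port="spikes"),
                   EdgeSpec(source="sab", source_port="current", target="b", target_port="current"),
                   EdgeSpec(source="b", source_port="spikes", target="sba", target_port="spikes"),
                   EdgeSpec(source="sba", source_port="current", target="a", target_port="current")])
        order = _execution_order(bp)
        assert sorted(order) == ["a", "b", "sab", "sba"]
        model = build_model(bp, seed=0)
        for _ in range(50):
            model.step({})
        assert model.clock.step_index == 50

    def test_two_node_smoke_fixture_builds_and_steps(self, two_pool_blueprint, tmp_path):
        path = tmp_path / "bp.json"
        path.write_text(serialize_blueprint(two_pool_blueprint))
        model = build_model(deserialize_blueprint(path.read_text()), seed=11)
        out = model.step({("a", "current"): np.full(4, 30.0)})
        assert out[("b", "spikes")].shape == (3,)


class TestPrecision:
    def test_float16_model_builds_and_steps(self, two_pool_blueprint):
        model = build_model(two_pool_blueprint, precision="float16", seed=2)
        out = model.step({("a", "current"): np.full(4, 30.0)})
        assert out[("b", "spikes")].shape == (3,)
        assert model.component("a").state.v.dtype == np.float16

    def test_unknown_precision_rejected(self, two_pool_blueprint):
        with pytest.raises(ConfigurationError):
            build_model(two_pool_blueprint, precision="float128")
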