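"""Metrics, fixtures, configuration, and the command-line interface."""

import json
import warnings

import numpy as np
import pytest
from click.testing import CliRunner

from tvcoupling.cli import main
from tvcoupling.evaluation import (
    ConfigError,
    RunConfig,
    build_system,
    fixture_50node,
    fixture_6node_analogue,
    fixture_6node_noisy,
    fixture_consensus,
    fixture_sync,
    relative_error,
    run_config,
    suggest_snapshot_offset,
    support_metrics,
    synchronization_index,
)


class TestRelativeError:
    def test_exact_estimate_scores_zero(self, rng):
        C = rng.normal(size=(4, 4))
        m = relative_error(C, C)
        assert m.max_abs_error == 0.0 and m.rel_frobenius_error == 0.0

    def test_zero_truth_guards_division(self):
        m = relative_error(np.full((3, 3), 0.2), np.zeros((3, 3)))
        assert m.rel_frobenius_error is None
        assert np.isclose(m.max_abs_error, 0.2)

    def test_hand_example(self):
        C_true = np.array([[0.0, 1.0], [0.0, 0.0]])
        C_hat = np.array([[0.0, 1.1], [0.0, 0.0]])
        assert np.isclose(relative_error(C_hat, C_true).max_abs_error, 0.1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_error(np.eye(3), np.eye(4))


class TestSupportMetrics:
    def test_perfect_mask(self):
        m = np.array([[False, True], [True, False]])
        assert support_metrics(m, m) == (1.0, 1.0)

    def test_empty_prediction_convention(self):
        truth = np.array([[False, True], [True, False]])
        empty = np.zeros((2, 2), dtype=bool)
        precision, recall = support_metrics(empty, truth)
        assert precision == 1.0 and recall == 0.0

    def test_counting_case(self):
        truth = np.zeros((4, 4), dtype=bool)
        pred = np.zeros((4, 4), dtype=bool)
        edges = [(0, 1), (1, 2), (2, 3), (3, 0)]
        for i, j in edges:
            truth[i, j] = True
        for i, j in edges[:3]:
            pred[i, j] = True
        pred[0, 2] = True  # one false positive, one false negative
        assert support_metrics(pred, truth) == (0.75, 0.75)


class TestSynchronizationIndex:
    def test_identical_nodes_fully_synchronized(self):
        X = np.tile([1.0, 2.0, 3.0], 5)
        assert synchronization_index(X, 5, 3) == 0.0

    def test_two_scalar_nodes(self):
        assert synchronization_index(np.array([0.0, 3.0]), 2, 1) == 3.0

    def test_decreasing_along_consensus_trajectory(self):
        from scipy.linalg import expm

        from tvcoupling.network_model import CouplingSpec, coupling_at

        spec = CouplingSpec(N=4, weight_fns={(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0},
                            symmetric=True)
        C = coupling_at(spec, 0.0)
        x0 = np.array([1.0, -1.0, 0.5, -0.5])
        vals = [synchronization_index(expm(C * t) @ x0, 4, 1) for t in (0.0, 1.0, 3.0)]
        assert vals[0] > vals[1] > vals[2]


class TestFixtures:
    def test_fifty_node_recipe(self):
        cfg = fixture_50node(0)
        assert len(cfg.network["edges"]) == 100  # N k / 2
        fns = {(e["i"], e["j"]): e["fn"] for e in cfg.network["edges"]}
        assert fns[(0, 2)] == "abs_sin" and fns[(1, 3)] == "log1p"
        assert cfg.simulation["K"] == 100
        sys_ = build_system(cfg)
        assert sys_.state_dim == 150
        from tvcoupling.network_model import coupling_at

        assert coupling_at(sys_.coupling, 0.0)[0, 2] == 0.0  # |sin 0|

    def test_six_node_directed_and_m12(self):
        cfg = fixture_6node_analogue(0)
        sys_ = build_system(cfg)
        from tvcoupling.network_model import coupling_at

        C = coupling_at(sys_.coupling, 1.0)
        assert not np.allclose(C, C.T)  # directed
        assert np.max(np.abs(C.sum(axis=1))) <= 1e-12
        assert cfg.simulation["K"] + 1 == 12

    def test_noisy_variant_scales_offset_with_noise(self):
        weak = fixture_6node_noisy(0, 0.01)
        strong = fixture_6node_noisy(0, 0.1)
        assert weak.simulation["dt_snap"] < strong.simulation["dt_snap"]
        assert weak.simulation["central"] and weak.noise["high"] == 0.01
        assert np.isclose(
            weak.simulation["dt_snap"], suggest_snapshot_offset(0.01)
        )

    def test_consensus_shapes_and_guard(self):
        cfg = fixture_consensus(N=30, seed=0, K=20)
        sys_ = build_system(cfg)
        assert sys_.n == 1 and sys_.state_dim == 30
        with pytest.raises(ValueError):
            fixture_consensus(N=8)

    def test_consensus_conserves_state_sum(self):
        from tvcoupling.evaluation import simulate_from_config

        cfg = fixture_consensus(N=30, seed=0, K=3)
        cfg.simulation["t_end"] = 1.0
        cfg.identification["times"] = [0.5]
        _, ens = simulate_from_config(cfg)
        sums = ens.states.sum(axis=2)  # (K, T)
        assert np.max(np.abs(sums - sums[:, :1])) <= 1e-9

    def test_sync_fixture_validates(self):
        cfg = fixture_sync(0)
        assert cfg.identification["times"][0] < 1.0 < cfg.identification["times"][-1]


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = fixture_6node_analogue(3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = RunConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()
        assert back.sha256() == cfg.sha256()

    def test_edge_csv_round_trip(self, tmp_path):
        cfg = fixture_6node_analogue(0)
        path = tmp_path / "edges.csv"
        cfg.edges_to_csv(path)
        edges = RunConfig.edges_from_csv(path)
        assert edges == cfg.network["edges"]

    @pytest.mark.parametrize(
        "mutate,key",
        [
            (lambda d: d["network"].pop("dynamics"), "network.dynamics"),
            (lambda d: d["network"].update(dynamics="rossler"), "network.dynamics"),
            (lambda d: d["simulation"].update(K=0), "simulation.K"),
            (lambda d: d["identification"].update(times=[]), "identification.times"),
            (lambda d: d["network"]["edges"].append({"i": 0, "j": 1, "fn": "nope"}),
             "fn"),
        ],
    )
    def test_validation_names_offending_key(self, mutate, key):
        d = fixture_6node_analogue(0).to_dict()
        mutate(d)
        with pytest.raises(ConfigError, match=key.split(".")[-1]):
            RunConfig.from_dict(d)

    def test_unknown_block_rejected(self):
        d = fixture_6node_analogue(0).to_dict()
        d["extra"] = {}
        with pytest.raises(ConfigError, match="extra"):
            RunConfig.from_dict(d)


class TestEndToEnd:
    def test_run_config_reproducible(self):
        cfg = fixture_consensus(N=30, seed=1, K=20)
        cfg.identification["times"] = [0.2]
        cfg.simulation["t_end"] = 0.3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_config(cfg)
            b = run_config(fixture_consensus(N=30, seed=1, K=20).__class__.from_dict(cfg.to_dict()))
        assert np.array_equal(a["sweep"].estimates[0].C_hat, b["sweep"].estimates[0].C_hat)
        assert a["manifest"]["config_sha256"] == b["manifest"]["config_sha256"]


class TestCli:
    def test_demo_reports_metrics_table(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["demo", "--fixture", "six-node", "--seed", "0",
                   "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        assert "max_abs_err" in result.output
        assert (tmp_path / "manifest.json").exists()
        metrics = json.loads((tmp_path / "metrics.json").read_text())
        assert all(m["max_abs_error"] <= 1e-2 for m in metrics)

    def test_simulate_sweep_evaluate_chain(self, tmp_path):
        cfg = fixture_consensus(N=30, seed=0, K=20)
        cfg.identification["times"] = [0.2]
        cfg.simulation["t_end"] = 0.3
        cfg_path = tmp_path / "cfg.yaml"
        cfg.to_yaml(cfg_path)
        runner = CliRunner()
        r1 = runner.invoke(main, ["simulate", "--config", str(cfg_path),
                                  "--out", str(tmp_path)])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(main, ["sweep", "--config", str(cfg_path),
                                  "--ensemble", str(tmp_path / "ensemble.npz"),
                                  "--out", str(tmp_path)])
        assert r2.exit_code == 0, r2.output
        r3 = runner.invoke(main, ["evaluate",
                                  "--estimate", str(tmp_path / "sweep.csv"),
                                  "--truth", str(tmp_path / "sweep.csv")])
        assert r3.exit_code == 0, r3.output
        scores = json.loads(r3.output)
        assert scores[0]["max_abs_error"] == 0.0  # identical files

    def test_identify_requires_time(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        fixture_consensus(N=30, seed=0, K=20).to_yaml(cfg_path)
        runner = CliRunner()
        result = runner.invoke(main, ["identify", "--config", str(cfg_path),
                                      "--out", str(tmp_path)])
        assert result.exit_code != 0
        assert "--time" in result.output or "time" in result.output.lower()
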