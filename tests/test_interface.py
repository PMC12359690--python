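"""On-disk formats, round-trips, and the command-line chain."""

import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from ksnet import interface
from ksnet.cli import main as cli_main
from ksnet.types import ProbabilisticNetwork


class TestKsTable:
    def test_canonical_row_parsed(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("kinase\tsubstrate\tsite\nAKT1\tP53396\tS455\n")
        pairs, rejects = interface.read_ks_table(path)
        assert [(p.kinase_id, p.site_id) for p in pairs] == \
            [("AKT1", "P53396_S455")]
        assert rejects.empty

    def test_case_insensitive_site_token(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("kinase\tsubstrate\tsite\nAKT1\tP53396\ts455\n")
        pairs, _ = interface.read_ks_table(path)
        assert pairs[0].site_id == "P53396_S455"

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("kinase\tsubstrate\tsite\n")
        pairs, rejects = interface.read_ks_table(path)
        assert pairs == [] and rejects.empty

    def test_malformed_rows_collected_with_line_numbers(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text(
            "kinase\tsubstrate\tsite\n"
            "K1\tP1\tS10\n"
            "K2\tP2\tX10\n"       # bad residue
            "K3\tP3\tS0\n"        # bad position
            "K4\tP4\tT7\n"
            "K5\tP5\tY3\n"
        )
        pairs, rejects = interface.read_ks_table(path)
        assert len(pairs) == 3
        assert sorted(rejects["line"]) == [3, 4]

    def test_missing_columns_raise(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("kinase\tresidue\nK1\tS10\n")
        with pytest.raises(ValueError, match="missing required columns"):
            interface.read_ks_table(path)


class TestRoundTrips:
    def test_network_round_trip_exact(self, tmp_path, rng):
        from tests.conftest import random_network_edges

        records = [
            (k, s, round(p, 6))
            for k, s, p in random_network_edges(
                rng, n_kinases=20, n_sites=100, n_edges=1000)
        ]
        net = ProbabilisticNetwork.from_records(records)
        path = tmp_path / "net.tsv"
        interface.write_network(net, path, seed=1)
        back = interface.read_network(path)
        assert len(back) == len(net)
        pd.testing.assert_frame_equal(
            back.edges[["kinase_id", "site_id", "probability"]],
            net.edges[["kinase_id", "site_id", "probability"]],
        )

    def test_pssm_round_trip(self, tmp_path, small_world):
        interface.write_pssm_dir(small_world.pssms, tmp_path / "pssms")
        back = interface.read_pssm_dir(tmp_path / "pssms")
        assert set(back) == set(small_world.pssms)
        kid = next(iter(back))
        assert np.allclose(
            back[kid].weights.to_numpy(),
            small_world.pssms[kid].weights.to_numpy(),
            atol=1e-8,
        )

    def test_pssm_zero_cell_rejected(self, tmp_path):
        d = tmp_path / "pssms"
        d.mkdir()
        from ksnet.types import AMINO_ACIDS

        header = "position\t" + "\t".join(AMINO_ACIDS)
        row = "-1\t0.0" + "\t0.05" * 19
        (d / "KX.tsv").write_text(header + "\n" + row + "\n")
        with pytest.raises(ValueError):
            interface.read_pssm_dir(d)

    def test_world_round_trip(self, tmp_path, small_world):
        interface.write_world(small_world, tmp_path / "world")
        back = interface.read_world(tmp_path / "world")
        assert back.truth_keys == small_world.truth_keys
        assert [s.flank for s in back.sites] == \
            [s.flank for s in small_world.sites]
        assert np.allclose(
            back.expression.to_numpy(), small_world.expression.to_numpy(),
            atol=1e-6,
        )

    def test_gmt_round_trip_and_duplicate_rejection(self, tmp_path):
        sets = {"A": {"g1", "g2"}, "B": {"g3"}}
        path = tmp_path / "sets.gmt"
        interface.write_gmt(sets, path)
        assert interface.read_gmt(path) == sets
        path.write_text("A\tA\tg1\nA\tA\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            interface.read_gmt(path)

    def test_matrix_round_trip_with_missing(self, tmp_path):
        df = pd.DataFrame(
            [[1.25, np.nan], [0.5, -2.0]],
            index=["P1_S1", "P1_S2"], columns=["c1", "c2"],
        )
        df.index.name = "site_id"
        interface.write_matrix(df, tmp_path / "m.tsv")
        back = interface.read_matrix(tmp_path / "m.tsv")
        assert np.isnan(back.at["P1_S1", "c2"])
        assert back.at["P1_S2", "c2"] == pytest.approx(-2.0)

    def test_feature_table_round_trip(self, tmp_path, small_world_features):
        interface.write_feature_table(small_world_features, tmp_path / "ft.tsv")
        back = interface.read_feature_table(tmp_path / "ft.tsv")
        assert back.feature_names == small_world_features.feature_names
        assert len(back) == len(small_world_features)

    def test_headers_carry_version_and_seed(self, tmp_path):
        net = ProbabilisticNetwork.from_records([("K1", "P1_S1", 0.5)])
        interface.write_network(net, tmp_path / "n.tsv", seed=42)
        text = (tmp_path / "n.tsv").read_text()
        assert text.startswith("# ksnet v")
        assert "# seed: 42" in text


class TestCli:
    def _simulate(self, runner, out_dir, seed=5):
        return runner.invoke(
            cli_main,
            ["simulate", "--seed", str(seed), "--out", str(out_dir),
             "--n-kinases", "6", "--n-sites", "120", "--n-true-pairs", "50"],
            catch_exceptions=False,
        )

    def test_simulate_twice_is_byte_identical(self, tmp_path):
        runner = CliRunner()
        for d in ("a", "b"):
            res = self._simulate(runner, tmp_path / d)
            assert res.exit_code == 0
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert not cmp.diff_files
        sub = filecmp.dircmp(tmp_path / "a" / "pssms", tmp_path / "b" / "pssms")
        assert not sub.diff_files

    def test_train_without_required_option_exits_2(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["train", "--seed", "1"])
        assert res.exit_code == 2
        assert "Missing option" in res.output

    def test_unknown_flag_exits_2(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--bogus", "1"])
        assert res.exit_code == 2

    def test_full_chain_flags_planted_kinase(self, tmp_path):
        """simulate -> features -> train -> predict -> activity: the kinase
        activated in a synthetic condition comes out significant."""
        runner = CliRunner()
        world_dir = tmp_path / "world"
        res = self._simulate(runner, world_dir, seed=9)
        assert res.exit_code == 0

        ft = tmp_path / "features.tsv"
        res = runner.invoke(
            cli_main,
            ["features", "--world", str(world_dir), "--out", str(ft)],
            catch_exceptions=False,
        )
        assert res.exit_code == 0

        net_path = tmp_path / "network.tsv"
        res = runner.invoke(
            cli_main,
            ["train", "--world", str(world_dir), "--features", str(ft),
             "--positives", str(world_dir / "truth.tsv"),
             "--out", str(net_path), "--seed", "9", "--n-runs", "2",
             "--k-folds", "3", "--neg-ratio", "5", "--reduced-grid"],
            catch_exceptions=False,
        )
        assert res.exit_code == 0

        summary = tmp_path / "summary.tsv"
        res = runner.invoke(
            cli_main,
            ["predict", "--network", str(net_path), "--out", str(summary)],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
        assert interface.read_table(summary)["n_total"].sum() > 0

        act = tmp_path / "activity.tsv"
        res = runner.invoke(
            cli_main,
            ["activity", "--network", str(net_path), "--world", str(world_dir),
             "--out", str(act), "--seed", "9", "--n-perm", "200",
             "--percentile", "0.8", "--min-set-size", "4"],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
        full = interface.read_table(str(act) + ".full.tsv")
        assert len(full) > 0


class TestCliAnalysis:
    def test_fit_cluster_compare_evaluate_subcommands(self, tmp_path):
        """The analysis subcommands run end to end on a simulated world."""
        runner = CliRunner()
        world_dir = tmp_path / "world"
        res = runner.invoke(
            cli_main,
            ["simulate", "--seed", "21", "--out", str(world_dir),
             "--n-kinases", "8", "--n-sites", "200", "--n-true-pairs", "80"],
            catch_exceptions=False,
        )
        assert res.exit_code == 0

        # A generator-produced network stands in for a full training run.
        from ksnet import synthetic_data as sd

        world = interface.read_world(world_dir)
        net = sd.generate_probabilistic_network(world, seed=22)
        net_path = tmp_path / "network.tsv"
        interface.write_network(net, net_path, seed=22)

        res = runner.invoke(
            cli_main,
            ["fit", "--network", str(net_path), "--world", str(world_dir),
             "--out", str(tmp_path / "fits"), "--seed", "22",
             "--grid", "reduced"],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
        assert (tmp_path / "fits" / "sweep_log.tsv").exists()

        res = runner.invoke(
            cli_main,
            ["cluster", "--network", str(net_path),
             "--out", str(tmp_path / "clusters")],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
        nwk = (tmp_path / "clusters" / "dendrogram.nwk").read_text()
        assert nwk.strip().endswith(";")

        res = runner.invoke(
            cli_main,
            ["evaluate", "--network", str(net_path), "--world", str(world_dir),
             "--out", str(tmp_path / "audit.tsv")],
            catch_exceptions=False,
        )
        assert res.exit_code == 0

        other_path = tmp_path / "other.tsv"
        other = net.edges.rename(columns={"probability": "score"})
        interface.write_table(other, other_path)
        res = runner.invoke(
            cli_main,
            ["compare", "--network", str(net_path), "--other", str(other_path),
             "--positives", str(world_dir / "truth.tsv"),
             "--out", str(tmp_path / "compare.tsv"), "--n-reps", "5",
             "--seed", "23"],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
        table = interface.read_table(tmp_path / "compare.tsv")
        assert len(table) == 5
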