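"""Forward sampling, selection, missingness, stratification, CSV output."""

import csv
import math

import numpy as np
import pytest

from dagforge import (
    MISSING,
    FunctionEvaluationError,
    LabelError,
    NodeRef,
    NodeSpec,
    RejectionBudgetExceededError,
    SequenceSet,
    build_graph,
    make_missing_node,
    simulate,
    stratify_rows,
    write_csv,
)
from dagforge.engine import sanitize_label
from dagforge.stdlib import bernoulli, constant, uniform

from conftest import add_one, const


def unit_uniform(rng):
    return float(rng.uniform(0.0, 1.0))


def symmetric_uniform(rng):
    return float(rng.uniform(-1.0, 1.0))


def accept_ones_half_zeros(x, rng):
    return x == 1 or rng.random() < 0.5


def sign_label(x):
    return "pos" if x > 0 else "neg"


def always_false():
    return False


def always_true():
    return True


class TestSimulate:
    def test_constant_column(self, config_factory):
        g = build_graph([NodeSpec("K", constant, {"value": 7})])
        table = simulate(g, config_factory(5))
        assert table.columns == {"K": [7, 7, 7, 7, 7]}

    def test_deterministic_child(self, config_factory):
        g = build_graph([
            NodeSpec("A", unit_uniform),
            NodeSpec("B", add_one, {"x": NodeRef("A")}),
        ])
        table = simulate(g, config_factory(200))
        assert table.columns["B"] == [a + 1 for a in table.columns["A"]]

    def test_native_values_pass_untranscoded(self, config_factory):
        payload = {"key": [1, 2, 3]}
        g = build_graph([
            NodeSpec("Obj", constant, {"value": payload}),
            NodeSpec("Same", const, {"value": NodeRef("Obj")}),
        ])
        table = simulate(g, config_factory(3))
        assert all(v is payload for v in table.columns["Same"])

    def test_user_error_is_wrapped_with_context(self, config_factory):
        def boom(rng):
            raise RuntimeError("bad")

        g = build_graph([NodeSpec("Bad", boom)])
        with pytest.raises(FunctionEvaluationError, match="Bad"):
            simulate(g, config_factory(3))

    def test_unobserved_node_has_no_column(self, config_factory):
        g = build_graph([
            NodeSpec("Hidden", unit_uniform, observed=False),
            NodeSpec("Seen", add_one, {"x": NodeRef("Hidden")}),
        ])
        table = simulate(g, config_factory(4))
        assert list(table.columns) == ["Seen"]

    def test_same_seed_reproduces_different_seed_varies(self, coin_graph,
                                                        config_factory):
        t1 = simulate(coin_graph, config_factory(50, seed=11))
        t2 = simulate(coin_graph, config_factory(50, seed=11))
        t3 = simulate(coin_graph, config_factory(50, seed=12))
        assert t1.columns == t2.columns
        assert t1.columns != t3.columns


class TestSelection:
    def make_selection_graph(self, accept_func):
        return build_graph([
            NodeSpec("X", bernoulli, {"p": 0.5}),
            NodeSpec("Keep", accept_func, {"x": NodeRef("X")}, kind="selection"),
        ])

    def test_constant_true_is_identity(self, config_factory):
        with_sel = build_graph([
            NodeSpec("X", unit_uniform),
            NodeSpec("Keep", always_true, kind="selection"),
        ])
        without = build_graph([NodeSpec("X", unit_uniform)])
        t1 = simulate(with_sel, config_factory(100, seed=5))
        t2 = simulate(without, config_factory(100, seed=5))
        assert t1.columns == t2.columns

    def test_selection_node_not_a_column(self, config_factory):
        g = self.make_selection_graph(accept_ones_half_zeros)
        table = simulate(g, config_factory(20))
        assert list(table.columns) == ["X"]

    def test_biased_acceptance_matches_bayes(self, config_factory):
        """Accepting X=1 surely and X=0 half the time turns P(X=1)=1/2 into
        P(X=1 | retained) = 2/3."""
        g = self.make_selection_graph(accept_ones_half_zeros)
        n = 10_000
        table = simulate(g, config_factory(n, seed=123))
        freq = sum(table.columns["X"]) / n
        se = math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(freq - 2 / 3) < 3 * se

    def test_zero_acceptance_exhausts_budget(self, config_factory):
        g = build_graph([
            NodeSpec("X", unit_uniform),
            NodeSpec("Keep", always_false, kind="selection"),
        ])
        cfg = config_factory(5, max_rejection_attempts=50)
        with pytest.raises(RejectionBudgetExceededError, match="0 samples"):
            simulate(g, cfg)

    def test_post_selection_distribution_total_variation(self, config_factory):
        """Empirical retained distribution vs the analytically normalized
        conditional: TV distance < 0.02 at n=10,000."""
        g = self.make_selection_graph(accept_ones_half_zeros)
        n = 10_000
        table = simulate(g, config_factory(n, seed=7))
        freq1 = sum(table.columns["X"]) / n
        tv = 0.5 * (abs(freq1 - 2 / 3) + abs((1 - freq1) - 1 / 3))
        assert tv < 0.02


class TestMissing:
    def make_graph(self, mask_func, mask_kwargs=None):
        return build_graph([
            NodeSpec("X", unit_uniform),
            NodeSpec("Mask", mask_func, mask_kwargs or {}),
            make_missing_node("X_obs", "X", "Mask"),
        ])

    def test_mask_always_true_all_sentinel(self, config_factory):
        g = self.make_graph(always_true)
        table = simulate(g, config_factory(10))
        assert all(v is MISSING for v in table.columns["X_obs"])

    def test_mask_always_false_identity(self, config_factory):
        g = self.make_graph(always_false)
        table = simulate(g, config_factory(10))
        assert table.columns["X_obs"] == table.columns["X"]

    def test_mcar_rate_calibrated(self, config_factory):
        q, n = 0.3, 10_000
        g = self.make_graph(bernoulli, {"p": q})
        table = simulate(g, config_factory(n, seed=42))
        frac = sum(v is MISSING for v in table.columns["X_obs"]) / n
        assert abs(frac - q) < 3 * math.sqrt(q * (1 - q) / n)

    def test_non_missing_entries_equal_underlying(self, config_factory):
        g = self.make_graph(bernoulli, {"p": 0.5})
        table = simulate(g, config_factory(500, seed=3))
        for x, x_obs in zip(table.columns["X"], table.columns["X_obs"]):
            assert x_obs is MISSING or x_obs == x


class TestStratify:
    def test_constant_label_single_stratum(self, config_factory):
        g = build_graph([
            NodeSpec("X", unit_uniform),
            NodeSpec("Grp", constant, {"value": "A"}, kind="stratify"),
        ])
        table = simulate(g, config_factory(50))
        out = stratify_rows(table, g)
        assert set(out.strata) == {"A"}
        assert out.strata["A"].n_rows == 50

    def test_sign_partition(self, config_factory):
        g = build_graph([
            NodeSpec("X", symmetric_uniform),
            NodeSpec("Grp", sign_label, {"x": NodeRef("X")}, kind="stratify"),
        ])
        n = 10_000
        table = simulate(g, config_factory(n, seed=9))
        out = stratify_rows(table, g)
        assert out.total_rows() == n
        assert all(x > 0 for x in out.strata["pos"].columns["X"])
        assert all(x <= 0 for x in out.strata["neg"].columns["X"])

    def test_three_labels_are_a_partition(self, config_factory):
        def label3(x):
            return "abc"[int(x * 3) % 3]

        g = build_graph([
            NodeSpec("X", unit_uniform),
            NodeSpec("Grp", label3, {"x": NodeRef("X")}, kind="stratify"),
        ])
        n = 3_000
        table = simulate(g, config_factory(n, seed=2))
        out = stratify_rows(table, g)
        sizes = {k: t.n_rows for k, t in out.strata.items()}
        assert sum(sizes.values()) == n
        pooled = sorted(
            x for t in out.strata.values() for x in t.columns["X"]
        )
        assert pooled == sorted(table.columns["X"])

    def test_stratify_node_not_a_column(self, config_factory):
        g = build_graph([
            NodeSpec("X", unit_uniform),
            NodeSpec("Grp", sign_label, {"x": NodeRef("X")}, kind="stratify"),
        ])
        table = simulate(g, config_factory(5))
        assert list(table.columns) == ["X"]

    @pytest.mark.parametrize(
        "label,expected",
        [("a b/c", "a_b_c"), (42, "42"), ("x", "x")],
    )
    def test_label_sanitization(self, label, expected):
        assert sanitize_label(label) == expected

    def test_unsanitizable_label(self):
        with pytest.raises(LabelError):
            sanitize_label("///")


class TestWriteCsv:
    def test_header_plus_rows(self, config_factory, tmp_path):
        g = build_graph([
            NodeSpec("A", constant, {"value": 1}),
            NodeSpec("B", constant, {"value": 2}),
        ])
        cfg = config_factory(3, csv_name="two_cols")
        path = write_csv(simulate(g, cfg), cfg)
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0] == "A,B"

    def test_missing_sentinel_becomes_empty_field(self, config_factory):
        g = build_graph([
            NodeSpec("X", constant, {"value": 5}),
            NodeSpec("Mask", always_true),
            make_missing_node("X_obs", "X", "Mask"),
        ])
        cfg = config_factory(2)
        path = write_csv(simulate(g, cfg), cfg)
        rows = list(csv.reader(path.open()))
        obs_col = rows[0].index("X_obs")
        assert all(row[obs_col] == "" for row in rows[1:])

    def test_coin_toss_round_trip(self, coin_graph, config_factory):
        cfg = config_factory(30, seed=1, csv_name="coin")
        table = simulate(coin_graph, cfg)
        path = write_csv(table, cfg)
        rows = list(csv.reader(path.open()))
        header, data = rows[0], rows[1:]
        seq_col = header.index("Sequence")
        assert [row[seq_col] for row in data] == table.columns["Sequence"]
        assert '"' not in path.read_text().splitlines()[1]  # unquoted strings

    def test_stratified_file_naming(self, config_factory, tmp_path):
        g = build_graph([
            NodeSpec("X", symmetric_uniform),
            NodeSpec("Grp", sign_label, {"x": NodeRef("X")}, kind="stratify"),
        ])
        cfg = config_factory(200, seed=4, csv_name="strat")
        table = simulate(g, cfg)
        out = stratify_rows(table, g)
        paths = {
            label: write_csv(sub, cfg, stratum_label=label)
            for label, sub in out.strata.items()
        }
        assert paths["pos"].name == "strat_pos.csv"
        assert paths["neg"].name == "strat_neg.csv"
        n_rows = sum(len(p.read_text().splitlines()) - 1 for p in paths.values())
        assert n_rows == 200

    def test_small_list_inlined_as_json(self, config_factory):
        g = build_graph([NodeSpec("V", constant, {"value": [1, 2, 3]})])
        cfg = config_factory(1)
        path = write_csv(simulate(g, cfg), cfg)
        rows = list(csv.reader(path.open()))
        assert rows[1][0] == "[1, 2, 3]"

    def test_large_array_goes_to_npy_sidecar(self, config_factory, tmp_path):
        big = np.arange(64 * 64, dtype=float).reshape(64, 64)
        g = build_graph([NodeSpec("Img", constant, {"value": big})])
        cfg = config_factory(1, csv_name="img")
        path = write_csv(simulate(g, cfg), cfg)
        cell = list(csv.reader(path.open()))[1][0]
        loaded = np.load(tmp_path / cell)
        assert np.array_equal(loaded, big)

    def test_large_sequence_set_goes_to_fasta_sidecar(self, config_factory,
                                                      tmp_path):
        seqs = SequenceSet(["ACGT" * 20 for _ in range(50)])  # 4,000 nt
        g = build_graph([NodeSpec("Rep", constant, {"value": seqs})])
        cfg = config_factory(1, csv_name="rep")
        path = write_csv(simulate(g, cfg), cfg)
        cell = list(csv.reader(path.open()))[1][0]
        from Bio import SeqIO
        records = list(SeqIO.parse(tmp_path / cell, "fasta"))
        assert len(records) == 50
        assert str(records[0].seq) == "ACGT" * 20
        assert records[0].id == "seq1"

    def test_custom_serializer_wins(self, config_factory):
        g = build_graph([NodeSpec("X", constant, {"value": 0.5})])
        cfg = config_factory(1, serializers={"X": lambda v: f"<{v}>"})
        path = write_csv(simulate(g, cfg), cfg)
        assert list(csv.reader(path.open()))[1][0] == "<0.5>"

    def test_byte_identical_reruns(self, coin_graph, tmp_path):
        from dagforge import SimulationConfig
        texts = []
        for sub in ("a", "b"):
            cfg = SimulationConfig(
                n_samples=40, seed=77, output_dir=tmp_path / sub, csv_name="c"
            )
            path = write_csv(simulate(coin_graph, cfg), cfg)
            texts.append(path.read_bytes())
        assert texts[0] == texts[1]
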