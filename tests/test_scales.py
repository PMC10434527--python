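"""Ingestion, completeness filtering, scoring, and reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bridgenet.exceptions import SchemaError, ValidationError
from bridgenet.scales import (
    NODE_IDS,
    Codebook,
    CodebookItem,
    ItemResponseTable,
    cronbach_alpha,
    default_codebook,
    descriptives,
    filter_complete,
    read_responses,
    recode_reverse,
    score_nodes,
)


class TestReadResponses:
    def test_round_trip(self, tmp_path, codebook, complete_items):
        path = tmp_path / "resp.csv"
        complete_items.to_csv(path, index=False)
        table = read_responses(str(path), codebook)
        assert table.n == 8
        assert list(table.values.columns) == codebook.item_ids

    def test_out_of_range_value_names_location(self, tmp_path, codebook, complete_items):
        complete_items.loc[2, "GAD3"] = 9
        path = tmp_path / "resp.csv"
        complete_items.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="GAD3"):
            read_responses(str(path), codebook)

    def test_missing_codebook_item_is_schema_error(self, tmp_path, codebook, complete_items):
        path = tmp_path / "resp.csv"
        complete_items.drop(columns=["PHQ9"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="PHQ9"):
            read_responses(str(path), codebook)

    def test_unknown_column_is_schema_error(self, tmp_path, codebook, complete_items):
        complete_items["EXTRA"] = 1
        path = tmp_path / "resp.csv"
        complete_items.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="EXTRA"):
            read_responses(str(path), codebook)

    def test_blank_cells_become_missing(self, tmp_path, codebook, complete_items):
        complete_items.loc[0, "TIPI1"] = np.nan
        path = tmp_path / "resp.csv"
        complete_items.to_csv(path, index=False)
        table = read_responses(str(path), codebook)
        assert table.values["TIPI1"].isna().sum() == 1

    def test_tsv_dialect(self, tmp_path, codebook, complete_items):
        path = tmp_path / "resp.tsv"
        complete_items.to_csv(path, index=False, sep="\t")
        assert read_responses(str(path), codebook).n == 8


class TestFilterComplete:
    def test_study_scale_counts(self, codebook):
        """536 submitted questionnaires with 29 incomplete leave 507 valid."""
        rng = np.random.default_rng(0)
        data = {
            it.item_id: rng.integers(it.min_value, it.max_value + 1, size=536).astype(float)
            for it in codebook.items
        }
        df = pd.DataFrame(data)
        incomplete_rows = rng.choice(536, size=29, replace=False)
        for r in incomplete_rows:
            cols = rng.choice(df.columns, size=rng.integers(1, 4), replace=False)
            df.loc[r, cols] = np.nan
        _, summary = filter_complete(ItemResponseTable(values=df, codebook=codebook))
        assert summary.n_submitted == 536
        assert summary.n_valid == 507
        assert round(summary.percent_valid, 2) == 94.59

    def test_all_complete_is_identity(self, codebook, complete_items):
        table = ItemResponseTable(values=complete_items.astype(float), codebook=codebook)
        kept, summary = filter_complete(table)
        assert summary.percent_valid == 100.0
        pd.testing.assert_frame_equal(kept.values, table.values)

    def test_all_incomplete_yields_empty(self, codebook, complete_items):
        df = complete_items.astype(float)
        df["TIPI1"] = np.nan
        kept, summary = filter_complete(ItemResponseTable(values=df, codebook=codebook))
        assert summary.n_valid == 0
        assert kept.n == 0
        with pytest.raises(Exception):
            score_nodes(kept)

    def test_idempotent(self, codebook, complete_items):
        df = complete_items.astype(float)
        df.loc[1, "PHQ2"] = np.nan
        once, s1 = filter_complete(ItemResponseTable(values=df, codebook=codebook))
        twice, s2 = filter_complete(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert s2.percent_valid == 100.0


class TestScoreNodes:
    @pytest.mark.parametrize(
        "direct,reverse,expected",
        [
            (7, 1, 7.0),  # recode 1 -> 8-1 = 7, mean(7, 7)
            (3, 5, 3.0),  # recode 5 -> 3, mean(3, 3)
            (4, 4, 4.0),
        ],
    )
    def test_dimension_recode_and_mean(self, codebook, direct, reverse, expected):
        # EXT pairs TIPI1 (direct) with TIPI6 (reverse-keyed)
        row = {it.item_id: it.min_value for it in codebook.items}
        row["TIPI1"], row["TIPI6"] = direct, reverse
        table = ItemResponseTable(
            values=pd.DataFrame([row], dtype=float), codebook=codebook
        )
        scores = score_nodes(table)
        assert scores.values.loc[0, "EXT"] == expected

    def test_symptom_items_pass_through(self, codebook):
        row = {it.item_id: it.min_value for it in codebook.items}
        row["GAD2"] = 2
        row["PHQ9"] = 3
        table = ItemResponseTable(values=pd.DataFrame([row], dtype=float), codebook=codebook)
        scores = score_nodes(table)
        assert scores.values.loc[0, "A2"] == 2
        assert scores.values.loc[0, "D9"] == 3

    def test_node_order_and_ranges(self, codebook, complete_items):
        table = ItemResponseTable(values=complete_items.astype(float), codebook=codebook)
        scores = score_nodes(table)
        assert tuple(scores.values.columns) == NODE_IDS
        assert scores.values[list(NODE_IDS[:5])].stack().between(1, 7).all()
        assert scores.values[list(NODE_IDS[5:])].isin([0, 1, 2, 3]).all().all()

    def test_incomplete_input_refused(self, codebook, complete_items):
        df = complete_items.astype(float)
        df.loc[0, "GAD1"] = np.nan
        with pytest.raises(ValidationError):
            score_nodes(ItemResponseTable(values=df, codebook=codebook))

    @settings(derandomize=True)
    @given(x=st.integers(min_value=1, max_value=7))
    def test_reverse_recode_is_involution(self, x):
        assert recode_reverse(recode_reverse(x, 1, 7), 1, 7) == x


class TestDescriptives:
    def test_matches_brute_force_per_column(self, likert_scores):
        table = descriptives(likert_scores)
        X = likert_scores.values
        for _, row in table.iterrows():
            col = X[row["node"]].to_numpy()
            assert row["mean"] == pytest.approx(col.sum() / len(col))
            m = col.sum() / len(col)
            sd = np.sqrt(((col - m) ** 2).sum() / (len(col) - 1))
            assert row["sd"] == pytest.approx(sd)

    def test_known_small_columns(self, codebook):
        rows = [{it.item_id: v for it in codebook.items} for v in (0, 1, 2, 3)]
        for r, v in zip(rows, (1, 2, 3, 4)):  # keep TIPI in range
            for it in codebook.items:
                if it.scale == "TIPI-C":
                    r[it.item_id] = v
        table = ItemResponseTable(values=pd.DataFrame(rows, dtype=float), codebook=codebook)
        desc = descriptives(score_nodes(table)).set_index("node")
        assert desc.loc["A1", "mean"] == 1.5
        assert desc.loc["A1", "sd"] == pytest.approx(1.29099, abs=1e-5)

    def test_constant_column_has_zero_sd(self, codebook):
        row = {it.item_id: 2 if it.scale != "TIPI-C" else 4 for it in codebook.items}
        table = ItemResponseTable(
            values=pd.DataFrame([row, row], dtype=float), codebook=codebook
        )
        desc = descriptives(score_nodes(table))
        assert (desc["sd"] == 0).all()
        assert desc.set_index("node").loc["A1", "mean"] == 2

    def test_single_row_refused(self, codebook, complete_items):
        table = ItemResponseTable(
            values=complete_items.iloc[:1].astype(float), codebook=codebook
        )
        with pytest.raises(ValidationError):
            descriptives(score_nodes(table))


class TestCronbachAlpha:
    def test_duplicated_columns_give_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 4, size=50).astype(float)
        X = np.column_stack([col] * 5)
        assert cronbach_alpha(X).alpha == pytest.approx(1.0)

    def test_spearman_brown_two_items(self):
        # equal-variance items with correlation 0.5 -> alpha = 2r/(1+r) = 2/3
        rng = np.random.default_rng(2)
        z = rng.standard_normal((20000, 2))
        x1 = z[:, 0]
        x2 = 0.5 * z[:, 0] + np.sqrt(1 - 0.25) * z[:, 1]
        res = cronbach_alpha(np.column_stack([x1, x2]))
        assert res.alpha == pytest.approx(2 / 3, abs=0.02)

    def test_hand_matrix_matches_formula(self):
        X = np.array([[0, 1, 2], [1, 1, 3], [2, 0, 1], [3, 2, 3]], dtype=float)
        k = 3
        item_vars = [X[:, j].var(ddof=1) for j in range(k)]
        total_var = X.sum(axis=1).var(ddof=1)
        expected = k / (k - 1) * (1 - sum(item_vars) / total_var)
        assert cronbach_alpha(X).alpha == pytest.approx(expected)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        X = rng.integers(0, 4, size=(60, 5)).astype(float)
        ours = cronbach_alpha(X).alpha
        theirs = pingouin.cronbach_alpha(data=pd.DataFrame(X))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10000, 5))
        assert cronbach_alpha(X).alpha < 0.1

    def test_degenerate_inputs_refused(self):
        with pytest.raises(ValidationError):
            cronbach_alpha(np.ones((10, 3)))  # zero total variance
        with pytest.raises(ValidationError):
            cronbach_alpha(np.zeros((10, 1)))  # single item


class TestCodebook:
    def test_default_covers_all_instruments(self, codebook):
        assert len(codebook.by_scale("TIPI-C")) == 10
        assert len(codebook.by_scale("GAD-7")) == 7
        assert len(codebook.by_scale("PHQ-9")) == 9
        dims = {it.dimension for it in codebook.by_scale("TIPI-C")}
        assert dims == set(NODE_IDS[:5])
        # one reverse-keyed item per dimension
        for d in NODE_IDS[:5]:
            pair = [it for it in codebook.by_scale("TIPI-C") if it.dimension == d]
            assert len(pair) == 2
            assert sum(it.reverse_keyed for it in pair) == 1

    def test_duplicate_ids_rejected(self):
        item = CodebookItem("X1", "GAD-7", False, 0, 3)
        with pytest.raises(SchemaError):
            Codebook((item, item))

    def test_yaml_round_trip(self, tmp_path, codebook):
        import yaml

        from bridgenet.scales import read_codebook

        recs = [
            {
                "item_id": it.item_id,
                "scale": it.scale,
                "dimension": it.dimension,
                "reverse_keyed": it.reverse_keyed,
                "min": it.min_value,
                "max": it.max_value,
            }
            for it in codebook.items
        ]
        path = tmp_path / "codebook.yaml"
        path.write_text(yaml.safe_dump(recs))
        loaded = read_codebook(str(path))
        assert loaded == codebook


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.lists(st.integers(min_value=0, max_value=3) | st.none(), min_size=4, max_size=4),
        min_size=1,
        max_size=12,
    )
)
def test_filter_complete_idempotent_property(data):
    cb = Codebook(tuple(CodebookItem(f"GAD{k}", "GAD-7", False, 0, 3) for k in range(1, 5)))
    df = pd.DataFrame(data, columns=cb.item_ids, dtype=float)
    once, _ = filter_complete(ItemResponseTable(values=df, codebook=cb))
    twice, s2 = filter_complete(once)
    pd.testing.assert_frame_equal(once.values, twice.values)
    assert s2.n_valid == s2.n_submitted
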