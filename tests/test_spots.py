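"""Spot normalization and the four-criterion differential filter, including
reconstruction of the reported differential tables from their printed means."""

import numpy as np
import pandas as pd
import pytest

from seedprotdev import reference_data as rd
from seedprotdev.simulate import SimConfig, generate_spot_table
from seedprotdev.spots import (
    GroupScheme,
    SpotTable,
    differential_filter,
    differential_results,
    direction_counts,
    group_stats,
    normalize_spot_percentages,
    signed_fold_change,
)


def make_table(values: dict, pI=5.0, MW=30000.0) -> SpotTable:
    df = pd.DataFrame(values)
    df.insert(0, "pI", pI)
    df.insert(1, "MW", MW)
    return SpotTable(df)


def scheme_2x2(table: SpotTable) -> GroupScheme:
    return GroupScheme.by_stage(table, "Sep18", "Sep25")


class TestNormalization:
    def test_single_spot_is_100(self):
        t = normalize_spot_percentages(make_table({"A_S_1": [7.0]}))
        assert t.data["A_S_1"].iloc[0] == pytest.approx(100.0)

    def test_one_to_three_ratio(self):
        t = normalize_spot_percentages(make_table({"A_S_1": [1.0, 3.0]}))
        assert t.data["A_S_1"].tolist() == pytest.approx([25.0, 75.0])

    def test_1267_equal_spots(self):
        t = normalize_spot_percentages(make_table({"A_S_1": np.ones(1267)}))
        assert t.data["A_S_1"].iloc[0] == pytest.approx(100 / 1267)

    def test_idempotent_and_sums_to_100(self):
        t = normalize_spot_percentages(make_table({"A_S_1": [2.0, 5.0, 13.0]}))
        again = normalize_spot_percentages(t)
        assert t.data.equals(again.data)
        assert t.data["A_S_1"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_column_names_the_column(self):
        with pytest.raises(ValueError, match="A_S_2"):
            normalize_spot_percentages(
                make_table({"A_S_1": [1.0, 1.0], "A_S_2": [0.0, 0.0]})
            )

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_table({"A_S_1": [1.0, -2.0]})


class TestFoldChange:
    def test_sign_convention(self):
        assert signed_fold_change(1.0, 4.0) == pytest.approx(4.0)
        assert signed_fold_change(4.0, 1.0) == pytest.approx(-4.0)
        assert signed_fold_change(2.0, 2.0) == pytest.approx(1.0)

    def test_zero_means(self):
        assert signed_fold_change(0.0, 1.0) == np.inf
        assert signed_fold_change(1.0, 0.0) == -np.inf
        assert np.isnan(signed_fold_change(0.0, 0.0))

    def test_antisymmetry(self):
        for m1, m2 in [(0.5, 1.7), (3.0, 0.2)]:
            assert signed_fold_change(m1, m2) == pytest.approx(
                -signed_fold_change(m2, m1)
            )


def _reconstruct(table, g1, g2, factor):
    """SpotTable/GroupScheme treating each printed cell mean as one replicate."""
    df = table[[*g1, *g2]].copy()
    df.columns = [c + "_1" for c in df.columns]
    df.insert(0, "pI", table["pI"])
    df.insert(1, "MW", table["MW"])
    sub_keys = ("Sumner", "Desirable") if factor == "timepoint" else ("Sep18", "Sep25")
    match = (lambda c, k: c.startswith(k)) if factor == "timepoint" else (
        lambda c, k: k in c
    )
    sub = {
        k: (
            tuple(c + "_1" for c in g1 if match(c, k)),
            tuple(c + "_1" for c in g2 if match(c, k)),
        )
        for k in sub_keys
    }
    scheme = GroupScheme(
        factor=factor,
        group1=tuple(c + "_1" for c in g1),
        group2=tuple(c + "_1" for c in g2),
        subgroups=sub,
    )
    return SpotTable(df, normalized=True), scheme


@pytest.fixture(scope="module")
def development_results():
    table, scheme = _reconstruct(
        rd.TABLE_DEVELOPMENT, rd.DEVELOPMENT_GROUP1, rd.DEVELOPMENT_GROUP2, "timepoint"
    )
    return differential_results(table, scheme)


@pytest.fixture(scope="module")
def cultivar_results():
    table, scheme = _reconstruct(
        rd.TABLE_CULTIVAR, rd.CULTIVAR_GROUP1, rd.CULTIVAR_GROUP2, "cultivar"
    )
    return differential_results(table, scheme)


class TestReportedTables:
    @pytest.mark.parametrize("spot,expected", [(1054, 4.4), (862, 2.2), (821, 3.2)])
    def test_development_fold_changes(self, development_results, spot, expected):
        assert round(development_results.loc[spot, "fold_change"], 1) == expected

    def test_cultivar_spot_966(self, cultivar_results):
        assert round(cultivar_results.loc[966, "fold_change"], 1) == 9.4

    def test_all_rows_close_to_printed_folds(
        self, development_results, cultivar_results
    ):
        """Recomputation from 3-decimal printed means matches the printed
        fold changes to within rounding propagation (cell means as small as
        0.003 shift a recomputed fold by up to ~0.25), with matching sign."""
        for res, ref in [
            (development_results, rd.TABLE_DEVELOPMENT),
            (cultivar_results, rd.TABLE_CULTIVAR),
        ]:
            diff = (res["fold_change"] - ref["fold_reported"]).abs()
            assert (diff <= 0.25).all()
            assert (np.sign(res["fold_change"]) == np.sign(ref["fold_reported"])).all()

    def test_direction_counts(self, development_results, cultivar_results):
        assert direction_counts(development_results, passing_only=False) == (9, 3)
        assert direction_counts(cultivar_results, passing_only=False) == (8, 3)

    def test_abundance_floor_cleared_by_every_row(self):
        floor = 0.25 * 100.0 / rd.N_SPOTS_REPORTED
        for ref, cells in [
            (rd.TABLE_DEVELOPMENT, rd.DEVELOPMENT_GROUP1 + rd.DEVELOPMENT_GROUP2),
            (rd.TABLE_CULTIVAR, rd.CULTIVAR_GROUP1 + rd.CULTIVAR_GROUP2),
        ]:
            assert (ref[cells].max(axis=1) >= floor).all()

    def test_subgroup_two_fold_criterion_holds(self, development_results):
        """Every reported development spot changes >= 2-fold within each
        cultivar individually (criterion 2)."""
        res = development_results
        for cv in ("Sumner", "Desirable"):
            folds = [
                abs(signed_fold_change(m1, m2))
                for m1, m2 in zip(res[f"{cv}_g1"], res[f"{cv}_g2"])
            ]
            assert min(folds) >= 2.0


class TestFilter:
    def test_identical_groups(self):
        t = normalize_spot_percentages(
            make_table(
                {
                    "S_Sep18_1": [1.0, 2.0],
                    "S_Sep18_2": [1.0, 2.0],
                    "S_Sep25_1": [1.0, 2.0],
                    "S_Sep25_2": [1.0, 2.0],
                }
            )
        )
        row = group_stats(t, GroupScheme.by_stage(t, "Sep18", "Sep25"), 0)
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_planted_spots_recovered(self):
        cfg = SimConfig(seed=7, n_spots=200, n_diff_spots=12, planted_fold=4.0,
                        noise_cv=0.1)
        table, truth = generate_spot_table(cfg)
        res = differential_filter(table, scheme_2x2(table))
        recovered = res.loc[truth["planted"], "passes"].sum()
        assert recovered >= 11
        # planted directions agree
        hit = res.index[res["passes"]]
        planted = truth.index[truth["planted"]]
        agree = (
            res.loc[hit.intersection(planted), "direction"]
            == truth.loc[hit.intersection(planted), "direction"]
        )
        assert agree.all()

    def test_zero_mean_group_flagged_not_passed(self):
        t = normalize_spot_percentages(
            make_table(
                {
                    "S_Sep18_1": [0.0, 2.0],
                    "S_Sep18_2": [0.0, 2.0],
                    "S_Sep25_1": [5.0, 2.0],
                    "S_Sep25_2": [5.0, 2.0],
                }
            )
        )
        res = differential_filter(t, GroupScheme.by_stage(t, "Sep18", "Sep25"))
        assert bool(res.loc[0, "zero_mean"])
        assert res.loc[0, "direction"] == "undefined"
        assert not res.loc[0, "passes"]

    def test_raising_fold_min_shrinks_pass_set(self):
        cfg = SimConfig(seed=3, n_spots=150, n_diff_spots=10, planted_fold=3.0)
        table, _ = generate_spot_table(cfg)
        scheme = scheme_2x2(table)
        pass2 = set(differential_filter(table, scheme, fold_min=2).query("passes").index)
        pass4 = set(differential_filter(table, scheme, fold_min=4).query("passes").index)
        assert pass4 <= pass2

    def test_invariant_to_spot_order_and_raw_rescaling(self):
        cfg = SimConfig(seed=9, n_spots=100, n_diff_spots=5)
        table, _ = generate_spot_table(cfg)
        scheme = scheme_2x2(table)
        base = differential_filter(table, scheme)["passes"]
        # shuffled spot order
        shuffled = SpotTable(
            table.data.sample(frac=1, random_state=0), normalized=True
        )
        resh = differential_filter(shuffled, scheme)["passes"].sort_index()
        assert resh.equals(base.sort_index())
        # uniform rescaling of one replicate column before normalization
        raw = table.data.copy()
        raw["Sumner_Sep18_1"] *= 37.5
        rescaled = normalize_spot_percentages(SpotTable(raw))
        assert differential_filter(rescaled, scheme)["passes"].equals(base)

    def test_alternate_group_criterion(self):
        cfg = SimConfig(
            seed=2,
            n_spots=100,
            n_diff_spots=6,
            groups=(
                ("Sumner", "Sep18", 2),
                ("Sumner", "Sep25", 2),
                ("Desirable", "Sep18", 2),
                ("Desirable", "Sep25", 2),
            ),
        )
        table, truth = generate_spot_table(cfg)
        scheme = scheme_2x2(table)
        res = differential_filter(table, scheme, alt_scheme=scheme)
        # re-confirming with the same groups cannot change the outcome
        assert res["passes"].equals(differential_filter(table, scheme)["passes"])
        assert "crit_alt" in res


def test_group_scheme_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        GroupScheme(factor="x", group1=("a",), group2=("a",))
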