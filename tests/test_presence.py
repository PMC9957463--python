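"""Acceptance rule, presence-matrix union merging, GO ranking and the
early-versus-late trend test."""

import numpy as np
import pandas as pd
import pytest

from seedprotdev.presence import (
    accept_protein,
    build_presence_matrix,
    go_trend_test,
    protein_diversity,
    rank_go_terms,
)
from seedprotdev.simulate import SimConfig, generate_detections

STAGES = ["Aug21", "Aug28", "Sep04", "Sep11", "Sep18", "Sep25"]


def record(pid="P1", cultivar="Sumner", stage="Sep18", rep=1, n=3, score=60.0, p=0.01):
    return {
        "protein_id": pid,
        "cultivar": cultivar,
        "stage": stage,
        "replicate": rep,
        "n_peptides": n,
        "score": score,
        "p_value": p,
    }


@pytest.mark.parametrize(
    "n,score,p,expected",
    [
        (2, 30, 0.01, True),   # peptide-count branch
        (1, 41, 0.04, True),   # score branch (> 40 strict)
        (1, 39, 0.001, False),
        (5, 100, 0.05, False),  # p not strictly below 0.05
        (2, 0, 0.049, True),
        (1, 40, 0.01, False),   # score must exceed 40
    ],
)
def test_acceptance_rule(n, score, p, expected):
    assert accept_protein(n, score, p) is expected


class TestPresenceMatrix:
    def test_single_replicate_single_column(self):
        det = pd.DataFrame([record(stage="Sep18", cultivar="Sumner")])
        m = build_presence_matrix(det, STAGES)
        assert m.loc["P1", ("Sumner", "Sep18")]
        assert m.loc["P1"].sum() == 1

    def test_union_merge_is_idempotent_and_order_independent(self):
        rows = [
            record(rep=1, n=1, score=20, p=0.5),   # fails
            record(rep=2, n=2, score=10, p=0.01),  # passes
        ]
        m1 = build_presence_matrix(pd.DataFrame(rows), STAGES)
        m2 = build_presence_matrix(pd.DataFrame(rows[::-1] + rows), STAGES)
        assert m1.equals(m2)
        assert m1.loc["P1", ("Sumner", "Sep18")]

    def test_unknown_stage_label_errors(self):
        det = pd.DataFrame([record(stage="Oct09")])
        with pytest.raises(ValueError, match="Oct09"):
            build_presence_matrix(det, STAGES)

    def test_adding_records_is_monotone(self):
        base = pd.DataFrame([record()])
        more = pd.DataFrame([record(), record(pid="P2", stage="Aug21")])
        c1 = protein_diversity(build_presence_matrix(base, STAGES))
        c2 = protein_diversity(build_presence_matrix(more, STAGES))
        assert (c2.loc[c1.index] >= c1).all()

    def test_planted_trajectories(self):
        cfg = SimConfig(seed=13, n_proteins=30)
        det, ann, truth = generate_detections(cfg)
        m = build_presence_matrix(det, list(cfg.stages))
        early, late = truth["early_stages"], [s for s in cfg.stages if s not in truth["early_stages"]]
        for pid in truth["early_only_proteins"]:
            for cv in cfg.cultivars:
                assert all(m.loc[pid, (cv, s)] for s in early)
                assert not any(m.loc[pid, (cv, s)] for s in late)
        for pid in truth["stable_proteins"]:
            assert m.loc[pid].all()


class TestGoRanking:
    def test_protein_counts_once_per_term(self):
        det = pd.DataFrame([record()])
        ann = pd.DataFrame(
            [
                {"protein_id": "P1", "go_id": "GO:1"},
                {"protein_id": "P1", "go_id": "GO:2"},
            ]
        )
        r = rank_go_terms(build_presence_matrix(det, STAGES), ann)
        assert set(r["go_id"]) == {"GO:1", "GO:2"}
        assert (r["max_count"] == 1).all()

    def test_min_count_threshold(self):
        det = pd.DataFrame(
            [record(pid=f"P{i}") for i in range(12)]
            + [record(pid="Q1", stage="Aug21")]
        )
        ann = pd.DataFrame(
            [{"protein_id": f"P{i}", "go_id": "GO:big"} for i in range(12)]
            + [{"protein_id": "Q1", "go_id": "GO:small"}]
        )
        r = rank_go_terms(build_presence_matrix(det, STAGES), ann, min_count=10)
        assert r["go_id"].tolist() == ["GO:big"]

    def test_empty_annotations(self):
        det = pd.DataFrame([record()])
        r = rank_go_terms(build_presence_matrix(det, STAGES), pd.DataFrame(columns=["protein_id", "go_id"]))
        assert r.empty


class TestGoTrend:
    def _matrix(self, counts_early, counts_late):
        """Build a matrix+annotation with given per-cell counts for GO:T."""
        rows = []
        n = max(counts_early + counts_late)
        for i, stage in enumerate(STAGES):
            k = (counts_early if i < 3 else counts_late)[0]
            for cv in ("Sumner", "Desirable"):
                for j in range(k):
                    rows.append(record(pid=f"P{j}", cultivar=cv, stage=stage))
        det = pd.DataFrame(rows)
        ann = pd.DataFrame([{"protein_id": f"P{j}", "go_id": "GO:T"} for j in range(n)])
        return build_presence_matrix(det, STAGES), ann

    def test_degenerate_separation_flagged_decreasing(self):
        m, ann = self._matrix([4], [0])
        res = go_trend_test(m, ann, STAGES[:3], STAGES[3:])
        row = res.iloc[0]
        assert row["flagged"] and row["direction"] == "decreasing"
        assert np.isinf(row["fold_change"])
        assert row["p_value"] == 0.0

    def test_identical_counts_not_flagged(self):
        m, ann = self._matrix([3], [3])
        res = go_trend_test(m, ann, STAGES[:3], STAGES[3:])
        assert not res.iloc[0]["flagged"]
        assert res.iloc[0]["p_value"] == 1.0

    def test_flagged_terms_satisfy_thresholds(self):
        cfg = SimConfig(seed=17, n_proteins=40)
        det, ann, truth = generate_detections(cfg)
        m = build_presence_matrix(det, list(cfg.stages))
        res = go_trend_test(m, ann, list(cfg.stages[:3]), list(cfg.stages[3:]))
        flagged = res[res["flagged"]]
        assert (flagged["p_value"] < 0.05).all()
        assert (flagged["fold_change"] > 2).all()

    def test_planted_trend_terms_recovered_exactly(self):
        cfg = SimConfig(seed=19, n_proteins=40)
        det, ann, truth = generate_detections(cfg)
        m = build_presence_matrix(det, list(cfg.stages))
        res = go_trend_test(m, ann, list(cfg.stages[:3]), list(cfg.stages[3:]))
        assert set(res.loc[res["flagged"], "go_id"]) == set(truth["trend_terms"])

    def test_overlapping_stage_sets_rejected(self):
        m, ann = self._matrix([1], [1])
        with pytest.raises(ValueError, match="overlap"):
            go_trend_test(m, ann, STAGES[:3], STAGES[2:])
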