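"""Presence-absence proteomics across developmental stages and GO trends.

Shotgun (gel-free, label-free) identification of a developing seed yields,
per protein and sample, a peptide count, a search-engine score and an
identification p-value. A protein is *accepted* in a sample when it has at
least two matching peptides or a score above 40, with p < 0.05. Replicate
and injection results within one (cultivar, stage) cell are union-merged,
because low-abundance proteins are detected stochastically; the result is a
boolean presence matrix of proteins by (cultivar, stage).

GO terms annotated to the present proteins are ranked by the highest number
of representative proteins in any single (cultivar, stage) cell, and a
simple early-versus-late trend test flags terms whose per-cell protein
counts change more than two-fold between the first and last stages with a
two-sided t-test p below 0.05 (e.g. histone terms that fade as chromatin
compacts during seed maturation).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

DETECTION_COLUMNS = [
    "protein_id",
    "cultivar",
    "stage",
    "replicate",
    "n_peptides",
    "score",
    "p_value",
]


def accept_protein(n_peptides: int, score: float, p_value: float) -> bool:
    """Acceptance rule for one identification record.

    True iff (>= 2 matching peptides OR score > 40) AND p-value < 0.05.
    """
    return (n_peptides >= 2 or score > 40) and p_value < 0.05


def build_presence_matrix(
    records: pd.DataFrame, stage_order: list[str]
) -> pd.DataFrame:
    """Union-merge accepted records into a protein x (cultivar, stage) matrix.

    *records* needs the columns ``protein_id, cultivar, stage, replicate,
    n_peptides, score, p_value``. Columns of the result are a MultiIndex
    (cultivar, stage) with stages in *stage_order*; a stage label outside
    *stage_order* is an error. A protein is present in a cell when at least
    one of its records there passes :func:`accept_protein`.
    """
    missing = [c for c in DETECTION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"detection table missing columns {missing}")
    unknown = sorted(set(records["stage"]) - set(stage_order))
    if unknown:
        raise ValueError(f"unknown stage labels {unknown}; expected {stage_order}")

    ok = records[
        [accept_protein(n, s, p)
         for n, s, p in zip(records["n_peptides"], records["score"], records["p_value"])]
    ]
    cultivars = sorted(records["cultivar"].unique())
    columns = pd.MultiIndex.from_tuples(
        [(cv, st) for cv in cultivars for st in stage_order],
        names=["cultivar", "stage"],
    )
    proteins = sorted(records["protein_id"].unique())
    matrix = pd.DataFrame(False, index=proteins, columns=columns)
    present = ok.groupby(["protein_id", "cultivar", "stage"]).size()
    for (pid, cv, st) in present.index:
        matrix.loc[pid, (cv, st)] = True
    return matrix


def protein_diversity(matrix: pd.DataFrame) -> pd.Series:
    """Number of distinct proteins present per (cultivar, stage) column."""
    return matrix.sum(axis=0)


def rank_go_terms(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    min_count: int = 0,
) -> pd.DataFrame:
    """Rank GO terms by their highest per-cell count of present proteins.

    *annotations* has columns ``protein_id, go_id`` (an ``aspect`` column is
    carried through if given). Each protein contributes once to every term
    it is annotated with. Terms whose maximum count over the (cultivar,
    stage) cells is below *min_count* are dropped. Result: one row per term
    with the per-cell counts, ``max_count``, and ``rank`` (1 = highest).
    """
    if annotations.empty:
        return pd.DataFrame(columns=["go_id", "max_count", "rank"])
    ann = annotations[annotations["protein_id"].isin(matrix.index)]
    rows = {}
    for go_id, grp in ann.groupby("go_id"):
        proteins = grp["protein_id"].unique()
        rows[go_id] = matrix.loc[matrix.index.intersection(proteins)].sum(axis=0)
    counts = pd.DataFrame(rows).T
    counts.index.name = "go_id"
    counts["max_count"] = counts.max(axis=1)
    counts = counts[counts["max_count"] >= min_count]
    counts = counts.sort_values("max_count", ascending=False)
    counts["rank"] = np.arange(1, len(counts) + 1)
    return counts.reset_index()


def _trend_ttest(early: np.ndarray, late: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(stats.ttest_ind(early, late).pvalue)
    if not np.isfinite(p):
        # both groups constant: equal -> no evidence, separated -> sentinel
        p = 1.0 if np.mean(early) == np.mean(late) else 0.0
    return p


def go_trend_test(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    early_stages: list[str],
    late_stages: list[str],
    alpha: float = 0.05,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Early-versus-late trend in per-cell protein counts, per GO term.

    For each term, the number of annotated present proteins in every
    (stage, cultivar) cell forms the samples: with 3 early and 3 late
    stages over 2 cultivars, n = 6 per side. A term is ``flagged`` when the
    two-sided t-test p-value is below *alpha* and the fold change of the
    means exceeds *fold_min* (a zero mean on one side gives an infinite
    fold, which passes). Terms absent everywhere are skipped.
    """
    if set(early_stages) & set(late_stages):
        raise ValueError("early and late stage sets overlap")
    if not early_stages or not late_stages:
        raise ValueError("early and late stage sets must be non-empty")
    cultivars = matrix.columns.get_level_values("cultivar").unique()
    rows = []
    ann = annotations[annotations["protein_id"].isin(matrix.index)]
    for go_id, grp in ann.groupby("go_id"):
        sub = matrix.loc[matrix.index.intersection(grp["protein_id"].unique())]
        early = np.array(
            [sub[(cv, st)].sum() for st in early_stages for cv in cultivars
             if (cv, st) in matrix.columns]
        , dtype=float)
        late = np.array(
            [sub[(cv, st)].sum() for st in late_stages for cv in cultivars
             if (cv, st) in matrix.columns]
        , dtype=float)
        if early.sum() == 0 and late.sum() == 0:
            continue
        em, lm = float(early.mean()), float(late.mean())
        if em == 0 or lm == 0:
            fold = float("inf")
        else:
            fold = max(em, lm) / min(em, lm)
        p = _trend_ttest(early, late)
        flagged = (p < alpha) and (fold > fold_min)
        rows.append(
            {
                "go_id": go_id,
                "early_mean": em,
                "late_mean": lm,
                "fold_change": fold,
                "p_value": p,
                "direction": "decreasing" if em > lm else (
                    "increasing" if lm > em else "flat"),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["go_id", "early_mean", "late_mean", "fold_change",
                 "p_value", "direction", "flagged"],
    )
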