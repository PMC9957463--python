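"""Spot-percentage normalization and the differential-accumulation filter
for 2-D gel spot tables.

A silver-stained 2-D gel is quantified as a table of spots (id, pI, MW) with
one intensity column per replicate gel. Intensities are made comparable
across gels as *spot percentages*: each spot's background-subtracted
integrated density as a percentage of the total density of all spots on that
gel, so every replicate column sums to 100.

The differential filter reproduces a conservative multi-criterion rule used
in comparative gel studies of developing seeds. With a 2 cultivars x 2 time
points design (2 replicate gels per cell), a spot is differentially
accumulated between the two levels of one factor when:

1. the pooled means (n = 4 per side, pooling the other factor) differ by at
   least two-fold with a t-test p-value below 0.05;
2. the two-fold change also holds within each level of the other factor
   individually (n = 2 per side);
3. the highest group-mean spot percentage is at least one-fourth of the
   mean spot percentage of all spots on the gel (an abundance floor that
   removes near-background spots);
4. optionally, criteria 1-2 are re-confirmed after substituting an
   alternate replicate group (a robustness check against a single
   anomalous sample group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

META_COLUMNS = ("pI", "MW")


def parse_replicate_label(label: str) -> tuple[str, str, str]:
    """Split a replicate column name ``<cultivar>_<stage>_<rep>``."""
    parts = label.split("_")
    if len(parts) < 3:
        raise ValueError(
            f"replicate column {label!r} does not follow <cultivar>_<stage>_<rep>"
        )
    return parts[0], "_".join(parts[1:-1]), parts[-1]


@dataclass
class SpotTable:
    """A spot quantification table.

    ``data`` holds one row per spot (index = spot id) with ``pI`` and ``MW``
    metadata columns followed by one intensity column per replicate named
    ``<cultivar>_<stage>_<rep>``. ``normalized`` records whether intensity
    columns are spot percentages (each summing to 100) or raw densities.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        for col in META_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"spot table missing {col!r} column")
        for col in self.replicate_columns:
            parse_replicate_label(col)
        if (self.data[self.replicate_columns] < 0).any().any():
            bad = (
                (self.data[self.replicate_columns] < 0)
                .any(axis=0)
                .pipe(lambda s: s[s].index.tolist())
            )
            raise ValueError(f"negative intensities in columns {bad}")

    @property
    def replicate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def n_spots(self) -> int:
        return len(self.data)

    def replicates_for(self, cultivar: str | None = None, stage: str | None = None) -> list[str]:
        cols = []
        for c in self.replicate_columns:
            cv, st, _ = parse_replicate_label(c)
            if (cultivar is None or cv == cultivar) and (stage is None or st == stage):
                cols.append(c)
        return cols

    @classmethod
    def read_csv(cls, path, normalized: bool = False) -> "SpotTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df, normalized=normalized)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="spot_id")


def normalize_spot_percentages(table: SpotTable) -> SpotTable:
    """Scale every replicate column so its spots sum to 100.

    Idempotent; raises on an all-zero replicate column, naming it.
    """
    df = table.data.copy()
    for col in table.replicate_columns:
        total = df[col].sum()
        if total <= 0:
            raise ValueError(f"replicate column {col!r} has zero total intensity")
        df[col] = df[col] * (100.0 / total)
    return SpotTable(df, normalized=True)


@dataclass(frozen=True)
class GroupScheme:
    """Two groups of replicate columns, partitioned into matched subgroups.

    For a time-point comparison the groups are the two stages and the
    subgroups are the cultivars (and vice versa for a cultivar comparison):
    the data from both levels of the other factor are included when
    comparing, while criterion 2 is checked per subgroup.
    """

    factor: str
    group1: tuple[str, ...]
    group2: tuple[str, ...]
    #: subgroup name -> (columns of group1, columns of group2)
    subgroups: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if set(self.group1) & set(self.group2):
            raise ValueError("group1 and group2 overlap")
        for name, (g1, g2) in self.subgroups.items():
            if not g1 or not g2:
                raise ValueError(f"subgroup {name!r} empty on one side")

    @classmethod
    def by_stage(cls, table: SpotTable, stage1: str, stage2: str) -> "GroupScheme":
        """Stage1 vs stage2, pooling cultivars; subgroups = cultivars."""
        cultivars = sorted({parse_replicate_label(c)[0] for c in table.replicate_columns})
        sub = {
            cv: (
                tuple(table.replicates_for(cultivar=cv, stage=stage1)),
                tuple(table.replicates_for(cultivar=cv, stage=stage2)),
            )
            for cv in cultivars
        }
        return cls(
            factor="timepoint",
            group1=tuple(table.replicates_for(stage=stage1)),
            group2=tuple(table.replicates_for(stage=stage2)),
            subgroups=sub,
        )

    @classmethod
    def by_cultivar(
        cls, table: SpotTable, cultivar1: str, cultivar2: str
    ) -> "GroupScheme":
        """Cultivar1 vs cultivar2, pooling stages; subgroups = stages."""
        stages = sorted({parse_replicate_label(c)[1] for c in table.replicate_columns})
        sub = {
            st: (
                tuple(table.replicates_for(cultivar=cultivar1, stage=st)),
                tuple(table.replicates_for(cultivar=cultivar2, stage=st)),
            )
            for st in stages
            if table.replicates_for(cultivar=cultivar1, stage=st)
            and table.replicates_for(cultivar=cultivar2, stage=st)
        }
        return cls(
            factor="cultivar",
            group1=tuple(table.replicates_for(cultivar=cultivar1)),
            group2=tuple(table.replicates_for(cultivar=cultivar2)),
            subgroups=sub,
        )


def signed_fold_change(mean1: float, mean2: float) -> float:
    """Signed ratio of group2 relative to group1.

    >= +1 when group2 is higher (ratio), <= -1 when lower (negated inverse
    ratio); +-inf when one mean is zero, NaN when both are.
    """
    if mean1 == 0 and mean2 == 0:
        return float("nan")
    if mean1 == 0:
        return float("inf")
    if mean2 == 0:
        return float("-inf")
    r = mean2 / mean1
    return r if r >= 1 else -1.0 / r


def _ttest_rows(g1: np.ndarray, g2: np.ndarray, welch: bool = False) -> np.ndarray:
    """Row-wise two-sided two-sample t-test p-values with degenerate handling.

    Zero variance in both groups yields p = 1 when the means are equal and
    the p = 0 sentinel when they are perfectly separated.
    """
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(g1, g2, axis=1, equal_var=not welch)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(g1.mean(axis=1), g2.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def differential_results(
    table: SpotTable,
    scheme: GroupScheme,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-spot group statistics for *scheme* (no filtering).

    Columns: subgroup means per side (``<name>_g1`` / ``<name>_g2``), pooled
    ``mean1``/``mean2``, signed ``fold_change``, ``p_value``, BH-adjusted
    ``p_bh``, and ``direction`` (up = higher in group2).
    """
    if not table.normalized:
        raise ValueError("spot table must be normalized to spot percentages first")
    df = table.data
    g1 = df[list(scheme.group1)].to_numpy(float)
    g2 = df[list(scheme.group2)].to_numpy(float)
    out = pd.DataFrame(index=df.index)
    out["pI"] = df["pI"]
    out["MW"] = df["MW"]
    for name, (c1, c2) in scheme.subgroups.items():
        out[f"{name}_g1"] = df[list(c1)].mean(axis=1)
        out[f"{name}_g2"] = df[list(c2)].mean(axis=1)
    out["mean1"] = g1.mean(axis=1)
    out["mean2"] = g2.mean(axis=1)
    out["fold_change"] = [
        signed_fold_change(m1, m2) for m1, m2 in zip(out["mean1"], out["mean2"])
    ]
    out["p_value"] = _ttest_rows(g1, g2, welch=welch)
    out["p_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    # a zero group mean leaves the ratio undefined: flagged, not propagated
    out["zero_mean"] = ~np.isfinite(out["fold_change"])
    out["direction"] = np.where(
        out["zero_mean"],
        "undefined",
        np.where(out["fold_change"] >= 0, "up", "down"),
    )
    return out


def group_stats(
    table: SpotTable, scheme: GroupScheme, spot_id, welch: bool = False
) -> pd.Series:
    """Statistics of a single spot under *scheme* (row of
    :func:`differential_results`)."""
    res = differential_results(table, scheme, welch=welch)
    if spot_id not in res.index:
        raise KeyError(f"spot {spot_id!r} not in table")
    return res.loc[spot_id]


def differential_filter(
    table: SpotTable,
    scheme: GroupScheme,
    fold_min: float = 2.0,
    alpha: float = 0.05,
    floor_frac: float = 0.25,
    alt_scheme: GroupScheme | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Apply the four-criterion differential-accumulation filter.

    Returns :func:`differential_results` augmented with boolean columns
    ``crit_fold_p`` (pooled fold and p), ``crit_subgroups`` (fold within
    every subgroup), ``crit_floor`` (abundance floor), optionally
    ``crit_alt`` (criteria 1-2 under *alt_scheme*), and ``passes``.
    Display columns ``fold_change_1dp`` and ``p_value_3dp`` round to the
    precision customarily reported.
    """
    res = differential_results(table, scheme, welch=welch)
    fc = res["fold_change"].abs()
    res["crit_fold_p"] = (
        np.isfinite(res["fold_change"]) & (fc >= fold_min) & (res["p_value"] < alpha)
    )

    sub_ok = pd.Series(True, index=res.index)
    for name in scheme.subgroups:
        sub_fc = np.array(
            [
                signed_fold_change(m1, m2)
                for m1, m2 in zip(res[f"{name}_g1"], res[f"{name}_g2"])
            ]
        )
        sub_ok &= pd.Series(
            np.isfinite(sub_fc) & (np.abs(sub_fc) >= fold_min), index=res.index
        )
    res["crit_subgroups"] = sub_ok

    floor = floor_frac * 100.0 / table.n_spots
    cell_cols = [f"{name}_g{i}" for name in scheme.subgroups for i in (1, 2)]
    res["crit_floor"] = res[cell_cols].max(axis=1) >= floor

    res["passes"] = res["crit_fold_p"] & res["crit_subgroups"] & res["crit_floor"]
    if alt_scheme is not None:
        alt = differential_filter(
            table, alt_scheme, fold_min=fold_min, alpha=alpha,
            floor_frac=floor_frac, welch=welch,
        )
        res["crit_alt"] = alt["crit_fold_p"] & alt["crit_subgroups"]
        res["passes"] &= res["crit_alt"]

    res["fold_change_1dp"] = res["fold_change"].round(1)
    res["p_value_3dp"] = res["p_value"].round(3)
    return res


def direction_counts(results: pd.DataFrame, passing_only: bool = True) -> tuple[int, int]:
    """Counts of (up, down) spots by the sign of the fold change."""
    sel = results[results["passes"]] if passing_only and "passes" in results else results
    n_up = int((sel["fold_change"] > 0).sum())
    n_down = int((sel["fold_change"] < 0).sum())
    return n_up, n_down
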