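"""Item-level questionnaire data: validation, descriptives and group tests.

The central container is :class:`ItemDataset`, a subjects-by-items table of
PHQ-9 depression items (ordinal, 0-3) and intolerance-of-uncertainty
dimension scores (prospective anxiety ``AA`` and inhibitory anxiety ``IA``,
continuous on 1-5), with an optional two-level group label (e.g.
urban/rural) and numeric covariates (age, gender).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PHQ_ITEMS = tuple(f"PHQ{i}" for i in range(1, 10))
IU_ITEMS = ("AA", "IA")
DEFAULT_ITEMS = PHQ_ITEMS + IU_ITEMS


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ValidationError(ValueError):
    """A value violates the instrument's range constraints."""


@dataclass
class ItemDataset:
    """Validated subjects x items matrix with group labels and covariates.

    PHQ columns must contain only the integers 0-3; ``AA``/``IA`` columns
    must lie in [1, 5].  ``group`` (if present) is a string label per
    subject; ``covariates`` holds numeric columns such as age or 0/1 gender.
    """

    values: pd.DataFrame
    group: pd.Series | None = None
    covariates: pd.DataFrame | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self._validate()

    # -- basic protocol ------------------------------------------------
    @property
    def item_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return self.n_subjects

    def group_levels(self) -> list[str]:
        if self.group is None:
            return []
        return sorted(self.group.unique())

    def subset(self, mask: np.ndarray) -> "ItemDataset":
        """Row-subset (boolean mask or integer indexer), resetting the index."""
        vals = self.values.iloc[mask].reset_index(drop=True)
        grp = None if self.group is None else self.group.iloc[mask].reset_index(drop=True)
        cov = (
            None
            if self.covariates is None
            else self.covariates.iloc[mask].reset_index(drop=True)
        )
        return ItemDataset(vals, grp, cov, n_dropped=0)

    def split_groups(self) -> dict[str, "ItemDataset"]:
        if self.group is None:
            raise ValueError("dataset has no group labels")
        levels = self.group_levels()
        if len(levels) != 2:
            raise ValueError(f"expected exactly two group levels, got {levels}")
        return {
            lev: self.subset(np.flatnonzero((self.group == lev).to_numpy()))
            for lev in levels
        }

    def select_items(self, items: list[str]) -> "ItemDataset":
        missing = [c for c in items if c not in self.values.columns]
        if missing:
            raise SchemaError(f"unknown items: {missing}")
        return ItemDataset(
            self.values[items].copy(),
            None if self.group is None else self.group.copy(),
            None if self.covariates is None else self.covariates.copy(),
        )

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("missing values remain after listwise deletion")
        for col in self.values.columns:
            x = self.values[col].to_numpy()
            if col in PHQ_ITEMS:
                bad = ~np.isin(x, (0, 1, 2, 3))
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise ValidationError(
                        f"column {col!r} row {row}: value {x[bad][0]!r} outside {{0,1,2,3}}"
                    )
            elif col in IU_ITEMS:
                bad = (x < 1) | (x > 5)
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise ValidationError(
                        f"column {col!r} row {row}: value {x[bad][0]!r} outside [1, 5]"
                    )
        if self.group is not None and len(self.group) != len(self.values):
            raise ValidationError("group labels length mismatch")
        if self.covariates is not None and len(self.covariates) != len(self.values):
            raise ValidationError("covariate length mismatch")


def read_item_table(
    path,
    schema: dict[str, str] | None = None,
    group_column: str | None = None,
    covariate_columns: list[str] | None = None,
) -> ItemDataset:
    """Read a subjects-by-items CSV into a validated :class:`ItemDataset`.

    ``schema`` maps canonical item labels (``PHQ1``..``PHQ9``, ``AA``,
    ``IA``) to CSV column names; by default columns are expected under the
    canonical names.  Rows with any missing mapped value are dropped
    listwise; the count is logged and recorded on the dataset.
    """
    df = pd.read_csv(path)
    schema = schema or {}
    mapping = {canon: schema.get(canon, canon) for canon in DEFAULT_ITEMS}
    present = {canon: col for canon, col in mapping.items() if col in df.columns}
    missing_required = [
        canon for canon in PHQ_ITEMS if mapping[canon] not in df.columns
    ]
    if missing_required:
        raise SchemaError(
            f"missing PHQ columns in {path}: "
            + ", ".join(mapping[c] for c in missing_required)
        )
    used = [present[c] for c in present]
    extra = []
    if group_column is not None:
        if group_column not in df.columns:
            raise SchemaError(f"group column {group_column!r} not found")
        extra.append(group_column)
    for c in covariate_columns or []:
        if c not in df.columns:
            raise SchemaError(f"covariate column {c!r} not found")
        extra.append(c)

    sub = df[used + extra]
    keep = ~sub.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_item_table: dropped %d rows with missing values", n_dropped)
    sub = sub.loc[keep].reset_index(drop=True)

    values = pd.DataFrame({canon: sub[col] for canon, col in present.items()})
    values = values[[c for c in DEFAULT_ITEMS if c in values.columns]].astype(float)
    group = sub[group_column].astype(str) if group_column else None
    if group is not None:
        group = group.reset_index(drop=True)
        group.name = "group"
    cov = None
    if covariate_columns:
        cov = sub[covariate_columns].astype(float).reset_index(drop=True)
    ds = ItemDataset(values, group, cov, n_dropped=n_dropped)
    return ds


# -- descriptives ------------------------------------------------------

@dataclass
class DescriptiveRow:
    """Mean, sample SD, moment skewness and excess kurtosis for one item."""

    item: str
    group: str | None
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    defined: bool = True


def describe_items(data: ItemDataset, by_group: bool = False) -> list[DescriptiveRow]:
    """Per-item descriptives: mean, sample SD (n-1), moment skewness
    g1 = m3/m2^(3/2) and excess kurtosis g2 = m4/m2^2 - 3 with 1/n central
    moments.  Constant columns get NaN skew/kurtosis flagged undefined.
    """
    if by_group:
        groups = data.split_groups()
    else:
        groups = {None: data}
    rows: list[DescriptiveRow] = []
    for gname, ds in groups.items():
        if ds.n_subjects < 3:
            raise ValueError("need at least 3 subjects per group for descriptives")
        for item in ds.item_labels:
            x = ds.values[item].to_numpy(dtype=float)
            m = float(np.mean(x))
            sd = float(np.std(x, ddof=1))
            if sd == 0.0:
                rows.append(DescriptiveRow(item, gname, m, sd, np.nan, np.nan, False))
                continue
            g1 = float(stats.skew(x, bias=True))
            g2 = float(stats.kurtosis(x, fisher=True, bias=True))
            rows.append(DescriptiveRow(item, gname, m, sd, g1, g2))
    return rows


def descriptives_frame(rows: list[DescriptiveRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "item": r.item,
                "group": r.group,
                "mean": r.mean,
                "sd": r.sd,
                "skewness": r.skewness,
                "kurtosis": r.kurtosis,
            }
            for r in rows
        ]
    )


# -- depression prevalence --------------------------------------------

def phq_total_and_prevalence(
    data: ItemDataset, cutoff: int = 8
) -> tuple[pd.Series, pd.DataFrame]:
    """PHQ-9 totals and per-group depressed/not counts at ``total >= cutoff``.

    Returns ``(totals, counts)`` where ``counts`` is a groups x
    {depressed, not_depressed} table (a single row labelled 'all' when the
    dataset carries no group labels).
    """
    if not (0 <= cutoff <= 27):
        raise ValueError("cutoff must lie in [0, 27]")
    missing = [c for c in PHQ_ITEMS if c not in data.values.columns]
    if missing:
        raise SchemaError(f"PHQ columns missing: {missing}")
    totals = data.values[list(PHQ_ITEMS)].sum(axis=1)
    depressed = totals >= cutoff
    if data.group is None:
        counts = pd.DataFrame(
            {"depressed": [int(depressed.sum())], "not_depressed": [int((~depressed).sum())]},
            index=["all"],
        )
    else:
        counts = (
            pd.crosstab(data.group, depressed.map({True: "depressed", False: "not_depressed"}))
            .reindex(columns=["depressed", "not_depressed"], fill_value=0)
        )
        counts.index.name = None
        counts.columns.name = None
    return totals, counts


# -- two-group univariate tests ---------------------------------------

@dataclass
class GroupTestResult:
    statistic_name: str
    value: float
    df: float
    p: float
    extra: dict = field(default_factory=dict)


def chi_square_2x2(counts: np.ndarray | pd.DataFrame) -> GroupTestResult:
    """Uncorrected Pearson chi-square on a 2x2 contingency table (df = 1)."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a marginal total is zero")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return GroupTestResult("chi_square", float(chi2), float(dof), float(p))


def t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> GroupTestResult:
    """Pooled-variance Student t-test from group summaries, with Cohen's d.

    ``s_p^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2)``;
    ``t = (m1-m2) / (s_p sqrt(1/n1 + 1/n2))``; two-sided p on
    ``df = n1+n2-2``; ``d = (m1-m2)/s_p``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = m1 - m2
    if sp2 == 0.0:
        if diff == 0.0:
            return GroupTestResult("t", 0.0, float(df), 1.0, {"cohens_d": 0.0})
        return GroupTestResult(
            "t", float(np.sign(diff)) * np.inf, float(df), 0.0,
            {"cohens_d": np.inf, "degenerate": True},
        )
    sp = np.sqrt(sp2)
    t = diff / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    d = diff / sp
    return GroupTestResult("t", float(t), float(df), float(p), {"cohens_d": float(d)})


def t_from_columns(x: np.ndarray, y: np.ndarray) -> GroupTestResult:
    """Pooled t-test on raw columns via their summaries (same contract)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return t_from_summary(
        float(np.mean(x)), float(np.std(x, ddof=1)), len(x),
        float(np.mean(y)), float(np.std(y, ddof=1)), len(y),
    )


def group_item_tests(data: ItemDataset) -> pd.DataFrame:
    """Per-item pooled t-tests between the two groups (Table-1 style)."""
    groups = data.split_groups()
    (la, a), (lb, b) = sorted(groups.items())
    rows = []
    for item in data.item_labels:
        res = t_from_columns(a.values[item].to_numpy(), b.values[item].to_numpy())
        rows.append(
            {
                "item": item,
                "group_a": la,
                "group_b": lb,
                "t": res.value,
                "df": res.df,
                "p": res.p,
                "cohens_d": res.extra.get("cohens_d"),
            }
        )
    return pd.DataFrame(rows)
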