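"""Reading, missingness coding and descriptive statistics for speeded-test data.

Responses are stored as floating-point matrices with ``numpy.nan`` marking an
unanswered cell.  The completion indicators derived from a response matrix use
three states: ``1.0`` (attempted, including deliberately skipped items that
were followed by a later answer), ``0.0`` (the first item of the terminal
not-reached run) and ``numpy.nan`` (structurally missing: every cell after
that first not-reached item).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseMatrix",
    "IndicatorMatrix",
    "CovariateTable",
    "DescriptiveSummary",
    "read_response_matrix",
    "code_missingness",
    "build_covariates",
    "design_matrix",
    "summarize_descriptives",
    "cohens_d",
    "cronbach_alpha",
]

#: design-column layout per model id
MODEL_DESIGNS: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("gender",),
    3: ("condition",),
    4: ("gender", "condition", "gender_x_condition"),
}


@dataclass
class ResponseMatrix:
    """Scored responses, one row per person, one column per item.

    ``values[n, k]`` is 1.0 (correct), 0.0 (incorrect) or nan (no recorded
    answer).  ``item_order`` is the administration order of the items; the
    missingness coding and the linear constraint on completion difficulties
    are meaningless if the columns are permuted.
    """

    values: np.ndarray
    item_order: list[str] = field(default_factory=list)
    person_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("response values must be a 2-D array")
        n, k = self.values.shape
        if n < 1 or k < 1:
            raise ValueError("response matrix must have at least one person and one item")
        finite = self.values[np.isfinite(self.values)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("response cells must be 0, 1 or missing")
        if not self.item_order:
            self.item_order = [f"item_{j + 1}" for j in range(k)]
        if not self.person_ids:
            self.person_ids = [f"p{i + 1}" for i in range(n)]
        if len(self.item_order) != k:
            raise ValueError("item_order length does not match number of columns")
        if len(self.person_ids) != n:
            raise ValueError("person_ids length does not match number of rows")
        if len(set(self.person_ids)) != n:
            raise ValueError("duplicate person id")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


@dataclass
class IndicatorMatrix:
    """Completion indicators: 1 attempted, 0 first not-reached, nan afterwards."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("indicator values must be a 2-D array")
        for i, row in enumerate(self.values):
            zeros = np.flatnonzero(row == 0.0)
            if zeros.size > 1:
                raise ValueError(f"row {i}: more than one 0 indicator")
            nans = np.flatnonzero(np.isnan(row))
            if zeros.size == 0:
                if nans.size:
                    raise ValueError(f"row {i}: structural missing without a 0 indicator")
            else:
                expected = np.arange(zeros[0] + 1, row.size)
                if not np.array_equal(nans, expected):
                    raise ValueError(
                        f"row {i}: structural missings must fill the run after the 0"
                    )

    @property
    def attempted_counts(self) -> np.ndarray:
        """Number of attempted items (indicator == 1) per person."""
        return np.nansum(self.values == 1.0, axis=1).astype(int)


@dataclass
class CovariateTable:
    """Person covariates: dummies for gender (1 = women) and condition (1 = threat)."""

    gender: np.ndarray
    condition: np.ndarray
    subsample: np.ndarray | None = None
    person_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gender = np.asarray(self.gender, dtype=int)
        self.condition = np.asarray(self.condition, dtype=int)
        for name, arr in (("gender", self.gender), ("condition", self.condition)):
            if not np.all(np.isin(arr, (0, 1))):
                raise ValueError(f"{name} dummy must be 0/1")
        if self.gender.shape != self.condition.shape:
            raise ValueError("covariate columns must have equal length")
        if self.subsample is not None:
            self.subsample = np.asarray(self.subsample)
            if self.subsample.shape != self.gender.shape:
                raise ValueError("subsample labels must have covariate length")
        if not self.person_ids:
            self.person_ids = [f"p{i + 1}" for i in range(self.gender.size)]

    @property
    def n_persons(self) -> int:
        return self.gender.size


def read_response_matrix(
    path: str | Path,
    missing_token: str = "NA",
    delimiter: str = ",",
    id_column: str | None = None,
) -> ResponseMatrix:
    """Parse a delimited text file into a :class:`ResponseMatrix`.

    The header row holds the item identifiers in administration order.  Cells
    must parse to ``0``, ``1`` or ``missing_token``; anything else is a hard
    error naming the offending row and column.  A missing-value encoding such
    as ``"9"`` must be declared explicitly via ``missing_token`` — it is never
    inferred from the data.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"{path}: empty response file")
    person_ids: list[str] = []
    if id_column is None and frame.columns[0].lower() in {"person_id", "id", "person"}:
        id_column = frame.columns[0]
    if id_column is not None:
        if id_column not in frame.columns:
            raise ValueError(f"{path}: id column {id_column!r} not found")
        person_ids = [str(v) for v in frame[id_column]]
        if len(set(person_ids)) != len(person_ids):
            raise ValueError(f"{path}: duplicate person id")
        frame = frame.drop(columns=[id_column])
    items = [str(c) for c in frame.columns]
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame[col]):
            cell = cell.strip()
            if cell == missing_token:
                values[i, j] = np.nan
            elif cell in {"0", "1"}:
                values[i, j] = float(cell)
            else:
                raise ValueError(
                    f"{path}: unparseable cell {cell!r} at row {i + 1}, column {col!r}"
                )
    resp = ResponseMatrix(values, item_order=items, person_ids=person_ids)
    logger.info(
        "read %s: N=%d, K=%d, missing fraction=%.3f",
        path, resp.n_persons, resp.n_items, resp.missing_fraction(),
    )
    return resp


def code_missingness(resp: ResponseMatrix) -> IndicatorMatrix:
    """Derive completion indicators from a response matrix.

    Per row: every cell with an observed response is 1; a missing cell that is
    followed by a later observed response is a deliberate skip and is also
    scored 1; the first cell of the terminal missing run is 0; all later cells
    of that run are structurally missing.  A fully observed row is all 1s; a
    fully missing row is a 0 followed by structural missings.
    """
    n, k = resp.values.shape
    out = np.empty((n, k), dtype=float)
    observed = ~np.isnan(resp.values)
    for i in range(n):
        idx = np.flatnonzero(observed[i])
        if idx.size == 0:
            out[i, 0] = 0.0
            out[i, 1:] = np.nan
            continue
        last = idx[-1]
        out[i, : last + 1] = 1.0
        if last + 1 < k:
            out[i, last + 1] = 0.0
            out[i, last + 2 :] = np.nan
    return IndicatorMatrix(out)


def _to_dummy(series: pd.Series, positive_label: str, name: str) -> np.ndarray:
    vals = series.to_numpy()
    if np.issubdtype(np.asarray(vals).dtype, np.number):
        arr = np.asarray(vals, dtype=float)
        if not np.all(np.isin(arr, (0.0, 1.0))):
            raise ValueError(f"numeric {name} column must be a 0/1 dummy")
        return arr.astype(int)
    return np.asarray([1 if str(v) == positive_label else 0 for v in vals], dtype=int)


def build_covariates(
    table: pd.DataFrame,
    model_id: int,
    gender_col: str = "gender",
    condition_col: str = "condition",
    subsample_col: str | None = None,
    women_label: str = "woman",
    threat_label: str = "threat",
) -> tuple[CovariateTable, pd.DataFrame]:
    """Map a raw person table to dummies and the per-model design columns.

    Any condition label other than ``threat_label`` is treated as a control
    arm and mapped to 0, so multiple control arms collapse into a single
    reference category.  Numeric columns must already be 0/1 dummies.
    """
    if model_id not in MODEL_DESIGNS:
        raise ValueError(f"unknown model_id {model_id!r}; expected 1-4")
    for col in (gender_col, condition_col):
        if col not in table.columns:
            raise ValueError(f"covariate table lacks required column {col!r}")
    gender = _to_dummy(table[gender_col], women_label, "gender")
    condition = _to_dummy(table[condition_col], threat_label, "condition")
    subsample = None
    if subsample_col is not None and subsample_col in table.columns:
        subsample = table[subsample_col].to_numpy()
    ids = [str(v) for v in table["person_id"]] if "person_id" in table.columns else []
    cov = CovariateTable(gender, condition, subsample, person_ids=ids)
    return cov, design_matrix(cov, model_id)


def design_matrix(cov: CovariateTable, model_id: int) -> pd.DataFrame:
    """Design columns for the latent regression: none / gender / condition / full."""
    if model_id not in MODEL_DESIGNS:
        raise ValueError(f"unknown model_id {model_id!r}; expected 1-4")
    cols = {}
    for name in MODEL_DESIGNS[model_id]:
        if name == "gender":
            cols[name] = cov.gender
        elif name == "condition":
            cols[name] = cov.condition
        else:
            cols[name] = cov.gender * cov.condition
    frame = pd.DataFrame(cols, index=pd.RangeIndex(cov.n_persons))
    return frame


def cohens_d(x: np.ndarray, y: np.ndarray) -> dict:
    """Standardised mean difference (x minus y) with pooled SD and a 95% CI.

    The pooled SD uses the usual Hedges pooling without small-sample bias
    correction; the CI uses the normal approximation
    ``SE = sqrt(1/n1 + 1/n2 + d^2 / (2 (n1 + n2)))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        return {"d": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "n1": n1, "n2": n2, "flag": "group with < 2 members"}
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        return {"d": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "n1": n1, "n2": n2, "flag": "zero pooled variance"}
    d = (np.mean(x) - np.mean(y)) / np.sqrt(sp2)
    se = np.sqrt(1.0 / n1 + 1.0 / n2 + d * d / (2.0 * (n1 + n2)))
    return {"d": float(d), "ci_low": float(d - 1.959963984540054 * se),
            "ci_high": float(d + 1.959963984540054 * se),
            "n1": n1, "n2": n2, "flag": None}


@dataclass
class DescriptiveSummary:
    """Observed-score layer: per-person counts, group statistics and gaps."""

    attempted_count: np.ndarray
    correct_count: np.ndarray
    group_stats: pd.DataFrame
    gender_gaps: dict
    per_item: pd.DataFrame
    proportion_correct_aggregate: float
    proportion_correct_per_person: float
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "group_stats": self.group_stats.to_dict(orient="records"),
            "gender_gaps": self.gender_gaps,
            "proportion_correct_aggregate": self.proportion_correct_aggregate,
            "proportion_correct_per_person": self.proportion_correct_per_person,
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, default=float)

    def write(self, outdir: str | Path, prefix: str = "descriptives") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        p = outdir / f"{prefix}_groups.csv"
        self.group_stats.to_csv(p, index=False)
        paths.append(p)
        p = outdir / f"{prefix}_per_item.csv"
        self.per_item.to_csv(p, index=False)
        paths.append(p)
        p = outdir / f"{prefix}.json"
        p.write_text(self.to_json())
        paths.append(p)
        return paths


def summarize_descriptives(
    resp: ResponseMatrix,
    ind: IndicatorMatrix,
    cov: CovariateTable | None = None,
) -> DescriptiveSummary:
    """Sum scores, group means/SDs, gender gaps (women minus men) and
    per-item attempt/correct proportion curves.

    ``attempted_count`` counts indicator 1s, so it includes skipped-but-reached
    items; ``answered_count`` (in metadata) counts only recorded answers.
    Both per-person-averaged and aggregate proportion-correct figures are
    reported because the denominator convention is ambiguous in practice.
    """
    if ind.values.shape != resp.values.shape:
        raise ValueError("response and indicator matrices are not aligned")
    attempted = ind.attempted_counts
    answered = (~np.isnan(resp.values)).sum(axis=1)
    correct = np.nansum(resp.values == 1.0, axis=1).astype(int)
    if np.any(correct > attempted):
        raise ValueError("correct count exceeds attempted count")

    total_answered = int(answered.sum())
    prop_aggregate = float(correct.sum() / total_answered) if total_answered else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        per_person = np.where(answered > 0, correct / np.maximum(answered, 1), np.nan)
    prop_per_person = float(np.nanmean(per_person)) if np.isfinite(per_person).any() else np.nan

    frame = pd.DataFrame({
        "attempted": attempted,
        "answered": answered,
        "correct": correct,
    })
    groupers = []
    if cov is not None:
        if cov.n_persons != resp.n_persons:
            raise ValueError("covariate table is not aligned with responses")
        frame["gender"] = cov.gender
        frame["condition"] = cov.condition
        groupers = ["gender", "condition"]
        if cov.subsample is not None:
            frame["subsample"] = cov.subsample
            groupers.append("subsample")

    rows = []

    def _emit(label: dict, sub: pd.DataFrame) -> None:
        for outcome in ("attempted", "answered", "correct"):
            rows.append({**label, "outcome": outcome, "n": len(sub),
                         "mean": float(sub[outcome].mean()),
                         "sd": float(sub[outcome].std(ddof=1)) if len(sub) > 1 else np.nan})

    _emit({"group": "overall"}, frame)
    for g in groupers:
        for value, sub in frame.groupby(g):
            _emit({"group": f"{g}={value}"}, sub)
    if cov is not None and cov.subsample is not None:
        for (s, g), sub in frame.groupby(["subsample", "gender"]):
            _emit({"group": f"subsample={s},gender={g}"}, sub)
    group_stats = pd.DataFrame(rows)

    gaps: dict = {}
    if cov is not None:
        women = frame[frame["gender"] == 1]
        men = frame[frame["gender"] == 0]
        for outcome in ("attempted", "answered", "correct"):
            gaps[outcome] = cohens_d(women[outcome].to_numpy(), men[outcome].to_numpy())

    item_rows = []
    masks = {"all": np.ones(resp.n_persons, dtype=bool)}
    if cov is not None:
        masks["women"] = cov.gender == 1
        masks["men"] = cov.gender == 0
    for label, mask in masks.items():
        if not mask.any():
            continue
        att_prop = (ind.values[mask] == 1.0).mean(axis=0)
        cor_prop = np.nansum(resp.values[mask] == 1.0, axis=0) / mask.sum()
        for j, item in enumerate(resp.item_order):
            item_rows.append({"group": label, "item": item, "position": j + 1,
                              "prop_attempted": float(att_prop[j]),
                              "prop_correct": float(cor_prop[j])})
    per_item = pd.DataFrame(item_rows)

    return DescriptiveSummary(
        attempted_count=attempted,
        correct_count=correct,
        group_stats=group_stats,
        gender_gaps=gaps,
        per_item=per_item,
        proportion_correct_aggregate=prop_aggregate,
        proportion_correct_per_person=prop_per_person,
        metadata={
            "answered_count": answered.tolist(),
            "d_variant": "pooled SD, women minus men, normal-approximation CI",
        },
    )


def cronbach_alpha(
    resp: ResponseMatrix,
    scoring_rule: str = "missing_as_wrong",
) -> dict:
    """Cronbach's alpha of the item columns under an explicit scoring rule.

    ``missing_as_wrong`` scores every unanswered cell 0; ``observed_only``
    restricts to persons with a fully observed row (listwise deletion), which
    can be very restrictive for speeded data.
    """
    if resp.n_items < 2:
        raise ValueError("alpha requires at least 2 items")
    if scoring_rule == "missing_as_wrong":
        data = np.nan_to_num(resp.values, nan=0.0)
    elif scoring_rule == "observed_only":
        complete = ~np.isnan(resp.values).any(axis=1)
        if complete.sum() < 2:
            raise ValueError("fewer than 2 complete rows for observed_only scoring")
        data = resp.values[complete]
    else:
        raise ValueError(f"unknown scoring rule {scoring_rule!r}")
    k = data.shape[1]
    item_var = data.var(axis=0, ddof=1)
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    alpha = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    return {"alpha": float(alpha), "scoring_rule": scoring_rule, "n": int(data.shape[0])}
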