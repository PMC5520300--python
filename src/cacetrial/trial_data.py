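"""Trial records, cross-tabulation and classical two-arm summaries.

This module holds the data model for a two-arm smoking-cessation trial with
a continuous infant outcome (birth weight in grams), CSV input, and the
descriptive layer every downstream estimator consumes: the arm x quit-status
cross-tabulation, the quit-rate contrast between arms, Fisher's exact test
for the 2x2 quit table, and the two-sample t test computed from summary
statistics.

All estimation is complete-case on birth weight: records without a recorded
weight are excluded from every cell and total, and counted per arm as
missing.  No imputation is performed anywhere in the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rounding import round_half_up

log = logging.getLogger(__name__)

__all__ = [
    "Arm",
    "TrialRecord",
    "TrialCohort",
    "Cell",
    "CrossTab",
    "RateContrast",
    "TestResult",
    "TrialDataError",
    "DEFAULT_DIALECT",
    "read_trial_csv",
    "write_trial_csv",
    "cross_tab",
    "quit_rate_contrast",
    "fisher_exact_2x2",
    "two_sample_t_from_summary",
]


class TrialDataError(ValueError):
    """Raised for malformed trial input or inestimable descriptive requests."""


class Arm(str, Enum):
    CONTROL = "control"
    INCENTIVES = "incentives"


#: latent principal-stratum labels carried by synthetic cohorts only
STRATUM_LABELS = ("HS", "IQ", "PQ")


@dataclass(frozen=True)
class TrialRecord:
    """One mother/baby pair.

    ``quit`` is the cotinine-validated cessation indicator at the primary
    outcome; ``birth_weight`` is in grams and may be missing (``None``).
    ``stratum`` is the latent compliance label ('HS' hardened smoker /
    never-quitter, 'IQ' independent quitter / always-quitter, 'PQ' potential
    quitter / complier); it is attached by the synthetic generator only and
    never read by any estimator.
    """

    id: str
    arm: Arm
    quit: bool | None
    birth_weight: float | None
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.birth_weight is not None:
            w = float(self.birth_weight)
            if not math.isfinite(w) or w <= 0:
                raise TrialDataError(
                    f"record {self.id!r}: birth weight must be strictly positive "
                    f"and finite, got {self.birth_weight!r}"
                )
        if self.quit is None and self.birth_weight is not None:
            raise TrialDataError(
                f"record {self.id!r}: quit status may be missing only together "
                "with birth weight"
            )
        if self.stratum is not None and self.stratum not in STRATUM_LABELS:
            raise TrialDataError(
                f"record {self.id!r}: unknown stratum label {self.stratum!r}"
            )

    @property
    def analyzable(self) -> bool:
        """True when the record enters the complete-case analysis set."""
        return self.birth_weight is not None and self.quit is not None


@dataclass(frozen=True)
class TrialCohort:
    """Ordered collection of trial records plus a free-text provenance tag."""

    records: tuple[TrialRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def strip_strata(self) -> "TrialCohort":
        """Drop latent stratum labels (estimators must behave identically)."""
        return TrialCohort(
            tuple(replace(r, stratum=None) for r in self.records),
            provenance=self.provenance,
        )

    def analyzable_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Complete-case (arm, quit, weight) arrays in record order.

        ``arm`` is boolean (True = incentives), ``quit`` boolean, ``weight``
        float64 grams.  This is the array form every estimator and the
        bootstrap operate on.
        """
        recs = [r for r in self.records if r.analyzable]
        arm = np.fromiter((r.arm is Arm.INCENTIVES for r in recs), bool, len(recs))
        quit = np.fromiter((bool(r.quit) for r in recs), bool, len(recs))
        weight = np.fromiter((float(r.birth_weight) for r in recs), float, len(recs))
        return arm, quit, weight

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "arm": [r.arm.value for r in self.records],
                "quit": [r.quit for r in self.records],
                "birth_weight": [r.birth_weight for r in self.records],
                "stratum": [r.stratum for r in self.records],
            }
        )


#: default CSV column-name map (logical name -> file column)
DEFAULT_DIALECT: Mapping[str, str] = {
    "id": "id",
    "arm": "group",
    "quit": "quit",
    "birth_weight": "birthweight_g",
    "stratum": "stratum",
}

_ARM_LABELS = {
    "control": Arm.CONTROL,
    "incentives": Arm.INCENTIVES,
}

_TRUE = {"1", "true", "yes", "quit", "t"}
_FALSE = {"0", "false", "no", "smoker", "f"}


def _parse_quit(value, row_label: str) -> bool | None:
    if value is None or pd.isna(value):
        return None
    s = str(value).strip().lower()
    if s in ("", "na", "nan"):
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    try:
        return bool(int(float(s)))
    except ValueError:
        raise TrialDataError(f"{row_label}: cannot parse quit indicator {value!r}")


def read_trial_csv(
    path,
    dialect: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> TrialCohort:
    """Read a cohort from a delimited text file (UTF-8, header row).

    ``dialect`` maps logical names {'id','arm','quit','birth_weight',
    'stratum'} to file column names; unspecified entries fall back to
    :data:`DEFAULT_DIALECT`.  Missing birth weight is an empty field or NA,
    never 0.  Row order is preserved.  Unknown arm labels and non-positive
    weights are hard errors naming the offending row; duplicate ids are kept
    with a logged warning.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, dtype="string", keep_default_na=True)
    for logical in ("arm", "quit", "birth_weight"):
        if cols[logical] not in df.columns:
            raise TrialDataError(
                f"{path}: required column {cols[logical]!r} (for {logical!r}) "
                f"not found; available: {list(df.columns)}"
            )
    has_id = cols["id"] in df.columns
    has_stratum = cols["stratum"] in df.columns

    records: list[TrialRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        label = f"{path} row {i + 2}"  # header is line 1
        rid = str(row[cols["id"]]) if has_id and pd.notna(row[cols["id"]]) else str(i)
        raw_arm = row[cols["arm"]]
        if pd.isna(raw_arm) or str(raw_arm).strip().lower() not in _ARM_LABELS:
            raise TrialDataError(
                f"{label}: unknown arm label {raw_arm!r} "
                f"(expected one of {sorted(_ARM_LABELS)})"
            )
        arm = _ARM_LABELS[str(raw_arm).strip().lower()]
        raw_w = row[cols["birth_weight"]]
        if pd.isna(raw_w) or str(raw_w).strip() in ("", "NA", "nan"):
            weight = None
        else:
            weight = float(raw_w)
            if not math.isfinite(weight) or weight <= 0:
                raise TrialDataError(
                    f"{label}: birth weight must be positive, got {raw_w!r}"
                )
        quit = _parse_quit(row[cols["quit"]], label)
        if quit is None and weight is not None:
            raise TrialDataError(
                f"{label}: quit status missing for a record with a birth weight"
            )
        stratum = None
        if has_stratum and pd.notna(row[cols["stratum"]]):
            s = str(row[cols["stratum"]]).strip()
            stratum = s if s else None
        if rid in seen:
            log.warning("duplicate id %r at %s; record kept", rid, label)
        seen.add(rid)
        records.append(TrialRecord(rid, arm, quit, weight, stratum))
    return TrialCohort(tuple(records), provenance=provenance or str(path))


def write_trial_csv(
    cohort: TrialCohort,
    path,
    dialect: Mapping[str, str] | None = None,
    include_stratum: bool = False,
) -> None:
    """Write a cohort in the CSV dialect :func:`read_trial_csv` accepts."""
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = cohort.to_frame()
    df["quit"] = df["quit"].map(lambda q: "" if q is None else int(q))
    df["birth_weight"] = df["birth_weight"].map(
        lambda w: "" if w is None else repr(float(w))
    )
    out = pd.DataFrame(
        {
            cols["id"]: df["id"],
            cols["arm"]: df["arm"],
            cols["quit"]: df["quit"],
            cols["birth_weight"]: df["birth_weight"],
        }
    )
    if include_stratum:
        out[cols["stratum"]] = df["stratum"].fillna("")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cross-tabulation


@dataclass(frozen=True)
class Cell:
    """Count, mean and sample SD (n-1 denominator) of one table cell.

    ``mean``/``sd`` are ``None`` when undefined (n = 0, resp. n < 2).
    """

    n: int
    mean: float | None
    sd: float | None

    @staticmethod
    def from_values(values: np.ndarray) -> "Cell":
        n = int(values.size)
        if n == 0:
            return Cell(0, None, None)
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if n >= 2 else None
        return Cell(n, mean, sd)


@dataclass(frozen=True)
class CrossTab:
    """Birth weight by randomized arm x quit status, complete case.

    ``cells`` is keyed by ``(arm, quit)``; ``arm_totals`` and ``overall``
    aggregate the analyzable records; ``n_missing`` counts records excluded
    per arm for missing birth weight.
    """

    cells: Mapping[tuple[Arm, bool], Cell]
    arm_totals: Mapping[Arm, Cell]
    overall: Cell
    n_missing: Mapping[Arm, int]

    def cell(self, arm: Arm, quit: bool) -> Cell:
        return self.cells[(arm, quit)]

    @staticmethod
    def from_cell_summaries(
        cells: Mapping[tuple[Arm, bool], tuple[int, float | None, float | None]],
        n_missing: Mapping[Arm, int] | None = None,
    ) -> "CrossTab":
        """Build a table from per-cell (n, mean, sd) summaries.

        Arm and overall totals are reconstructed as count-weighted means of
        the cells, so the weighted-mean invariant holds exactly; pooled SDs
        at the aggregate level are not recoverable from cell summaries and
        are left ``None``.
        """
        cdict = {
            key: Cell(int(n), None if m is None else float(m), None if s is None else float(s))
            for key, (n, m, s) in cells.items()
        }
        for arm in Arm:
            for q in (False, True):
                cdict.setdefault((arm, q), Cell(0, None, None))
        arm_totals = {}
        for arm in Arm:
            pair = [cdict[(arm, False)], cdict[(arm, True)]]
            n = sum(c.n for c in pair)
            mean = (
                sum(c.n * c.mean for c in pair if c.n) / n if n else None
            )
            arm_totals[arm] = Cell(n, mean, None)
        n_all = sum(t.n for t in arm_totals.values())
        mean_all = (
            sum(t.n * t.mean for t in arm_totals.values() if t.n) / n_all
            if n_all
            else None
        )
        return CrossTab(
            cells=cdict,
            arm_totals=arm_totals,
            overall=Cell(n_all, mean_all, None),
            n_missing=dict(n_missing or {arm: 0 for arm in Arm}),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (one row per cell, plus totals)."""
        rows = []
        for arm in Arm:
            for q, label in ((False, "smoker"), (True, "quitter")):
                c = self.cells[(arm, q)]
                rows.append((arm.value, label, c.n, c.mean, c.sd))
            t = self.arm_totals[arm]
            rows.append((arm.value, "all", t.n, t.mean, t.sd))
        rows.append(("all", "all", self.overall.n, self.overall.mean, self.overall.sd))
        return pd.DataFrame(rows, columns=["arm", "status", "n", "mean_g", "sd_g"])


def cross_tab(cohort: TrialCohort) -> CrossTab:
    """Cross-tabulate birth weight by arm x quit status, complete case."""
    if len(cohort) == 0:
        raise TrialDataError("empty cohort")
    arm, quit, weight = cohort.analyzable_arrays()
    n_missing = {a: 0 for a in Arm}
    for r in cohort:
        if not r.analyzable:
            n_missing[r.arm] += 1
    cells = {}
    arm_totals = {}
    for a, is_inc in ((Arm.CONTROL, False), (Arm.INCENTIVES, True)):
        in_arm = arm == is_inc
        for q in (False, True):
            cells[(a, q)] = Cell.from_values(weight[in_arm & (quit == q)])
        arm_totals[a] = Cell.from_values(weight[in_arm])
    return CrossTab(
        cells=cells,
        arm_totals=arm_totals,
        overall=Cell.from_values(weight),
        n_missing=n_missing,
    )


# ---------------------------------------------------------------------------
# quit-rate contrast and hypothesis tests


@dataclass(frozen=True)
class RateContrast:
    """Quit proportions by arm on complete-case denominators."""

    p1: float  # incentives arm
    p0: float  # control arm
    diff: float
    n_quit1: int
    n1: int
    n_quit0: int
    n0: int


def quit_rate_contrast(xtab: CrossTab) -> RateContrast:
    n1 = xtab.arm_totals[Arm.INCENTIVES].n
    n0 = xtab.arm_totals[Arm.CONTROL].n
    if n1 == 0 or n0 == 0:
        raise TrialDataError("both arms need at least one analyzable record")
    q1 = xtab.cell(Arm.INCENTIVES, True).n
    q0 = xtab.cell(Arm.CONTROL, True).n
    p1, p0 = q1 / n1, q0 / n0
    return RateContrast(p1=p1, p0=p0, diff=p1 - p0, n_quit1=q1, n1=n1, n_quit0=q0, n0=n0)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise TrialDataError(f"p-value outside [0,1]: {self.p_value}")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities no larger than the
    observed table's, at fixed margins.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise TrialDataError("counts must be nonnegative")
    if sum(counts) == 0:
        raise TrialDataError("all-zero table")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p), method="fisher_exact")


def two_sample_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    equal_var: bool = False,
) -> TestResult:
    """Two-sided two-sample t test from group summaries (Welch by default)."""
    if n1 < 2 or n2 < 2:
        raise TrialDataError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise TrialDataError("standard deviations must be nonnegative")
    method = "pooled_t" if equal_var else "welch_t"
    if sd1 == 0 and sd2 == 0:
        # degenerate convention: identical constants are indistinguishable
        p = 1.0 if mean1 == mean2 else 0.0
        log.info("degenerate t test (both SDs zero): p set to %g by convention", p)
        stat = 0.0 if mean1 == mean2 else math.inf * math.copysign(1, mean1 - mean2)
        return TestResult(statistic=stat, p_value=p, method=method)
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if equal_var:
        df = float(n1 + n2 - 2)
    else:  # Welch-Satterthwaite
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        df=df,
    )
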