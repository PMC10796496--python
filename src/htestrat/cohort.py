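"""Patient-level data model, CSV I/O and the printed grouped trial cohort.

The analyses in this package operate on two representations of a two-arm
acute-stroke cohort:

* :class:`PatientRecord` — one subject with on-admission covariates, the
  treatment arm (1 = Cerebrolysin add-on, 0 = control), and outcomes
  (symptomatic hemorrhagic transformation, any HT, day-90 modified Rankin
  Scale and the derived favorable functional outcome, mRS <= 2).
* :class:`GroupedCohort` — event/total counts per (risk-score stratum, arm)
  cell, the form in which the published endpoint tables print the trial.

``printed_cerehetis_cohort`` reconstructs the CEREHETIS middle-cerebral-artery
stroke cohort (n = 238) exactly from its published per-stratum counts; day-90
mRS is not recoverable at the unit level from those tables, so expanded
records carry binary outcomes only and mRS-dependent stages run on synthetic
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientRecord",
    "GroupedCohort",
    "Stratum",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
    "build_grouped_cohort",
    "printed_cerehetis_cohort",
    "contingency_test",
    "mann_whitney",
    "CSV_SCHEMA",
]


class CohortValidationError(ValueError):
    """A record violates the documented schema (reports row and field)."""


@dataclass
class PatientRecord:
    """One subject's covariates, treatment arm and outcomes.

    Binary fields are 0/1 integers.  ``ffo`` must equal ``1`` exactly when
    ``mrs90 <= 2``, and a symptomatic HT implies any HT.  ``mrs90`` may be
    ``None`` for cohorts reconstructed from grouped binary tables.
    """

    id: str
    arm: int
    age: float
    sex: int
    nihss: int
    aspects: int
    hmca: int
    af_ecg: int
    glucose: float
    prestroke_mrs: int
    onset_to_treatment: float
    sht: int
    any_ht: int
    mrs90: int | None = None
    ffo: int | None = None

    def validate(self, row: int | str = "?") -> None:
        def err(fieldname: str, msg: str) -> None:
            raise CohortValidationError(f"row {row}, field '{fieldname}': {msg}")

        for name in ("arm", "sex", "hmca", "af_ecg", "sht", "any_ht"):
            v = getattr(self, name)
            if v not in (0, 1):
                err(name, f"expected 0/1, got {v!r}")
        if not 0 <= self.aspects <= 10:
            err("aspects", f"must be in [0, 10], got {self.aspects}")
        if not 0 <= self.nihss <= 42:
            err("nihss", f"must be in [0, 42], got {self.nihss}")
        if not 0 <= self.prestroke_mrs <= 6:
            err("prestroke_mrs", f"must be in [0, 6], got {self.prestroke_mrs}")
        if self.mrs90 is not None and not 0 <= self.mrs90 <= 6:
            err("mrs90", f"must be in [0, 6], got {self.mrs90}")
        if self.sht == 1 and self.any_ht != 1:
            err("any_ht", "symptomatic HT implies any HT")
        if self.mrs90 is not None:
            expected = int(self.mrs90 <= 2)
            if self.ffo is not None and self.ffo != expected:
                err("ffo", f"must equal 1 iff mrs90 <= 2 (mrs90={self.mrs90})")
            if self.ffo is None:
                self.ffo = expected
        if self.ffo not in (0, 1, None):
            err("ffo", f"expected 0/1, got {self.ffo!r}")


#: Documented CSV header.  Binaries are explicit 0/1 integers; empty cells in
#: ``mrs90``/``ffo`` mark values unavailable at the unit level.
CSV_SCHEMA: tuple[str, ...] = tuple(f.name for f in fields(PatientRecord))

_REQUIRED = tuple(c for c in CSV_SCHEMA if c not in ("mrs90", "ffo"))
_INT_COLS = (
    "arm", "sex", "nihss", "aspects", "hmca", "af_ecg",
    "prestroke_mrs", "sht", "any_ht",
)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame in schema column order."""
    df = pd.DataFrame([vars(r) for r in records], columns=list(CSV_SCHEMA))
    return df


def frame_to_records(df: pd.DataFrame, validate: bool = True) -> list[PatientRecord]:
    """Convert a schema-conformant DataFrame to validated records."""
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {missing}")
    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        kwargs = {}
        for name in CSV_SCHEMA:
            if name in ("mrs90", "ffo"):
                v = row.get(name)
                kwargs[name] = None if v is None or pd.isna(v) else int(v)
            elif name == "id":
                kwargs[name] = str(row[name])
            elif name in _INT_COLS:
                kwargs[name] = int(row[name])
            else:
                kwargs[name] = float(row[name])
        rec = PatientRecord(**kwargs)
        if validate:
            rec.validate(row=i)
        records.append(rec)
    return records


def read_cohort(path) -> list[PatientRecord]:
    """Read a patient CSV (documented schema), validate, preserve row order."""
    df = pd.read_csv(path)
    return frame_to_records(df)


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


@dataclass
class Stratum:
    """One (score value, arm) cell of a grouped cohort."""

    score: int
    arm: int
    n: int
    events: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("stratum size must be nonnegative")
        for name, e in self.events.items():
            if not 0 <= e <= self.n:
                raise ValueError(
                    f"events[{name!r}] = {e} outside [0, n = {self.n}] "
                    f"in stratum (score={self.score}, arm={self.arm})"
                )


@dataclass
class GroupedCohort:
    """Event/total counts per (score stratum, arm) cell.

    Expanding to unit records and regrouping is the identity for every
    binary outcome carried in ``events``.
    """

    strata: list[Stratum]
    score_name: str = "hti"

    @property
    def n(self) -> int:
        return sum(s.n for s in self.strata)

    def outcome_names(self) -> list[str]:
        names: list[str] = []
        for s in self.strata:
            for k in s.events:
                if k not in names:
                    names.append(k)
        return names

    def arm_totals(self, outcome: str) -> dict[int, tuple[int, int]]:
        """Per-arm (events, n) totals for one outcome."""
        out: dict[int, tuple[int, int]] = {}
        for s in self.strata:
            e, n = out.get(s.arm, (0, 0))
            out[s.arm] = (e + s.events.get(outcome, 0), n + s.n)
        return out

    def expand_units(self) -> pd.DataFrame:
        """Expand counts to one row per subject.

        Within a cell, event patterns for multiple outcomes are assigned
        front-to-back per outcome independently: outcome columns are marginal
        reconstructions (their joint distribution within a cell is not
        identified by the printed tables beyond the symptomatic-implies-any
        hierarchy, which the front-packing preserves whenever
        ``events[sht] <= events[any_ht]``).
        """
        frames = []
        for s in self.strata:
            cell = {"arm": s.arm, self.score_name: s.score}
            df = pd.DataFrame([cell] * s.n)
            for name in self.outcome_names():
                e = s.events.get(name, 0)
                df[name] = np.r_[np.ones(e, dtype=int), np.zeros(s.n - e, dtype=int)]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_dict(self) -> dict:
        return {
            "score_name": self.score_name,
            "strata": [
                {"score": s.score, "arm": s.arm, "n": s.n, "events": dict(s.events)}
                for s in self.strata
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupedCohort":
        return cls(
            strata=[Stratum(**s) for s in d["strata"]],
            score_name=d.get("score_name", "hti"),
        )


def build_grouped_cohort(
    records: Sequence[PatientRecord],
    score: Sequence[int],
    outcomes: Sequence[str] = ("sht", "any_ht", "ffo"),
    score_name: str = "hti",
) -> GroupedCohort:
    """Group unit records into (score, arm) cells with per-outcome event counts.

    ``score`` gives the integer stratifying score for each record, in record
    order.  Cell counts sum to ``len(records)``.
    """
    if len(score) != len(records):
        raise ValueError("score must be defined for every record")
    cells: dict[tuple[int, int], Stratum] = {}
    for rec, sc in zip(records, score):
        key = (int(sc), rec.arm)
        if key not in cells:
            cells[key] = Stratum(score=int(sc), arm=rec.arm, n=0,
                                 events={o: 0 for o in outcomes})
        cell = cells[key]
        cell.n += 1
        for o in outcomes:
            v = getattr(rec, o)
            if v is None:
                raise ValueError(f"outcome {o!r} missing on record {rec.id}")
            cell.events[o] += int(v)
    strata = [cells[k] for k in sorted(cells)]
    return GroupedCohort(strata=strata, score_name=score_name)


# Published per-stratum counts: HTI 0-4, (Cerebrolysin n, control n) and
# per-outcome events.  The Cerebrolysin arm has no HTI = 4 patients.
_PRINTED = {
    #  hti: (n_treat, n_ctrl, sht_t, sht_c, anyht_t, anyht_c, ffo_t, ffo_c)
    0: (34, 67, 0, 2, 2, 5, 32, 58),
    1: (34, 37, 0, 4, 6, 11, 24, 23),
    2: (17, 30, 1, 7, 4, 13, 10, 15),
    3: (6, 11, 2, 3, 3, 7, 3, 1),
    4: (0, 2, 0, 1, 0, 1, 0, 1),
}


def printed_cerehetis_cohort() -> GroupedCohort:
    """The published CEREHETIS MCA-stroke cohort (n = 238), grouped by HTI.

    Strata are (HTI value 0-4) x (arm), with event counts for symptomatic HT,
    any HT and favorable functional outcome taken from the trial's endpoint
    tables.  Unit-level mRS is not recoverable and is not carried.
    """
    strata = []
    for hti, (nt, nc, st, sc, at, ac, ft, fc) in _PRINTED.items():
        strata.append(Stratum(hti, 1, nt, {"sht": st, "any_ht": at, "ffo": ft}))
        strata.append(Stratum(hti, 0, nc, {"sht": sc, "any_ht": ac, "ffo": fc}))
    return GroupedCohort(strata=strata, score_name="hti")


def contingency_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Cells are [[a, b], [c, d]].  Returns ``(chi2, p)`` with p from the
    upper tail of chi-square(1).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the tie-corrected normal approximation; when both samples are of
    size <= ``exact_max_n`` and tie-free the exact null distribution is used
    instead (tiny-sample switch).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.r_[x, y])) < x.size + y.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n
                         and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)
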