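"""ICD-9 billing events -> per-code case/control status.

A *case* for a given ICD-9 code is a person with more than three billing
instances of that exact code (count > 3, i.e. at least ``case_min_instances``
with the default of 4); everyone else is a control — there is no exclusion
zone, so persons with 1–3 instances count as controls.  A code is retained
as a phenotype only when it has more than ten cases (``min_cases`` default
11).  Both thresholds are configurable.

Codes are ICD-9 strings ``[VE]?\\d{1,3}(.\\d{1,2})?``; the 3-digit *category*
is the part before the decimal point (V/E prefixes kept), e.g. 405.11 -> 405.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError

ICD9_RE = re.compile(r"^[VE]?\d{1,3}(\.\d{1,2})?$")


def validate_code(code: str) -> str:
    """Return the code unchanged if well-formed, else raise ParseError."""
    if not isinstance(code, str) or not ICD9_RE.match(code):
        raise ParseError(f"malformed ICD-9 code: {code!r}")
    return code


def truncate_to_category(code: str) -> str:
    """3-digit disease category of an ICD-9 code: substring before the dot.

    V/E-prefixed codes keep their prefix ("V70.0" -> "V70").  Idempotent.
    """
    validate_code(code)
    return code.split(".", 1)[0]


def count_code_instances(events: pd.DataFrame) -> pd.DataFrame:
    """Exact per-(person, code) billing multiplicities.

    ``events`` needs columns ``person_id`` and ``icd9_code`` (extra columns
    such as ``event_date`` are ignored; duplicate same-day rows count as
    separate instances).  Pairs absent from the table have implicit count 0.
    Malformed codes raise :class:`ParseError` naming the offending row.
    """
    if events.empty:
        return pd.DataFrame(columns=["person_id", "icd9_code", "n_instances"])
    codes = events["icd9_code"].astype(str)
    bad = ~codes.str.match(ICD9_RE)
    if bad.any():
        row = events.index[bad][0]
        raise ParseError(f"malformed ICD-9 code {codes.loc[row]!r} at event row {row}")
    counts = (
        events.groupby(["person_id", "icd9_code"], sort=True)
        .size()
        .rename("n_instances")
        .reset_index()
    )
    return counts


def derive_status(
    counts: pd.DataFrame, code: str, persons, case_min_instances: int = 4
) -> pd.Series:
    """Case/control vector (1/0) for one code over the full person universe.

    Case iff instance count >= ``case_min_instances`` (default 4, i.e. the
    "more than three instances" rule); everyone else, including persons with
    no events at all, is a control.
    """
    sub = counts[counts["icd9_code"] == code]
    case_ids = set(sub.loc[sub["n_instances"] >= case_min_instances, "person_id"])
    status = pd.Series(
        [1 if p in case_ids else 0 for p in persons], index=list(persons), dtype=np.int8
    )
    status.index.name = "person_id"
    return status


def derive_status_table(
    events: pd.DataFrame, persons, case_min_instances: int = 4
) -> pd.DataFrame:
    """Persons x codes status frame (1 = case, 0 = control) for every code seen."""
    counts = count_code_instances(events)
    persons = list(persons)
    if counts.empty:
        return pd.DataFrame(index=pd.Index(persons, name="person_id"))
    wide = counts.pivot(index="person_id", columns="icd9_code", values="n_instances")
    wide = wide.reindex(persons).fillna(0)
    out = (wide >= case_min_instances).astype(np.int8)
    out.index.name = "person_id"
    out.columns.name = None
    return out.sort_index(axis=1)


@dataclass
class StatusMatrix:
    """Per-phenotype case/control assignments surviving the inclusion filter."""

    statuses: pd.DataFrame   # persons x retained codes, values {0,1}
    summary: pd.DataFrame    # per input code: category, n_case, n_control, retained

    @property
    def persons(self):
        return self.statuses.index

    @property
    def codes(self):
        return list(self.statuses.columns)


def filter_phenotypes(statuses: pd.DataFrame, min_cases: int = 11) -> StatusMatrix:
    """Drop codes with fewer than ``min_cases`` cases (default 11, the
    "more than ten case subjects" inclusion rule)."""
    n_persons = len(statuses)
    n_case = statuses.sum(axis=0).astype(int)
    summary = pd.DataFrame(
        {
            "icd9_code": statuses.columns,
            "category": [truncate_to_category(c) for c in statuses.columns],
            "n_case": n_case.to_numpy(),
            "n_control": n_persons - n_case.to_numpy(),
            "retained": (n_case >= min_cases).to_numpy(),
        }
    )
    kept = summary.loc[summary["retained"], "icd9_code"]
    return StatusMatrix(statuses=statuses[list(kept)], summary=summary)


def derive_phenotypes(
    events: pd.DataFrame, persons, case_min_instances: int = 4, min_cases: int = 11
) -> StatusMatrix:
    """Events -> filtered StatusMatrix in one step."""
    return filter_phenotypes(
        derive_status_table(events, persons, case_min_instances), min_cases
    )
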