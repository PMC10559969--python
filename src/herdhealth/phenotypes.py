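"""Build costed per-cow-per-parity health phenotypes from raw treatment logs.

The pipeline is: deduplicate raw records into billable events, apply the
record edits (abortion-initiated lactations, final-month calvings, the
two-descendant sire/MGS rule), assign fixed costs, and aggregate within
cow-parity.  A treatment dated between dry-off of parity *p* and the next
calving (the dry period) accrues to parity *p*; aggregation windows are
therefore [calving of p, calving of p+1).  Censored or disposed lactations
sum whatever accrued with no days-in-milk adjustment.

All currency arithmetic is done in integer cents so lactational sums are
exact; dollar columns are emitted at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .treatments import (
    CATEGORIES,
    CostTable,
    DedupKind,
    SPECIFIC_TREATMENTS,
    TREATMENT_TYPES,
    TreatmentType,
)

MAX_PARITY = 3
FINAL_MONTH_DAYS = 30


@dataclass
class EditReport:
    """Counts of records removed by each cleaning rule."""

    unknown_code: int = 0
    abortion_lactations: int = 0
    final_month_lactations: int = 0
    descendant_rule_cows: int = 0
    events_before_first_calving: int = 0
    events_beyond_max_parity: int = 0
    notes: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"records with unknown treatment code discarded: {self.unknown_code}",
            f"lactations commenced with an abortion removed: {self.abortion_lactations}",
            f"lactations calving within {FINAL_MONTH_DAYS} d of study end removed: "
            f"{self.final_month_lactations}",
            f"cows removed by the >=2-descendant sire/MGS rule: {self.descendant_rule_cows}",
            f"events dated before first calving rejected: {self.events_before_first_calving}",
            f"events beyond parity {MAX_PARITY} dropped: {self.events_beyond_max_parity}",
        ]
        lines += [str(n) for n in self.notes]
        return "\n".join(lines)


def _to_day_numbers(dates: pd.Series) -> pd.Series:
    """Dates as comparable integer day numbers (accepts ints or datelikes)."""
    if pd.api.types.is_numeric_dtype(dates):
        return dates.astype(np.int64)
    dt = pd.to_datetime(dates)
    return pd.Series(dt.values.astype("datetime64[D]").astype(np.int64), index=dates.index)


def deduplicate_events(
    events: pd.DataFrame,
    types: Mapping[str, TreatmentType] = TREATMENT_TYPES,
    report: EditReport | None = None,
) -> pd.DataFrame:
    """Collapse raw treatment records into billable events.

    ``events`` needs columns ``cow_id``, ``date``, ``treatment_code`` and may
    carry ``parity`` (events are deduplicated within cow-parity when present,
    within the whole cow history otherwise).  Rules, applied per cow (and
    parity) and treatment type in chronological order:

    * all types: same-day repeats collapse to one record;
    * window types: a record is a new event only if the configured number of
      days (3/5/7) elapsed since the most recent record of the same type --
      closely spaced records are follow-up treatments of one illness event;
    * once-per-lactation types: only the first record is kept;
    * per-day types: no elapsed-day restriction beyond the same-day collapse.

    Records with codes outside the 14-type vocabulary are counted in the
    report and dropped; processing continues.  The operation is idempotent.
    """
    report = report if report is not None else EditReport()
    ev = events.copy()
    if ev.empty:
        return ev

    ev["treatment_code"] = ev["treatment_code"].astype(str).str.strip().str.lower()
    known = ev["treatment_code"].isin(types)
    report.unknown_code += int((~known).sum())
    ev = ev[known].copy()
    if ev.empty:
        return ev

    ev["_day"] = _to_day_numbers(ev["date"])
    group_cols = ["cow_id", "treatment_code"]
    if "parity" in ev.columns:
        group_cols.insert(1, "parity")
    ev = ev.sort_values(group_cols + ["_day"], kind="stable")

    keep = np.ones(len(ev), dtype=bool)
    for (_, *rest), idx in ev.groupby(group_cols, sort=False).groups.items():
        code = rest[-1]
        t = types[code]
        days = ev.loc[idx, "_day"].to_numpy()
        k = np.ones(len(days), dtype=bool)
        # same-day collapse applies to every rule kind
        k[1:] &= days[1:] != days[:-1]
        if t.dedup is DedupKind.ONCE_PER_LACTATION:
            k[1:] = False
        elif t.dedup is DedupKind.WINDOW:
            # anchor at the most recent record (kept or not): short gaps mark
            # a continuing illness episode even across dropped records
            k[1:] &= (days[1:] - days[:-1]) >= t.window_days
        keep[ev.index.get_indexer(idx)] = k

    out = ev[keep].drop(columns="_day")
    return out.reset_index(drop=True)


def assign_costs(events: pd.DataFrame, cost_table: CostTable) -> pd.DataFrame:
    """Attach the fixed cost (in cents and dollars) to each event."""
    ev = events.copy()
    if ev.empty:
        ev["cost_cents"] = pd.Series(dtype=np.int64)
        ev["cost"] = pd.Series(dtype=float)
        return ev
    ev["treatment_code"] = ev["treatment_code"].astype(str).str.strip().str.lower()
    cents = {}
    for code in ev["treatment_code"].unique():
        cents[code] = cost_table.cost_cents(code)  # KeyError names missing code
    ev["cost_cents"] = ev["treatment_code"].map(cents).astype(np.int64)
    ev["cost"] = ev["cost_cents"] / 100.0
    return ev


def _descendant_counts(cow_pedigree: pd.DataFrame) -> pd.Series:
    """Daughters + granddaughters per bull, over the cows in the data."""
    sires = cow_pedigree["sire_id"].dropna()
    mgs = cow_pedigree["mgs_id"].dropna()
    return pd.concat([sires, mgs]).value_counts()


def apply_record_edits(
    lactations: pd.DataFrame,
    events: pd.DataFrame,
    pedigree: pd.DataFrame,
    study_end,
) -> tuple[pd.DataFrame, pd.DataFrame, EditReport]:
    """Apply the record edits and return filtered tables plus a report.

    1. lactations commenced with an abortion are removed;
    2. lactations calving within 30 d of study end are removed (no
       opportunity to accumulate 30 d of treatment cost);
    3. cows whose sire or MGS has fewer than 2 descendants (daughters or
       granddaughters) among the remaining cows are removed.

    Events belonging to removed cow-lactations are filtered accordingly.
    """
    if study_end is None:
        raise ValueError("study end date is required for the final-month edit")
    report = EditReport()
    lac = lactations.copy()
    lac["_calving"] = _to_day_numbers(lac["calving_date"])
    end_day = int(_to_day_numbers(pd.Series([study_end])).iloc[0])

    if "abortion" in lac.columns:
        aborted = lac["abortion"].fillna(False).astype(bool)
    else:
        aborted = pd.Series(False, index=lac.index)
    report.abortion_lactations = int(aborted.sum())
    lac = lac[~aborted]

    final_month = (end_day - lac["_calving"]) < FINAL_MONTH_DAYS
    report.final_month_lactations = int(final_month.sum())
    lac = lac[~final_month]

    # >=2-descendant rule on the cows remaining after the edits above
    ped = pedigree.set_index("animal_id")
    cows = pd.Index(lac["cow_id"].unique())
    cow_ped = ped.reindex(cows)
    counts = _descendant_counts(cow_ped)

    def _ok(parent) -> bool:
        if pd.isna(parent):
            return True  # rule needs an identified bull to count against
        return counts.get(parent, 0) >= 2

    keep_cow = cow_ped.apply(
        lambda r: _ok(r.get("sire_id")) and _ok(r.get("mgs_id")), axis=1
    )
    dropped_cows = set(cows[~keep_cow.to_numpy(dtype=bool)])
    report.descendant_rule_cows = len(dropped_cows)
    lac = lac[~lac["cow_id"].isin(dropped_cows)].drop(columns="_calving")

    kept_keys = set(zip(lac["cow_id"], lac["parity"]))
    ev = events.copy()
    if not ev.empty:
        if "parity" in ev.columns:
            mask = [
                (c, p) in kept_keys for c, p in zip(ev["cow_id"], ev["parity"])
            ]
            ev = ev[mask]
        else:
            ev = ev[ev["cow_id"].isin(set(lac["cow_id"]))]
    return lac.reset_index(drop=True), ev.reset_index(drop=True), report


def assign_parity(
    events: pd.DataFrame,
    lactations: pd.DataFrame,
    report: EditReport | None = None,
) -> pd.DataFrame:
    """Assign each event to a parity by its date.

    The window for parity *p* is [calving of p, calving of p+1), which
    includes the dry period following lactation *p*.  Events before the first
    calving are rejected; events past the configured maximum parity are
    dropped; both are counted in the report.
    """
    report = report if report is not None else EditReport()
    ev = events.copy()
    if ev.empty:
        ev["parity"] = pd.Series(dtype=np.int64)
        return ev
    ev["_day"] = _to_day_numbers(ev["date"])
    lac = lactations.copy()
    lac["_calving"] = _to_day_numbers(lac["calving_date"])

    calvings = {
        cow: grp.sort_values("parity")[["parity", "_calving"]].to_numpy()
        for cow, grp in lac.groupby("cow_id")
    }
    parities = np.empty(len(ev), dtype=np.int64)
    for i, (cow, day) in enumerate(zip(ev["cow_id"], ev["_day"])):
        tab = calvings.get(cow)
        if tab is None or day < tab[0, 1]:
            parities[i] = -1  # before first calving / unknown cow
            continue
        # last calving at or before the event date
        j = int(np.searchsorted(tab[:, 1], day, side="right")) - 1
        parities[i] = int(tab[j, 0])
    ev["parity"] = parities

    before = ev["parity"] == -1
    report.events_before_first_calving += int(before.sum())
    beyond = ev["parity"] > MAX_PARITY
    report.events_beyond_max_parity += int(beyond.sum())
    return ev[~before & ~beyond].drop(columns="_day").reset_index(drop=True)


PHENOTYPE_COST_COLUMNS = CATEGORIES + ["THC"] + [f"{t}_cost" for t in SPECIFIC_TREATMENTS]


def aggregate_costs(
    costed_events: pd.DataFrame,
    lactations: pd.DataFrame,
    report: EditReport | None = None,
) -> pd.DataFrame:
    """Sum costed events into one phenotype row per cow-parity.

    Every lactation in ``lactations`` yields a row, with explicit zeros for
    cows without treatments.  Category costs sum the events mapped to each of
    the five categories; THC is their total; the four specific-treatment
    costs (metritis, retained placenta, displaced abomasum, ketosis) are also
    reported.  Events must already be deduplicated and costed; those lacking
    a ``parity`` column are assigned one from the calving dates.
    """
    report = report if report is not None else EditReport()
    ev = costed_events
    if not ev.empty and "parity" not in ev.columns:
        ev = assign_parity(ev, lactations, report)

    base = lactations[["cow_id", "parity"]].copy()
    base = base[base["parity"] <= MAX_PARITY]
    if "herd_id" in lactations.columns:
        base["herd_id"] = lactations.loc[base.index, "herd_id"]
    out = base.drop_duplicates(["cow_id", "parity"]).reset_index(drop=True)

    cents_cols = {}
    for cat in CATEGORIES:
        cents_cols[cat] = np.zeros(len(out), dtype=np.int64)
    spec_cols = {t: np.zeros(len(out), dtype=np.int64) for t in SPECIFIC_TREATMENTS}

    if not ev.empty:
        key = pd.MultiIndex.from_frame(out[["cow_id", "parity"]])
        pos = {k: i for i, k in enumerate(key)}
        cat_of = {c: t.category.value for c, t in TREATMENT_TYPES.items()}
        for cow, par, code, cents in zip(
            ev["cow_id"], ev["parity"], ev["treatment_code"], ev["cost_cents"]
        ):
            i = pos.get((cow, par))
            if i is None:
                report.notes.append(
                    f"event for {cow} parity {par} has no matching lactation row"
                )
                continue
            cents_cols[cat_of[code]][i] += cents
            if code in spec_cols:
                spec_cols[code][i] += cents

    total = np.zeros(len(out), dtype=np.int64)
    for cat in CATEGORIES:
        out[cat] = cents_cols[cat] / 100.0
        total += cents_cols[cat]
    out["THC"] = total / 100.0
    for t in SPECIFIC_TREATMENTS:
        out[f"{t}_cost"] = spec_cols[t] / 100.0
    return out


def testday_edits(testdays: pd.DataFrame) -> pd.DataFrame:
    """Filter test-day rows to the admissible measurement ranges.

    Keeps rows with DIM >= 4, milk weight strictly greater than 2.27 kg, fat
    percentage in [1.0, 9.9] and protein percentage in [1.0, 6.0].
    """
    td = testdays
    ok = (
        (td["dim"] >= 4)
        & (td["milk_kg"] > 2.27)
        & (td["fat_pct"] >= 1.0)
        & (td["fat_pct"] <= 9.9)
        & (td["protein_pct"] >= 1.0)
        & (td["protein_pct"] <= 6.0)
    )
    return td[ok].reset_index(drop=True)


def build_phenotypes(
    events: pd.DataFrame,
    lactations: pd.DataFrame,
    pedigree: pd.DataFrame,
    cost_table: CostTable,
    study_end,
) -> tuple[pd.DataFrame, EditReport]:
    """Full pipeline: edits -> parity assignment -> dedup -> costs -> aggregate."""
    report = EditReport()
    lac, ev, edit_report = apply_record_edits(lactations, events, pedigree, study_end)
    report.abortion_lactations = edit_report.abortion_lactations
    report.final_month_lactations = edit_report.final_month_lactations
    report.descendant_rule_cows = edit_report.descendant_rule_cows
    if not ev.empty and "parity" not in ev.columns:
        ev = assign_parity(ev, lac, report)
    ev = deduplicate_events(ev, report=report)
    ev = assign_costs(ev, cost_table)
    phen = aggregate_costs(ev, lac, report)
    return phen, report
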