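"""Embedded relational store for the stationary-state database extension.

Two tables keyed by the case identifier mirror the screening database's
extension: ``stationary_states`` holds every recorded equilibrium (branch
point index, parameter, state coordinates, stability flag, stable-interval
label and multistability annotations) and ``bifurcations`` holds the
detected bifurcation values (LP/AH label, parameter, state).  Backed by a
single SQLite file — zero-setup and queryable with plain SQL; CSV
import/export round-trips both tables.

State vectors are stored as JSON arrays of binary64 floats, so numeric
round trips are exact.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["StationaryStateRecord", "BifurcationRecord", "ResultsStore",
           "IntegrityError"]


class IntegrityError(RuntimeError):
    """Duplicate key with a different payload, or broken reference."""


@dataclass(frozen=True)
class StationaryStateRecord:
    case_id: int
    point_id: int
    parameter: float
    state: tuple
    stable: bool
    interval_label: Optional[str] = None      # "hyp1", "dep2", ... or None
    scenario_class: Optional[str] = None      # "A".."J", "none", ...
    coexistence_at_original: tuple = ()       # regime sets at the case's g

    def key(self):
        return (self.case_id, self.point_id)


@dataclass(frozen=True)
class BifurcationRecord:
    case_id: int
    label: str                                # "LP1", "AH2", ...
    kind: str                                 # "LP" | "AH"
    parameter: float
    state: tuple

    def key(self):
        return (self.case_id, self.label)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS stationary_states (
    case_id INTEGER NOT NULL,
    point_id INTEGER NOT NULL,
    parameter REAL NOT NULL,
    state TEXT NOT NULL,
    stable INTEGER NOT NULL,
    interval_label TEXT,
    scenario_class TEXT,
    coexistence_at_original TEXT,
    PRIMARY KEY (case_id, point_id)
);
CREATE TABLE IF NOT EXISTS bifurcations (
    case_id INTEGER NOT NULL,
    label TEXT NOT NULL,
    kind TEXT NOT NULL,
    parameter REAL NOT NULL,
    state TEXT NOT NULL,
    PRIMARY KEY (case_id, label)
);
"""


def _dump_state(state):
    return json.dumps([float(x) for x in state])


def _load_state(text):
    return tuple(json.loads(text))


class ResultsStore:
    """SQLite-backed store; use as a context manager or call close()."""

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self._con = sqlite3.connect(self.path)
        self._con.executescript(_SCHEMA)

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def close(self):
        self._con.close()

    # -- writing ----------------------------------------------------------
    def write_case(self, records, bifurcations=()) -> None:
        """Transactional, idempotent insert of one case's rows.

        Re-running with identical inputs is a no-op; a duplicate key with a
        differing payload raises :class:`IntegrityError` and rolls back.
        """
        records = list(records)
        bifurcations = list(bifurcations)
        case_ids = {r.case_id for r in records}
        for b in bifurcations:
            if b.case_id not in case_ids:
                raise IntegrityError(
                    f"bifurcation {b.label} references case {b.case_id} with "
                    "no stationary-state rows in this write")
        cur = self._con.cursor()
        try:
            cur.execute("BEGIN")
            for r in records:
                row = (r.case_id, r.point_id, float(r.parameter),
                       _dump_state(r.state), int(bool(r.stable)),
                       r.interval_label, r.scenario_class,
                       json.dumps([sorted(s) for s in r.coexistence_at_original]))
                existing = cur.execute(
                    "SELECT parameter, state, stable, interval_label, "
                    "scenario_class, coexistence_at_original FROM "
                    "stationary_states WHERE case_id=? AND point_id=?",
                    (r.case_id, r.point_id)).fetchone()
                if existing is None:
                    cur.execute(
                        "INSERT INTO stationary_states VALUES (?,?,?,?,?,?,?,?)",
                        row)
                elif tuple(existing) != row[2:]:
                    raise IntegrityError(
                        f"stationary state ({r.case_id}, {r.point_id}) already "
                        "stored with a different payload")
            for b in bifurcations:
                row = (b.case_id, b.label, b.kind, float(b.parameter),
                       _dump_state(b.state))
                existing = cur.execute(
                    "SELECT kind, parameter, state FROM bifurcations "
                    "WHERE case_id=? AND label=?", (b.case_id, b.label)).fetchone()
                if existing is None:
                    cur.execute("INSERT INTO bifurcations VALUES (?,?,?,?,?)", row)
                elif tuple(existing) != row[2:]:
                    raise IntegrityError(
                        f"bifurcation ({b.case_id}, {b.label}) already stored "
                        "with a different payload")
            self._con.commit()
        except Exception:
            self._con.rollback()
            raise

    # -- reading ----------------------------------------------------------
    def _state_rows(self, where="", params=()):
        q = ("SELECT case_id, point_id, parameter, state, stable, "
             "interval_label, scenario_class, coexistence_at_original "
             "FROM stationary_states")
        if where:
            q += " WHERE " + where
        q += " ORDER BY case_id, point_id"
        out = []
        for row in self._con.execute(q, params):
            out.append(StationaryStateRecord(
                case_id=row[0], point_id=row[1], parameter=row[2],
                state=_load_state(row[3]), stable=bool(row[4]),
                interval_label=row[5], scenario_class=row[6],
                coexistence_at_original=tuple(
                    frozenset(s) for s in json.loads(row[7] or "[]")),
            ))
        return out

    def query_states(self, *, case_id=None, stable=None, interval_label=None,
                     scenario_class=None, predicate=None):
        """Filtered stationary-state records, ordered by (case_id, point_id).

        Field filters combine with AND; ``predicate`` is an optional final
        Python-side filter over the record.
        """
        clauses, params = [], []
        if case_id is not None:
            clauses.append("case_id=?"); params.append(case_id)
        if stable is not None:
            clauses.append("stable=?"); params.append(int(bool(stable)))
        if interval_label is not None:
            clauses.append("interval_label=?"); params.append(interval_label)
        if scenario_class is not None:
            clauses.append("scenario_class=?"); params.append(scenario_class)
        rows = self._state_rows(" AND ".join(clauses), tuple(params))
        if predicate is not None:
            rows = [r for r in rows if predicate(r)]
        return rows

    def query_bifurcations(self, *, case_id=None, kind=None):
        clauses, params = [], []
        if case_id is not None:
            clauses.append("case_id=?"); params.append(case_id)
        if kind is not None:
            clauses.append("kind=?"); params.append(kind)
        q = "SELECT case_id, label, kind, parameter, state FROM bifurcations"
        if clauses:
            q += " WHERE " + " AND ".join(clauses)
        q += " ORDER BY case_id, label"
        return [BifurcationRecord(case_id=r[0], label=r[1], kind=r[2],
                                  parameter=r[3], state=_load_state(r[4]))
                for r in self._con.execute(q, tuple(params))]

    def case_ids(self):
        return [r[0] for r in self._con.execute(
            "SELECT DISTINCT case_id FROM stationary_states ORDER BY case_id")]

    def check_referential_integrity(self) -> None:
        orphan = self._con.execute(
            "SELECT b.case_id, b.label FROM bifurcations b LEFT JOIN "
            "(SELECT DISTINCT case_id FROM stationary_states) s "
            "ON b.case_id = s.case_id WHERE s.case_id IS NULL").fetchall()
        if orphan:
            raise IntegrityError(f"bifurcations reference unknown cases: {orphan}")

    # -- CSV import/export ------------------------------------------------
    def export_csv(self, states_path, bifurcations_path) -> None:
        import pandas as pd
        sr = self._state_rows()
        pd.DataFrame([{
            "case_id": r.case_id, "point_id": r.point_id,
            "parameter": repr(r.parameter), "state": _dump_state(r.state),
            "stable": int(r.stable), "interval_label": r.interval_label or "",
            "scenario_class": r.scenario_class or "",
            "coexistence_at_original": json.dumps(
                [sorted(s) for s in r.coexistence_at_original]),
        } for r in sr]).to_csv(states_path, index=False)
        br = self.query_bifurcations()
        pd.DataFrame([{
            "case_id": b.case_id, "label": b.label, "kind": b.kind,
            "parameter": repr(b.parameter), "state": _dump_state(b.state),
        } for b in br]).to_csv(bifurcations_path, index=False)

    def import_csv(self, states_path, bifurcations_path) -> None:
        import pandas as pd
        sdf = pd.read_csv(states_path, keep_default_na=False)
        by_case = {}
        for _, row in sdf.iterrows():
            rec = StationaryStateRecord(
                case_id=int(row["case_id"]), point_id=int(row["point_id"]),
                parameter=float(row["parameter"]),
                state=_load_state(row["state"]), stable=bool(int(row["stable"])),
                interval_label=row["interval_label"] or None,
                scenario_class=row["scenario_class"] or None,
                coexistence_at_original=tuple(
                    frozenset(s) for s in json.loads(
                        row["coexistence_at_original"] or "[]")),
            )
            by_case.setdefault(rec.case_id, ([], []))[0].append(rec)
        bdf = pd.read_csv(bifurcations_path, keep_default_na=False)
        for _, row in bdf.iterrows():
            rec = BifurcationRecord(
                case_id=int(row["case_id"]), label=row["label"],
                kind=row["kind"], parameter=float(row["parameter"]),
                state=_load_state(row["state"]))
            if rec.case_id in by_case:
                by_case[rec.case_id][1].append(rec)
        for case_id, (records, bifs) in by_case.items():
            self.write_case(records, bifs)
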