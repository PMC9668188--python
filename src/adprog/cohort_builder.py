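"""Participant selection, exclusion rules and annual label construction.

Follow-up visits are rounded to the nearest whole year (ties round up).
Participants are excluded when their trajectory is uninformative or
internally inconsistent: no follow-up within the horizon, CN baselines who
reach dementia within the horizon or who progress and later revert, and
MCI baselines ever labelled CN or who reach AD and revert.  For the kept
participants, each visit's diagnosis labels its rounded year; converters
who leave the study are carried forward at the converted stage through the
horizon, while non-converters contribute no row for years without a visit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ParticipantRecord",
    "ExclusionLog",
    "apply_exclusions",
    "build_labels",
    "records_from_frames",
    "round_month_to_year",
    "EXCLUSION_RULES",
]

_DX_LEVEL = {"CN": 0, "MCI": 1, "AD": 2}

CATEGORIES = ("CN-stable", "CN-converter", "MCI-stable", "MCI-converter")

EXCLUSION_RULES = (
    "baseline_ad_or_no_followup",
    "cn_reached_ad",
    "cn_progressed_then_reverted",
    "mci_diagnosed_cn",
    "mci_reached_ad_then_reverted",
)


class DataError(ValueError):
    pass


@dataclass
class ParticipantRecord:
    """Raw participant: baseline diagnosis, features, follow-up visits.

    ``visits`` is a list of (month >= 1, diagnosis) pairs, kept sorted by
    month with unique months.
    """

    id: object
    baseline_dx: str
    baseline_features: dict = field(default_factory=dict)
    visits: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.visits = sorted(self.visits, key=lambda v: v[0])
        months = [m for m, _ in self.visits]
        if len(set(months)) != len(months):
            raise DataError(f"participant {self.id}: duplicate visit months")
        for m, d in self.visits:
            if d not in _DX_LEVEL:
                raise DataError(
                    f"participant {self.id}: unknown diagnosis {d!r} at month {m}")
        if self.baseline_dx not in _DX_LEVEL:
            raise DataError(
                f"participant {self.id}: unknown baseline diagnosis "
                f"{self.baseline_dx!r}")


def round_month_to_year(month: int) -> int:
    """Nearest whole year; a half-year ties to the later year (18 -> 2)."""
    return int((month + 6) // 12)


def _visits_in_horizon(rec: ParticipantRecord, horizon_years: int):
    """Visits whose rounded year falls in 1..horizon, with the year."""
    out = []
    for m, d in rec.visits:
        y = round_month_to_year(m)
        if 1 <= y <= horizon_years:
            out.append((m, y, d))
    return out


@dataclass
class ExclusionLog:
    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})
    excluded_ids: dict[str, list] = field(
        default_factory=lambda: {r: [] for r in EXCLUSION_RULES})

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "excluded_ids": self.excluded_ids}, indent=1)


def _exclusion_rule(rec: ParticipantRecord, horizon_years: int) -> str | None:
    """First matching exclusion rule for a record, or None if kept."""
    vis = _visits_in_horizon(rec, horizon_years)
    if rec.baseline_dx == "AD" or not vis:
        return "baseline_ad_or_no_followup"
    levels = [_DX_LEVEL[rec.baseline_dx]] + [_DX_LEVEL[d] for _, _, d in vis]
    if rec.baseline_dx == "CN":
        if max(levels) == _DX_LEVEL["AD"]:
            return "cn_reached_ad"
        # any rise followed by a fall
        for i in range(1, len(levels)):
            if levels[i] < max(levels[:i + 1]) and max(levels[:i + 1]) > levels[0]:
                return "cn_progressed_then_reverted"
    else:  # MCI baseline
        if any(lv == _DX_LEVEL["CN"] for lv in levels[1:]):
            return "mci_diagnosed_cn"
        reached_ad = False
        for lv in levels[1:]:
            if lv == _DX_LEVEL["AD"]:
                reached_ad = True
            elif reached_ad:
                return "mci_reached_ad_then_reverted"
    return None


def apply_exclusions(
    raw: list[ParticipantRecord], horizon_years: int = 5
) -> tuple[list[ParticipantRecord], ExclusionLog]:
    """Drop uninformative / inconsistent participants; log one count per rule.

    Idempotent: the kept list passes unchanged through a second application.
    """
    kept: list[ParticipantRecord] = []
    log = ExclusionLog()
    for rec in raw:
        rule = _exclusion_rule(rec, horizon_years)
        if rule is None:
            kept.append(rec)
        else:
            log.counts[rule] += 1
            log.excluded_ids[rule].append(rec.id)
    return kept, log


def build_labels(
    kept: list[ParticipantRecord], horizon_years: int = 5
) -> pd.DataFrame:
    """Annual label table for participants that passed the exclusions.

    Returns one row per (id, year) with columns ``id, year, label,
    category, exact_month, carried_forward``.  Rules:

    * each visit labels its rounded year; if two visits round to the same
      year, the chronologically later one wins (logged via the kept month);
    * once a participant is seen at a stage later than baseline, the
      converted stage is carried forward through every subsequent year up
      to the horizon (including gap years between converted visits);
    * non-converters contribute no row for years without a visit.

    ``exact_month`` is the visit month where a visit exists and <NA> for
    carried-forward rows.
    """
    rows = []
    for rec in kept:
        base_level = _DX_LEVEL[rec.baseline_dx]
        by_year: dict[int, tuple[int, str]] = {}
        for m, y, d in _visits_in_horizon(rec, horizon_years):
            if y not in by_year or m > by_year[y][0]:
                by_year[y] = (m, d)  # later visit wins on conflict

        converted_level = 0
        for year in range(1, horizon_years + 1):
            if year in by_year:
                m, d = by_year[year]
                label = d
                exact, carried = m, False
                if _DX_LEVEL[d] > base_level:
                    converted_level = max(converted_level, _DX_LEVEL[d])
            elif converted_level > base_level:
                label = {v: k for k, v in _DX_LEVEL.items()}[converted_level]
                exact, carried = None, True
            else:
                continue
            if rec.baseline_dx == "CN":
                category = "CN-converter" if _DX_LEVEL[label] > 0 else "CN-stable"
            else:
                category = "MCI-converter" if label == "AD" else "MCI-stable"
            rows.append((rec.id, year, label, category, exact, carried))

    frame = pd.DataFrame(
        rows, columns=["id", "year", "label", "category",
                       "exact_month", "carried_forward"])
    frame["exact_month"] = frame["exact_month"].astype("Int64")
    return frame


def records_from_frames(
    baseline: pd.DataFrame, visits: pd.DataFrame
) -> list[ParticipantRecord]:
    """Assemble records from a baseline table and a visit table."""
    feature_cols = [c for c in baseline.columns if c not in ("id", "baseline_dx")]
    by_id: dict = {}
    for _, row in baseline.iterrows():
        by_id[row["id"]] = ParticipantRecord(
            id=row["id"],
            baseline_dx=str(row["baseline_dx"]),
            baseline_features={c: row[c] for c in feature_cols},
            visits=[],
        )
    grouped = visits.groupby("id") if len(visits) else []
    for pid, grp in grouped:
        if pid not in by_id:
            raise DataError(f"visit for unknown participant {pid!r}")
        rec = by_id[pid]
        rec.visits = sorted(
            [(int(m), str(d)) for m, d in zip(grp["month"], grp["diagnosis"])],
            key=lambda v: v[0])
        ParticipantRecord.__post_init__(rec)  # re-validate
    return list(by_id.values())


def write_labels(labels: pd.DataFrame, log: ExclusionLog, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels.to_csv(out / "labels.csv", index=False)
    (out / "exclusion_log.json").write_text(log.to_json())
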