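"""SD event data model: onset tables, hit sequences, TOADs, branch reduction
and per-patient susceptibility summaries.

A spreading depolarization (SD) sweeping under a subdural strip registers at
each electrode as a slow-potential-change onset. Sorting the per-electrode
onsets gives the hit sequence; successive differences are the
time-of-arrival-differences (TOADs) that drive the trajectory search. An SD
must hit at least three electrodes to be searchable. SDs that start at an
interior electrode and run in both directions ("branching") can be reduced by
dropping the shorter branch (or the later one when lengths tie), which turns
the sequence monotone along the strip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EventSchemaError

__all__ = [
    "SDEvent",
    "HitSequence",
    "SusceptibilitySummary",
    "read_events",
    "write_events",
    "build_hit_sequence",
    "reduce_hit_sequence",
    "susceptibility_metrics",
]


@dataclass
class SDEvent:
    """One SD: per-electrode onset times in minutes (absent = not hit),
    optional depression / DC-shift durations and activity flags."""

    event_id: str
    onsets: dict[str, float]
    depression_durations: dict[str, float] = field(default_factory=dict)
    dc_shift_durations: dict[str, float] = field(default_factory=dict)
    active: dict[str, bool] = field(default_factory=dict)
    day: int = 0

    def __post_init__(self):
        if not self.onsets:
            raise EventSchemaError(f"event {self.event_id}: no onsets")
        for e, t in self.onsets.items():
            if not np.isfinite(t) or t < 0:
                raise EventSchemaError(
                    f"event {self.event_id}: onset for {e} must be finite and >= 0"
                )

    @property
    def first_onset(self) -> float:
        return min(self.onsets.values())

    def total_depression(self) -> float:
        return float(sum(self.depression_durations.values()))


@dataclass
class HitSequence:
    """Electrodes in order of SD arrival with the TOADs between them."""

    event_id: str
    electrodes: list[str]
    times: np.ndarray
    reduced: bool = False
    removed: list[str] = field(default_factory=list)
    reducible: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        if len(self.electrodes) != len(self.times):
            raise ValueError("electrodes/times length mismatch")
        if len(self.times) >= 2 and not (np.diff(self.times) > 0).all():
            raise ValueError("hit times must be strictly increasing")

    @property
    def toads(self) -> np.ndarray:
        return np.diff(self.times)

    def __len__(self) -> int:
        return len(self.electrodes)

    def to_json_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "electrodes": list(self.electrodes),
            "times_min": self.times.tolist(),
            "toads_min": self.toads.tolist(),
            "reduced": self.reduced,
            "removed": list(self.removed),
            "reducible": self.reducible,
        }


def build_hit_sequence(event: SDEvent, min_hits: int = 3) -> HitSequence:
    """Sort the event's onsets into a hit sequence and compute TOADs.

    Requires at least ``min_hits`` electrodes with onsets (three are needed
    for the trajectory search) and pairwise-distinct onset times: a tied
    onset would produce a zero TOAD, i.e. an infinite segment velocity.
    """
    items = sorted(event.onsets.items(), key=lambda kv: (kv[1], kv[0]))
    if len(items) < min_hits:
        raise EventSchemaError(
            f"event {event.event_id}: insufficient electrodes "
            f"({len(items)} < {min_hits})"
        )
    times = np.array([t for _, t in items])
    if (np.diff(times) <= 0).any():
        raise EventSchemaError(
            f"event {event.event_id}: simultaneous onsets "
            "(tied times give a zero TOAD)"
        )
    return HitSequence(
        event_id=event.event_id,
        electrodes=[e for e, _ in items],
        times=times,
    )


def reduce_hit_sequence(seq: HitSequence, strip_order: list[str]) -> HitSequence:
    """Remove the minor branch of a branching hit sequence.

    If the first-hit electrode is interior to the strip and the later hits
    split into two runs that move monotonically away from it in strip index,
    the run with fewer hits is removed (on a length tie, the run whose final
    hit occurs later). A sequence already monotone in strip index is returned
    unchanged with ``reduced=True``; a sequence not decomposable into at most
    two monotone runs is returned unchanged with ``reducible=False``.
    """
    idx = {lab: i for i, lab in enumerate(strip_order)}
    for lab in seq.electrodes:
        if lab not in idx:
            raise ValueError(f"electrode {lab} not on the strip")
    order = [idx[lab] for lab in seq.electrodes]

    diffs = np.diff(order)
    if (diffs > 0).all() or (diffs < 0).all():
        return replace(seq, reduced=True, reducible=True)

    first = order[0]
    up = [(lab, t) for lab, t in zip(seq.electrodes[1:], seq.times[1:])
          if idx[lab] > first]
    down = [(lab, t) for lab, t in zip(seq.electrodes[1:], seq.times[1:])
            if idx[lab] < first]

    def monotone_away(branch, sign):
        ids = [idx[lab] for lab, _ in branch]       # already in time order
        return all((b - a) * sign > 0 for a, b in zip([first] + ids, ids + []))

    if not up or not down or not monotone_away(up, +1) or not monotone_away(down, -1):
        return replace(seq, reduced=False, reducible=False)

    if len(up) != len(down):
        drop = up if len(up) < len(down) else down
    else:
        drop = up if up[-1][1] > down[-1][1] else down
    removed = [lab for lab, _ in drop]
    keep = [(lab, t) for lab, t in zip(seq.electrodes, seq.times)
            if lab not in removed]
    return HitSequence(
        event_id=seq.event_id,
        electrodes=[lab for lab, _ in keep],
        times=np.array([t for _, t in keep]),
        reduced=True,
        removed=removed,
        reducible=True,
    )


# ---------------------------------------------------------------------------
# Event table I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("event_id", "electrode", "onset_min")


def read_events(path: str) -> list[SDEvent]:
    """Read a long-format CSV/TSV event table.

    Required columns: ``event_id, electrode, onset_min``; optional:
    ``depression_min, dc_shift_min, active, day``. Rows whose onset is
    empty/NA mark electrodes not hit and are preserved as absent, never as
    zero. Duplicate (event, electrode) rows are a schema error.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in _REQUIRED:
        if col not in df.columns:
            raise EventSchemaError(f"missing required column {col!r}")
    dup = df.duplicated(subset=["event_id", "electrode"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()     # 1-based incl. header
        raise EventSchemaError(f"duplicate (event, electrode) rows at lines {rows}")
    bad = df["onset_min"].apply(
        lambda x: not (pd.isna(x) or isinstance(x, (int, float, np.number)))
    )
    if bad.any():
        raise EventSchemaError(
            f"non-numeric onset values at rows {(df.index[bad] + 2).tolist()}"
        )

    events = []
    for eid, grp in df.groupby("event_id", sort=False):
        onsets, depr, dc, act = {}, {}, {}, {}
        for _, row in grp.iterrows():
            e = str(row["electrode"])
            if not pd.isna(row["onset_min"]):
                onsets[e] = float(row["onset_min"])
            if "depression_min" in grp and not pd.isna(row.get("depression_min")):
                depr[e] = float(row["depression_min"])
            if "dc_shift_min" in grp and not pd.isna(row.get("dc_shift_min")):
                dc[e] = float(row["dc_shift_min"])
            if "active" in grp and not pd.isna(row.get("active")):
                act[e] = bool(row["active"])
        day = int(grp["day"].iloc[0]) if "day" in grp else 0
        events.append(
            SDEvent(event_id=str(eid), onsets=onsets, depression_durations=depr,
                    dc_shift_durations=dc, active=act, day=day)
        )
    return events


def write_events(events: list[SDEvent], path: str) -> None:
    rows = []
    for ev in events:
        labels = set(ev.onsets) | set(ev.depression_durations) | set(ev.active)
        for e in sorted(labels):
            rows.append(
                {
                    "event_id": ev.event_id,
                    "electrode": e,
                    "onset_min": ev.onsets.get(e, np.nan),
                    "depression_min": ev.depression_durations.get(e, np.nan),
                    "dc_shift_min": ev.dc_shift_durations.get(e, np.nan),
                    "active": ev.active.get(e, np.nan),
                    "day": ev.day,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Susceptibility metrics
# ---------------------------------------------------------------------------

@dataclass
class SusceptibilitySummary:
    """Per-patient SD-susceptibility variables: median inter-SD interval,
    peak daily counts (total / spreading depressions / isoelectric SDs) and
    PTDDD, the peak total SD-induced depression duration of a recording day."""

    median_interval_min: float | None
    peak_daily_sds: int | None
    peak_daily_spreading_depressions: int | None
    peak_daily_isoelectric_sds: int | None
    ptddd_min: float | None


def susceptibility_metrics(events: list[SDEvent]) -> SusceptibilitySummary:
    """Summaries over a time-ordered event list; empty input gives nulls.

    An SD counts as a spreading depression when any electrode was
    electrically active at onset, as isoelectric otherwise (flags are inputs,
    not derived from waveforms).
    """
    if not events:
        return SusceptibilitySummary(None, None, None, None, None)
    firsts = sorted(ev.first_onset for ev in events)
    intervals = np.diff(firsts)
    median_interval = float(np.median(intervals)) if len(intervals) else None

    by_day: dict[int, list[SDEvent]] = {}
    for ev in events:
        by_day.setdefault(ev.day, []).append(ev)
    daily_counts = {d: len(evs) for d, evs in by_day.items()}
    daily_depr = {d: sum(ev.total_depression() for ev in evs)
                  for d, evs in by_day.items()}

    def is_spreading_depression(ev: SDEvent) -> bool:
        return any(ev.active.get(e, False) for e in ev.onsets)

    daily_sd = {d: sum(is_spreading_depression(ev) for ev in evs)
                for d, evs in by_day.items()}
    daily_iso = {d: sum(not is_spreading_depression(ev) for ev in evs)
                 for d, evs in by_day.items()}

    return SusceptibilitySummary(
        median_interval_min=median_interval,
        peak_daily_sds=max(daily_counts.values()),
        peak_daily_spreading_depressions=max(daily_sd.values()),
        peak_daily_isoelectric_sds=max(daily_iso.values()),
        ptddd_min=float(max(daily_depr.values())),
    )
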