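"""Mediator-panel tables: loading, validation, filtering, windowing.

The central container is :class:`MediatorPanel`, a long-format table of
inflammatory-mediator concentrations (pg/ml; nitrite/nitrate in µM) indexed
by subject, time and mediator, with a group label per subject.  Missing
measurements are stored as explicit ``NaN`` markers in the ``value`` column
and are never imputed; every downstream computation uses pairwise-complete
observations.

Times are plain numbers with a declared unit (``day`` or ``hour``);
calendar-date parsing is out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("inflamnet")

LONG_COLUMNS = ["subject", "time", "mediator", "value", "group"]

__all__ = [
    "TimeWindow",
    "MediatorPanel",
    "HUMAN_DAILY_SCHEDULE",
    "MOUSE_HOURS_SCHEDULE",
    "load_panel",
    "save_panel",
    "filter_min_samples",
    "background_correct",
    "window_observations",
]


@dataclass(frozen=True)
class TimeWindow:
    """A consecutive time span, closed on both ends ([start, end]).

    A shared endpoint (e.g. day 1 in ``d0-d1`` and ``d1-2``) contributes
    observations to BOTH adjacent windows, which maximises usable samples
    under sparse daily sampling.
    """

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"window {self.label!r}: start ({self.start}) must be < end ({self.end})"
            )

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


#: Seven consecutive daily windows used for the human serum panels.
HUMAN_DAILY_SCHEDULE: list[TimeWindow] = [TimeWindow("d0-d1", 0, 1)] + [
    TimeWindow(f"d{i}-{i + 1}", i, i + 1) for i in range(1, 7)
]

#: Three consecutive hourly windows used for the mouse hepatocyte supernatants.
MOUSE_HOURS_SCHEDULE: list[TimeWindow] = [
    TimeWindow("1-3h", 1, 3),
    TimeWindow("3-6h", 3, 6),
    TimeWindow("6-24h", 6, 24),
]


@dataclass
class MediatorPanel:
    """Subject x time x mediator concentration table with group labels.

    Parameters
    ----------
    data
        Long-format frame with columns ``subject, time, mediator, value``.
        ``value`` is a non-negative float; ``NaN`` marks an explicit missing
        measurement.
    groups
        Map from subject identifier to group/condition label.
    mediators
        Ordered list of mediator names; defines node order downstream.
    time_unit
        ``"day"`` or ``"hour"``.
    """

    data: pd.DataFrame
    groups: dict[str, str]
    mediators: list[str]
    time_unit: str = "day"
    load_report: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing_cols = [c for c in ("subject", "time", "mediator", "value") if c not in df.columns]
        if missing_cols:
            raise ValueError(f"panel data lacks columns {missing_cols}")
        if self.time_unit not in ("day", "hour"):
            raise ValueError(f"time_unit must be 'day' or 'hour', got {self.time_unit!r}")
        if len(self.mediators) != len(set(self.mediators)):
            raise ValueError("duplicate mediator names in mediator list")
        unknown = set(df["mediator"]) - set(self.mediators)
        if unknown:
            raise ValueError(f"observations reference mediators not in the list: {sorted(unknown)}")
        unlabeled = set(df["subject"]) - set(self.groups)
        if unlabeled:
            raise ValueError(f"subjects without a group label: {sorted(unlabeled)}")
        dup = df.duplicated(subset=["subject", "time", "mediator"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["subject", "time", "mediator"]]
            raise ValueError(
                "duplicate (subject, time, mediator) triple: "
                f"({first['subject']!r}, {first['time']!r}, {first['mediator']!r})"
            )
        vals = df["value"].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            bad = df.loc[df["value"] < 0].iloc[0]
            raise ValueError(
                f"negative concentration for {bad['mediator']!r} "
                f"(subject {bad['subject']!r}, t={bad['time']!r}): {bad['value']}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.data["subject"]))

    def group_subjects(self, group: str) -> list[str]:
        subs = sorted(s for s, g in self.groups.items() if g == group)
        if not subs:
            raise ValueError(f"unknown or empty group {group!r}")
        return subs

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    def restrict_group(self, group: str) -> "MediatorPanel":
        """The sub-panel holding only one group's subjects."""
        subs = set(self.group_subjects(group))
        data = self.data[self.data["subject"].isin(subs)].reset_index(drop=True)
        groups = {s: g for s, g in self.groups.items() if s in subs}
        return MediatorPanel(data, groups, list(self.mediators), self.time_unit)

    def copy(self) -> "MediatorPanel":
        return MediatorPanel(
            data=self.data.copy(),
            groups=dict(self.groups),
            mediators=list(self.mediators),
            time_unit=self.time_unit,
        )

    def write_report(self, path) -> None:
        """Write the JSON load/validation report."""
        report = dict(self.load_report)
        report.update(
            n_rows=int(len(self.data)),
            n_subjects=len(self.subjects),
            n_mediators=len(self.mediators),
            n_missing=int(self.data["value"].isna().sum()),
            groups={g: sum(1 for x in self.groups.values() if x == g) for g in self.group_names},
        )
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)


def _coerce_numeric(series: pd.Series) -> pd.Series:
    # unparseable cells become explicit missing values (NaN)
    return pd.to_numeric(series, errors="coerce")


def load_panel(path, layout: str, time_unit: str = "day") -> MediatorPanel:
    """Read a mediator panel from CSV.

    ``layout="wide"``: one row per (subject, time), columns
    ``subject, time, group, <mediator 1>, <mediator 2>, ...``.
    ``layout="long"``: columns ``subject, time, mediator, value, group``.

    Unparseable numeric cells become explicit missing values.  Duplicate
    (subject, time, mediator) triples are a hard error naming the triple.
    """
    if layout == "wide":
        raw = pd.read_csv(path, dtype={"subject": str})
        needed = {"subject", "time", "group"}
        if not needed <= set(raw.columns):
            raise ValueError(f"wide CSV must have columns {sorted(needed)}")
        mediators = [c for c in raw.columns if c not in needed]
        groups = _extract_groups(raw)
        long = raw.melt(
            id_vars=["subject", "time"],
            value_vars=mediators,
            var_name="mediator",
            value_name="value",
        )
    elif layout == "long":
        raw = pd.read_csv(path, dtype={"subject": str, "mediator": str})
        needed = set(LONG_COLUMNS)
        if not needed <= set(raw.columns):
            raise ValueError(f"long CSV must have columns {sorted(needed)}")
        groups = _extract_groups(raw)
        mediators = list(pd.unique(raw["mediator"]))
        long = raw[["subject", "time", "mediator", "value"]].copy()
    else:
        raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")

    long["time"] = _coerce_numeric(long["time"])
    long["value"] = _coerce_numeric(long["value"])
    long = long.reset_index(drop=True)

    panel = MediatorPanel(long, groups, list(mediators), time_unit)
    panel.load_report = {
        "path": str(path),
        "layout": layout,
        "rows_read": int(len(raw)),
        "observations": int(len(long)),
        "missing_cells": int(long["value"].isna().sum()),
        "subjects": len(panel.subjects),
    }
    logger.info(
        "loaded %s (%s): %d rows, %d subjects, %d missing cells",
        path, layout, len(raw), len(panel.subjects), panel.load_report["missing_cells"],
    )
    return panel


def _extract_groups(df: pd.DataFrame) -> dict[str, str]:
    pairs = df[["subject", "group"]].drop_duplicates()
    conflicted = pairs["subject"].duplicated()
    if conflicted.any():
        bad = pairs.loc[conflicted, "subject"].iloc[0]
        raise ValueError(f"subject {bad!r} carries conflicting group labels")
    return dict(zip(pairs["subject"].astype(str), pairs["group"].astype(str)))


def save_panel(panel: MediatorPanel, path, layout: str = "long") -> None:
    """Write the panel back to CSV in the same dialects ``load_panel`` reads."""
    if layout == "long":
        out = panel.data.copy()
        out["group"] = out["subject"].map(panel.groups)
        out[LONG_COLUMNS].to_csv(path, index=False)
    elif layout == "wide":
        wide = panel.data.pivot(index=["subject", "time"], columns="mediator", values="value")
        wide = wide.reindex(columns=panel.mediators).reset_index()
        wide.insert(2, "group", wide["subject"].map(panel.groups))
        wide.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def filter_min_samples(panel: MediatorPanel, min_times: int) -> MediatorPanel:
    """Retain subjects with >= ``min_times`` distinct observed time points.

    A time point counts when the subject has at least one non-missing
    mediator value there.  Mirrors the cohort inclusion rule of at least
    three daily samples per subject.  Idempotent; an empty result is legal.
    """
    if min_times < 1:
        raise ValueError("min_times must be >= 1")
    present = panel.data.dropna(subset=["value"])
    counts = present.groupby("subject")["time"].nunique()
    keep = set(counts.index[counts >= min_times])
    dropped = set(panel.subjects) - keep
    if dropped:
        logger.info("filter_min_samples(%d): dropped %d subjects", min_times, len(dropped))
    data = panel.data[panel.data["subject"].isin(keep)].reset_index(drop=True)
    groups = {s: g for s, g in panel.groups.items() if s in keep}
    if data.empty:
        logger.warning("filter_min_samples(%d): no subjects retained", min_times)
    return MediatorPanel(data, groups, list(panel.mediators), panel.time_unit)


def background_correct(
    panel: MediatorPanel, mediator: str, blank_values: list[float]
) -> MediatorPanel:
    """Subtract the mean blank signal from one mediator, clamping at zero.

    Used e.g. for HMGB1 in cell-culture supernatants, where serum-containing
    medium itself carries an HMGB1-like ELISA signal.  Other mediators are
    untouched; missing values stay missing.
    """
    if mediator not in panel.mediators:
        raise ValueError(f"mediator {mediator!r} not in panel")
    if not len(blank_values):
        raise ValueError("blank_values must be non-empty")
    correction = float(np.mean(blank_values))
    data = panel.data.copy()
    mask = data["mediator"] == mediator
    data.loc[mask, "value"] = (data.loc[mask, "value"] - correction).clip(lower=0.0)
    return MediatorPanel(data, dict(panel.groups), list(panel.mediators), panel.time_unit)


def window_observations(
    panel: MediatorPanel, window: TimeWindow, subjects: list[str] | None = None
) -> pd.DataFrame:
    """Observations whose time t satisfies start <= t <= end.

    Both endpoints are included, so a boundary sample enters both adjacent
    windows of a schedule.  Rows are ordered deterministically by
    (subject, time, mediator).
    """
    df = panel.data
    mask = (df["time"] >= window.start) & (df["time"] <= window.end)
    if subjects is not None:
        mask &= df["subject"].isin(subjects)
    out = df.loc[mask].sort_values(["subject", "time", "mediator"], kind="mergesort")
    return out.reset_index(drop=True)
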