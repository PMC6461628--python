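"""Dynamic Bayesian network inference over discretized mediator time courses.

A first-order DBN is learned from short multi-subject series: each mediator
at time t may depend on a set of mediators at time t-1 (its own lag
included, so self-feedback loops are candidate structure like any other
edge).  Mediators inferred to drive their own expression — self-feedback —
are the network's central nodes.

The engine is deliberately simple and fully reproducible:

* per-mediator quantile discretization (default 3 levels) over the group's
  pooled observations;
* transitions only between strictly consecutive observed time steps of the
  same subject (series are never concatenated across subjects, and a gap
  produces no transition; a gap-tolerant option exists but defaults off);
* Bayesian–Dirichlet-equivalent (BDeu) family scoring with a uniform
  structure prior;
* per-child greedy parent-set search (add/remove one parent, best strict
  improvement, local optimum) with random restarts;
* per-edge confidence from subject-level bootstrap resampling.

Edges carry no sign: the model scores dependence, not direction of effect.
Seeds are explicit arguments everywhere randomness exists; there is no
global RNG state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MediatorPanel

logger = logging.getLogger("inflamnet")

DEFAULT_LEVELS = 3
DEFAULT_MAX_PARENTS = 3
DEFAULT_RESTARTS = 10
DEFAULT_ESS = 1.0  # equivalent sample size of the BDeu prior

MISSING = -1  # sentinel level for a missing measurement

__all__ = [
    "DiscretizedPanel",
    "TransitionTable",
    "DbnModel",
    "discretize",
    "build_transitions",
    "score_family",
    "learn_structure",
    "edge_confidence",
    "infer_dbn",
    "self_feedback_nodes",
    "write_edge_table",
    "write_model_json",
]


@dataclass
class DiscretizedPanel:
    """Long table of discrete levels plus the bin edges that produced them."""

    data: pd.DataFrame  # columns subject, time, mediator, level (NaN = missing)
    mediators: list[str]
    groups: dict[str, str]
    bin_edges: dict[str, list[float]]
    n_levels: dict[str, int]


@dataclass
class TransitionTable:
    """Rows of (subject, t-1 level vector, t level vector), MISSING = -1."""

    mediators: list[str]
    subjects: list[str]  # one entry per row
    prev: np.ndarray  # (rows, n) int
    nxt: np.ndarray  # (rows, n) int
    n_levels: dict[str, int]

    def __len__(self) -> int:
        return self.prev.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"prev_{m}": self.prev[:, i] for i, m in enumerate(self.mediators)}
        cols.update({f"next_{m}": self.nxt[:, i] for i, m in enumerate(self.mediators)})
        return pd.DataFrame({"subject": self.subjects, **cols})


@dataclass
class DbnModel:
    """Learned directed structure: lagged parents (t-1) -> child (t)."""

    mediators: list[str]
    edges: set[tuple[str, str]]  # (parent, child); parent == child is a self-loop
    confidence: dict[tuple[str, str], float] = field(default_factory=dict)
    score: float = float("nan")
    config: dict = field(default_factory=dict)

    @property
    def self_loops(self) -> set[str]:
        return {p for p, c in self.edges if p == c}

    def parents(self, child: str) -> set[str]:
        return {p for p, c in self.edges if c == child}


# -- discretization ------------------------------------------------------------


def discretize(panel: MediatorPanel, levels: int = DEFAULT_LEVELS) -> DiscretizedPanel:
    """Quantile-bin each mediator over the panel's pooled observations.

    A mediator with fewer distinct values than ``levels`` falls back to
    fewer bins (a constant mediator ends up in a single bin 0); bin edges
    are recorded for reproducibility.  Missing values stay missing.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    data = panel.data.copy()
    data["level"] = np.nan
    bin_edges: dict[str, list[float]] = {}
    n_levels: dict[str, int] = {}
    for m in panel.mediators:
        mask = (data["mediator"] == m) & data["value"].notna()
        vals = data.loc[mask, "value"]
        if vals.empty:
            bin_edges[m] = []
            n_levels[m] = 1
            continue
        codes, bins = pd.qcut(vals, q=levels, labels=False, retbins=True, duplicates="drop")
        k = len(bins) - 1
        if k < 1:  # constant mediator: one bin
            codes, k, bins = pd.Series(0, index=vals.index), 1, np.array([vals.iloc[0]] * 2)
        if k < levels:
            logger.debug("mediator %s: %d bins instead of %d (ties)", m, k, levels)
        data.loc[mask, "level"] = codes.astype(float)
        bin_edges[m] = [float(b) for b in bins]
        n_levels[m] = int(k)
    out = data[["subject", "time", "mediator", "level"]]
    return DiscretizedPanel(out, list(panel.mediators), dict(panel.groups), bin_edges, n_levels)


def build_transitions(
    dpanel: DiscretizedPanel,
    group: str,
    step: float = 1.0,
    gap_tolerant: bool = False,
) -> TransitionTable:
    """One row per consecutive (t-1, t) observation pair per subject.

    ``step`` is the nominal sampling interval; by default a pair of
    observed times forms a transition only when exactly one step apart, so
    gaps (e.g. a missing day) produce no row.  With ``gap_tolerant=True``
    any consecutive pair of observed times is treated as one step.
    """
    subjects = sorted(s for s, g in dpanel.groups.items() if g == group)
    if not subjects:
        raise ValueError(f"unknown or empty group {group!r}")
    mediators = dpanel.mediators
    present = dpanel.data.dropna(subset=["level"])
    wide = present.pivot(index=["subject", "time"], columns="mediator", values="level")
    wide = wide.reindex(columns=mediators)

    rows_prev, rows_next, row_subjects = [], [], []
    for s in subjects:
        if s not in wide.index.get_level_values("subject"):
            continue
        block = wide.loc[s].sort_index()
        times = block.index.to_numpy(dtype=float)
        mat = block.to_numpy(dtype=float)
        for k in range(len(times) - 1):
            if gap_tolerant or np.isclose(times[k + 1] - times[k], step):
                rows_prev.append(mat[k])
                rows_next.append(mat[k + 1])
                row_subjects.append(s)
    if rows_prev:
        prev = np.nan_to_num(np.asarray(rows_prev), nan=MISSING).astype(int)
        nxt = np.nan_to_num(np.asarray(rows_next), nan=MISSING).astype(int)
    else:
        prev = np.empty((0, len(mediators)), dtype=int)
        nxt = np.empty((0, len(mediators)), dtype=int)
    return TransitionTable(list(mediators), row_subjects, prev, nxt, dict(dpanel.n_levels))


# -- scoring -------------------------------------------------------------------


def score_family(
    child: str,
    parents: set[str] | frozenset[str],
    table: TransitionTable,
    ess: float = DEFAULT_ESS,
) -> float:
    """BDeu marginal-likelihood score of ``child`` given lagged ``parents``.

    Higher is better; the score is decomposable over children and invariant
    under relabeling of discrete levels.  Rows where the child's next value
    or any parent's previous value is missing are excluded.
    """
    if len(table) == 0:
        raise ValueError("empty transition table")
    idx = {m: i for i, m in enumerate(table.mediators)}
    ci = idx[child]
    pidx = [idx[p] for p in sorted(parents)]
    r = max(table.n_levels[child], 1)

    keep = table.nxt[:, ci] != MISSING
    for pi in pidx:
        keep &= table.prev[:, pi] != MISSING
    y = table.nxt[keep, ci]
    if y.size == 0:
        return -np.inf

    # encode each parent configuration as a single integer code
    q = 1
    code = np.zeros(y.size, dtype=np.int64)
    for pi in pidx:
        k = max(table.n_levels[table.mediators[pi]], 1)
        code = code * k + table.prev[keep, pi]
        q *= k

    joint = code * r + y
    n_jk = np.bincount(joint, minlength=q * r).reshape(q, r)
    n_j = n_jk.sum(axis=1)
    a_jk = ess / (q * r)
    a_j = ess / q
    occupied = n_j > 0
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j[occupied]))
        + np.sum(gammaln(a_jk + n_jk[occupied]) - gammaln(a_jk))
    )
    return score


# -- structure search ----------------------------------------------------------


def _greedy_child(
    child: str,
    table: TransitionTable,
    max_parents: int,
    restarts: int,
    rng: np.random.Generator,
    ess: float,
) -> tuple[frozenset[str], float]:
    """Best-of-restarts greedy parent-set search for one child."""
    candidates = list(table.mediators)
    cache: dict[frozenset, float] = {}

    def score(ps: frozenset) -> float:
        if ps not in cache:
            cache[ps] = score_family(child, ps, table, ess)
        return cache[ps]

    best_set, best_score = frozenset(), score(frozenset())
    for restart in range(restarts):
        if restart == 0:
            current: frozenset = frozenset()
        else:
            size = int(rng.integers(0, min(max_parents, len(candidates)) + 1))
            current = frozenset(rng.choice(candidates, size=size, replace=False))
        current_score = score(current)
        while True:
            moves: list[frozenset] = []
            if len(current) < max_parents:
                moves += [current | {c} for c in candidates if c not in current]
            moves += [current - {p} for p in current]
            scored = [(score(m), m) for m in moves]
            if not scored:
                break
            # deterministic tie-break: highest score, then canonical set order
            top_score, top_set = max(scored, key=lambda t: (t[0], sorted(t[1])))
            if top_score > current_score:
                current, current_score = top_set, top_score
            else:
                break
        if current_score > best_score or (
            current_score == best_score and sorted(current) < sorted(best_set)
        ):
            best_set, best_score = current, current_score
    return best_set, best_score


def learn_structure(
    table: TransitionTable,
    max_parents: int = DEFAULT_MAX_PARENTS,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    ess: float = DEFAULT_ESS,
) -> DbnModel:
    """Learn the most likely single first-order structure from transitions.

    Each child's parent set is searched independently (the score is
    decomposable), greedily, with ``restarts`` random initial sets; every
    accepted move strictly increases the family score.  Deterministic given
    the seed.  Self-loops (a child's own lag) are candidate parents like
    any other mediator.
    """
    if len(table) == 0:
        raise ValueError("empty transition table")
    edges: set[tuple[str, str]] = set()
    total = 0.0
    for j, child in enumerate(table.mediators):
        rng = np.random.default_rng([seed % (2**31), j])
        parents, fam_score = _greedy_child(child, table, max_parents, restarts, rng, ess)
        total += fam_score
        edges.update((p, child) for p in parents)
    model = DbnModel(
        mediators=list(table.mediators),
        edges=edges,
        confidence={e: 1.0 for e in edges},
        score=total,
        config={
            "max_parents": max_parents,
            "restarts": restarts,
            "seed": seed,
            "ess": ess,
        },
    )
    return model


# -- bootstrap confidence ------------------------------------------------------


def _resample_panel(panel: MediatorPanel, group: str, rng: np.random.Generator) -> MediatorPanel:
    """Subject-level bootstrap: resample the group's subjects with replacement."""
    subjects = panel.group_subjects(group)
    draw = rng.choice(subjects, size=len(subjects), replace=True)
    frames, groups = [], {}
    for k, s in enumerate(draw):
        block = panel.data[panel.data["subject"] == s].copy()
        alias = f"{s}#bs{k}"
        block["subject"] = alias
        groups[alias] = group
        frames.append(block)
    data = pd.concat(frames, ignore_index=True)
    return MediatorPanel(data, groups, list(panel.mediators), panel.time_unit)


def edge_confidence(
    panel: MediatorPanel,
    group: str,
    n_boot: int = 100,
    seed: int = 0,
    levels: int = DEFAULT_LEVELS,
    max_parents: int = DEFAULT_MAX_PARENTS,
    restarts: int = DEFAULT_RESTARTS,
    ess: float = DEFAULT_ESS,
    step: float = 1.0,
    gap_tolerant: bool = False,
) -> dict[tuple[str, str], float]:
    """Fraction of subject-bootstrap resamples in which each edge is learned.

    The full pipeline (discretization, transitions, structure search) is
    re-run on every resample, so the confidence reflects the whole
    procedure's stability, not just the final search.  Reproducible given
    the seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    counts: dict[tuple[str, str], int] = {}
    rng = np.random.default_rng(seed % (2**31))
    for b in range(n_boot):
        resampled = _resample_panel(panel, group, rng)
        d = discretize(resampled, levels)
        table = build_transitions(d, group, step=step, gap_tolerant=gap_tolerant)
        if len(table) == 0:
            continue
        model = learn_structure(table, max_parents, restarts, seed=seed + 1 + b, ess=ess)
        for e in model.edges:
            counts[e] = counts.get(e, 0) + 1
    return {e: c / n_boot for e, c in counts.items()}


def infer_dbn(
    panel: MediatorPanel,
    group: str,
    levels: int = DEFAULT_LEVELS,
    max_parents: int = DEFAULT_MAX_PARENTS,
    restarts: int = DEFAULT_RESTARTS,
    n_boot: int = 0,
    seed: int = 0,
    ess: float = DEFAULT_ESS,
    step: float = 1.0,
    gap_tolerant: bool = False,
) -> DbnModel:
    """End-to-end DBN inference for one group; optional bootstrap confidence.

    With ``n_boot > 0`` the point-estimate structure is annotated with
    subject-bootstrap confidences (edges never seen in a resample get 0).
    Discretization bins are computed from the group's own pooled
    observations, not the whole panel's.
    """
    d = discretize(panel.restrict_group(group), levels)
    table = build_transitions(d, group, step=step, gap_tolerant=gap_tolerant)
    model = learn_structure(table, max_parents, restarts, seed=seed, ess=ess)
    model.config.update(levels=levels, n_boot=n_boot, group=group)
    if n_boot > 0:
        conf = edge_confidence(
            panel, group, n_boot=n_boot, seed=seed, levels=levels,
            max_parents=max_parents, restarts=restarts, ess=ess,
            step=step, gap_tolerant=gap_tolerant,
        )
        model.confidence = {e: conf.get(e, 0.0) for e in model.edges}
    return model


def self_feedback_nodes(model: DbnModel, min_confidence: float = 0.0) -> list[str]:
    """Central nodes: mediators with a self-feedback loop at sufficient confidence.

    Sorted by confidence descending (ties broken by name for determinism).
    """
    hits = [
        (model.confidence.get((m, m), 0.0), m)
        for m in model.self_loops
        if model.confidence.get((m, m), 0.0) >= min_confidence
    ]
    return [m for _, m in sorted(hits, key=lambda t: (-t[0], t[1]))]


# -- export --------------------------------------------------------------------


def write_edge_table(model: DbnModel, path) -> None:
    """CSV edge table: parent, child, confidence, self_loop."""
    rows = [
        (p, c, model.confidence.get((p, c), float("nan")), p == c)
        for p, c in sorted(model.edges)
    ]
    pd.DataFrame(rows, columns=["parent", "child", "confidence", "self_loop"]).to_csv(
        path, index=False
    )


def write_model_json(model: DbnModel, path, bin_edges: dict | None = None) -> None:
    payload = {
        "mediators": model.mediators,
        "edges": [list(e) for e in sorted(model.edges)],
        "confidence": {f"{p}->{c}": v for (p, c), v in sorted(model.confidence.items())},
        "score": model.score,
        "config": model.config,
    }
    if bin_edges is not None:
        payload["bin_edges"] = bin_edges
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
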