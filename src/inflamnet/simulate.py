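"""Synthetic mediator cohorts with planted dynamic network structure.

Cohorts are generated from a latent log-scale first-order autoregressive
system per subject:

    x(t) = A x(t-1) + eps,    eps ~ Normal(0, noise_sigma^2 I)

where ``x`` is the vector of log-concentrations relative to each mediator's
baseline and ``A`` is a signed coupling matrix (the planted ground truth).
Observed concentrations are ``baseline * exp(x)`` — positive and
right-skewed with multiplicative assay noise, like multiplex
cytokine/chemokine panel data.  Hub mediators carry a self-weight on the
diagonal of ``A`` (self-feedback), giving them persistent, subject-specific
trajectories that their targets track; a negative coupling plants an
anti-correlated pair.  Per-window coupling overrides let a group gain extra
co-movement only inside chosen time windows.

Samples are deleted at ``missing_rate`` per (subject, time); a subject
whose surviving samples fall below the minimum-samples inclusion rule has
its missingness mask redrawn, so every emitted subject satisfies the rule.
Everything is reproducible bit-for-bit from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panel import (
    HUMAN_DAILY_SCHEDULE,
    MOUSE_HOURS_SCHEDULE,
    MediatorPanel,
    TimeWindow,
)

__all__ = [
    "HUMAN_MEDIATORS",
    "MOUSE_MEDIATORS",
    "GroupSpec",
    "SyntheticSpec",
    "SyntheticCohort",
    "hub_adjacency",
    "coupled_pairs_adjacency",
    "planted_pairs",
    "generate_cohort",
    "hub_demo_spec",
    "generate_paperlike_presets",
]

#: 25-plex human serum panel; HMGB1 (ELISA) and nitrite/nitrate appended.
HUMAN_MEDIATORS: list[str] = [
    "Eotaxin", "GM-CSF", "IFN-a2", "IFN-g", "IL-1b", "IL-1RA", "IL-2",
    "sIL-2Ra", "IL-4", "IL-5", "IL-6", "IL-7", "IL-8", "IL-10", "IL-12p40",
    "IL-12p70", "IL-13", "IL-15", "IL-17A", "IP-10", "MCP-1", "MIG",
    "MIP-1a", "MIP-1b", "TNF-a", "HMGB1", "NO2-+NO3-",
]

#: 20-plex mouse supernatant panel; HMGB1 and nitrite/nitrate appended.
MOUSE_MEDIATORS: list[str] = [
    "GM-CSF", "IFN-g", "IL-1a", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6",
    "IL-10", "IL-12p40", "IL-12p70", "IL-13", "IL-17", "IP-10", "KC",
    "MCP-1", "MIG", "MIP-1a", "TNF-a", "VEGF", "HMGB1", "NO2-+NO3-",
]

DEFAULT_NOISE_SIGMA = 0.1  # log-scale innovation sd, ~10% multiplicative assay CV
DEFAULT_BASELINE = 100.0  # pg/ml
DEFAULT_SELF_WEIGHT = 0.95  # hub self-feedback (AR coefficient)
DEFAULT_COUPLING = 0.9
BURN_IN_STEPS = 25  # enough for |eigenvalue| 0.95 dynamics to near stationarity


@dataclass
class GroupSpec:
    """One group/condition: size, planted coupling, hub set, window overrides."""

    name: str
    n_subjects: int
    adjacency: np.ndarray  # (n, n); adjacency[i, j] = weight of j(t-1) on i(t)
    self_drive: set[str] = field(default_factory=set)
    window_modifiers: list[tuple[TimeWindow, np.ndarray]] = field(default_factory=list)


@dataclass
class SyntheticSpec:
    """Full parameterization of a simulated cohort, with ground truth attached."""

    mediators: list[str]
    groups: list[GroupSpec]
    times: list[float]
    time_unit: str = "day"
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    baseline: float = DEFAULT_BASELINE
    missing_rate: float = 0.0
    min_samples: int = 3
    detection_limit: float | None = None
    seed: int = 0

    def validate(self) -> None:
        n = len(self.mediators)
        if len(set(self.mediators)) != n:
            raise ValueError("duplicate mediator names")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.min_samples > len(self.times):
            raise ValueError("min_samples exceeds the number of nominal time points")
        for g in self.groups:
            if g.n_subjects < 1:
                raise ValueError(f"group {g.name!r}: n_subjects must be >= 1")
            for mat in [g.adjacency] + [m for _, m in g.window_modifiers]:
                if mat.shape != (n, n):
                    raise ValueError(f"group {g.name!r}: adjacency shape {mat.shape} != ({n},{n})")
                if np.max(np.abs(mat)) > 1.0:
                    raise ValueError(f"group {g.name!r}: coupling magnitudes must be <= 1")
            unknown = g.self_drive - set(self.mediators)
            if unknown:
                raise ValueError(f"group {g.name!r}: unknown hub mediators {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        payload = {
            "mediators": self.mediators,
            "times": [float(t) for t in self.times],
            "time_unit": self.time_unit,
            "noise_sigma": self.noise_sigma,
            "baseline": self.baseline,
            "missing_rate": self.missing_rate,
            "min_samples": self.min_samples,
            "seed": self.seed,
            "groups": [
                {
                    "name": g.name,
                    "n_subjects": g.n_subjects,
                    "self_drive": sorted(g.self_drive),
                    "adjacency": g.adjacency.tolist(),
                    "window_modifiers": [
                        {"window": [w.label, w.start, w.end], "adjacency": m.tolist()}
                        for w, m in g.window_modifiers
                    ],
                }
                for g in self.groups
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    """A generated panel plus the planted truth it was generated from."""

    panel: MediatorPanel
    truth_adjacency: dict[str, np.ndarray]
    truth_window_modifiers: dict[str, list[tuple[TimeWindow, np.ndarray]]]
    truth_self_loops: dict[str, set[str]]


# -- adjacency builders --------------------------------------------------------


def hub_adjacency(
    mediators: list[str],
    hub: str,
    targets: list[str],
    coupling: float = DEFAULT_COUPLING,
    self_weight: float = DEFAULT_SELF_WEIGHT,
) -> np.ndarray:
    """Hub motif: ``hub`` drives its own expression and each target.

    Because the hub's trajectory is persistent (self-weight close to 1),
    targets coupled to its lag co-move with it — and with each other —
    inside any window, which is exactly the structure DyNA detects.
    """
    n = len(mediators)
    idx = {m: i for i, m in enumerate(mediators)}
    a = np.zeros((n, n))
    a[idx[hub], idx[hub]] = self_weight
    for t, c in zip(targets, np.broadcast_to(coupling, (len(targets),))):
        if t == hub:
            raise ValueError("hub cannot be its own target")
        a[idx[t], idx[hub]] = c
    return a


def coupled_pairs_adjacency(
    mediators: list[str],
    pairs: list[tuple[str, str, float]],
    self_weight: float = DEFAULT_SELF_WEIGHT,
) -> np.ndarray:
    """Plant independent correlated pairs: each (driver, follower, coupling).

    The driver gets a self-weight; the follower tracks the driver's lag with
    the given (possibly negative) coupling.
    """
    n = len(mediators)
    idx = {m: i for i, m in enumerate(mediators)}
    a = np.zeros((n, n))
    for driver, follower, c in pairs:
        a[idx[driver], idx[driver]] = self_weight
        a[idx[follower], idx[driver]] = c
    return a


def planted_pairs(adjacency: np.ndarray, mediators: list[str]) -> set[frozenset]:
    """Unordered mediator pairs with a planted off-diagonal coupling."""
    out: set[frozenset] = set()
    for i, j in zip(*np.nonzero(adjacency)):
        if i != j:
            out.add(frozenset((mediators[i], mediators[j])))
    return out


# -- generation ----------------------------------------------------------------


def _adjacency_at(group: GroupSpec, t: float) -> np.ndarray:
    for window, mat in group.window_modifiers:
        if window.contains(t):
            return mat
    return group.adjacency


def _simulate_subject(
    spec: SyntheticSpec, group: GroupSpec, rng: np.random.Generator
) -> np.ndarray:
    """Latent log-trajectory (T, n) for one subject."""
    n = len(spec.mediators)
    times = spec.times
    # subjects enter observation mid-process: burn the base system in so the
    # first sampled time already carries the stationary joint structure
    # (spread AND cross-correlation), not an uncoupled reset state
    x0 = rng.normal(0.0, spec.noise_sigma, size=n)
    for _ in range(BURN_IN_STEPS):
        x0 = group.adjacency @ x0 + rng.normal(0.0, spec.noise_sigma, size=n)
    x = np.empty((len(times), n))
    x[0] = x0
    for k in range(1, len(times)):
        a = _adjacency_at(group, times[k])
        x[k] = a @ x[k - 1] + rng.normal(0.0, spec.noise_sigma, size=n)
    return x


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Simulate a full cohort from the spec; bit-identical for a given seed."""
    spec.validate()
    times = [float(t) for t in spec.times]
    rows: list[tuple] = []
    groups_map: dict[str, str] = {}
    for gi, group in enumerate(spec.groups):
        for si in range(group.n_subjects):
            subject = f"{group.name}-{si + 1:02d}"
            rng = np.random.default_rng([spec.seed % (2**31), gi, si])
            x = _simulate_subject(spec, group, rng)
            obs = spec.baseline * np.exp(x)
            if spec.detection_limit is not None:
                obs = np.maximum(obs, spec.detection_limit)
            keep = _draw_sample_mask(rng, len(times), spec.missing_rate, spec.min_samples)
            groups_map[subject] = group.name
            for k, t in enumerate(times):
                if not keep[k]:
                    continue
                for mi, m in enumerate(spec.mediators):
                    rows.append((subject, t, m, obs[k, mi]))
    data = pd.DataFrame(rows, columns=["subject", "time", "mediator", "value"])
    panel = MediatorPanel(data, groups_map, list(spec.mediators), spec.time_unit)
    return SyntheticCohort(
        panel=panel,
        truth_adjacency={g.name: g.adjacency.copy() for g in spec.groups},
        truth_window_modifiers={g.name: list(g.window_modifiers) for g in spec.groups},
        truth_self_loops={g.name: set(g.self_drive) for g in spec.groups},
    )


def _draw_sample_mask(
    rng: np.random.Generator, n_times: int, missing_rate: float, min_samples: int
) -> np.ndarray:
    """Sample-level missingness, redrawn until the inclusion rule holds."""
    for _ in range(1000):
        keep = rng.random(n_times) >= missing_rate
        if keep.sum() >= min_samples:
            return keep
    return np.ones(n_times, dtype=bool)  # pathological missing_rate: keep all


# -- presets -------------------------------------------------------------------


def hub_demo_spec(
    n_subjects: int = 12,
    coupling: float = DEFAULT_COUPLING,
    seed: int = 0,
) -> tuple[SyntheticSpec, TimeWindow, list[str]]:
    """Small hub cohort: HMGB1 self-drive plus three targets, active in one window.

    The HMGB1 -> {IL-6, IL-8, IP-10} coupling is switched on only inside the
    d2-3 window; elsewhere only the hub's self-feedback runs.  Returns the
    spec, the active window, and the target list.
    """
    mediators = ["HMGB1", "IL-6", "IL-8", "IP-10", "TNF-a", "IL-10"]
    targets = ["IL-6", "IL-8", "IP-10"]
    base = hub_adjacency(mediators, "HMGB1", [], coupling)
    active_window = TimeWindow("d2-3", 2, 3)
    active = hub_adjacency(mediators, "HMGB1", targets, coupling)
    group = GroupSpec(
        name="hub",
        n_subjects=n_subjects,
        adjacency=base,
        self_drive={"HMGB1"},
        window_modifiers=[(active_window, active)],
    )
    spec = SyntheticSpec(
        mediators=mediators,
        groups=[group],
        times=list(range(8)),
        seed=seed,
    )
    return spec, active_window, targets


def _human_group(name: str, n: int, k_targets: int, extra_windows: int = 0) -> GroupSpec:
    """Hub-structured human group; denser groups couple more targets to HMGB1."""
    meds = HUMAN_MEDIATORS
    others = [m for m in meds if m != "HMGB1"]
    base = hub_adjacency(meds, "HMGB1", others[:k_targets])
    modifiers = []
    if extra_windows:
        # extra co-movement in the d1-2 and d2-3 windows only
        dense = hub_adjacency(meds, "HMGB1", others[: k_targets + extra_windows])
        modifiers = [(TimeWindow("d1-2", 1, 2), dense), (TimeWindow("d2-3", 2, 3), dense)]
    return GroupSpec(name, n, base, {"HMGB1"}, modifiers)


def generate_paperlike_presets(seed: int = 0) -> tuple[SyntheticSpec, SyntheticSpec]:
    """The two study designs as synthetic specs.

    Preset A: four human serum groups (13 / 8 / 40 / 12 subjects) on the
    daily d0-d7 grid; the non-survivor group carries the densest coupling
    plus extra co-movement in the d1-2/d2-3 windows, and the
    non-APAPo/non-NAC group the sparsest.  Preset B: four in-vitro
    hepatocyte conditions (Control, APAP, NAC, APAP+NAC) on the 1/3/6/24 h
    grid; APAP+NAC mixes in negative couplings so anti-correlated edges
    appear, and the untreated/NAC conditions are sparse.
    """
    human = SyntheticSpec(
        mediators=list(HUMAN_MEDIATORS),
        groups=[
            _human_group("APAPo+NAC", 13, k_targets=12),
            _human_group("non-APAPo+NAC", 8, k_targets=12),
            _human_group("non-APAPo non-NAC", 40, k_targets=6),
            _human_group("non-survivor", 12, k_targets=14, extra_windows=6),
        ],
        times=list(range(8)),
        time_unit="day",
        missing_rate=0.25,
        min_samples=3,
        seed=seed,
    )

    meds = MOUSE_MEDIATORS
    others = [m for m in meds if m != "HMGB1"]

    def mouse_group(name: str, n: int, k_pos: int, k_neg: int = 0) -> GroupSpec:
        coupling = np.array([DEFAULT_COUPLING] * k_pos + [-DEFAULT_COUPLING] * k_neg)
        a = hub_adjacency(meds, "HMGB1", others[: k_pos + k_neg], coupling)
        return GroupSpec(name, n, a, {"HMGB1"})

    mouse = SyntheticSpec(
        mediators=list(meds),
        groups=[
            mouse_group("Control", 12, k_pos=3),
            mouse_group("APAP", 3, k_pos=12),
            mouse_group("NAC", 9, k_pos=4),
            mouse_group("APAP+NAC", 3, k_pos=7, k_neg=4),
        ],
        times=[1.0, 3.0, 6.0, 24.0],
        time_unit="hour",
        missing_rate=0.0,
        min_samples=3,
        seed=seed,
    )
    return human, mouse
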