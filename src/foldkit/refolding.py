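"""Accelerated unfold/refold protocol on a coarse-grained chain model.

The protocol under study is a staged, instability-triggered cooling
schedule: denature a folded chain at a very high temperature, then
restart at an elevated temperature and step down a temperature ladder
whenever the packing metrics (sliding-window CA areas/volumes) start to
rise — a rise signals deterioration of packing, i.e. the current
temperature has become counter-productive.  The controller is engine-
agnostic; the bundled engine is a Gō-style structure-based model driven
by Metropolis Monte Carlo:

* one bead per residue at the CA position;
* harmonic virtual bonds between consecutive beads;
* attractive Lennard-Jones-style wells, with the minimum at the native
  distance, between native contacts (pairs |i-j| >= 3 closer than a
  cutoff in the reference structure);
* purely repulsive excluded volume between all other non-bonded pairs.

Because attraction exists only for native contacts the landscape is
funnelled towards the reference structure, which is what makes a
desk-scale refolding demonstration possible.  Temperatures are reduced
(dimensionless, in units of the contact well depth); the ladder maps
nominal Celsius-style stage labels to reduced temperatures via
configuration.  Progress is measured by the native-contact fraction Q
and by the packing metrics themselves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry_metrics import darvols_profile
from .structure_io import CATrace

logger = logging.getLogger("foldkit")

__all__ = [
    "ToyModel",
    "TemperatureLadder",
    "LadderStage",
    "InstabilityRule",
    "ProtocolTrace",
    "build_go_model",
    "total_energy",
    "acceptance_probability",
    "mc_run",
    "native_contact_fraction",
    "unfold_stage",
    "detect_instability",
    "run_refolding_protocol",
    "DEFAULT_LADDER",
    "DEFAULT_RULE",
    "HOT_TEMPERATURE",
]

# Engine defaults (energies in units of the contact well depth epsilon)
K_BOND = 10.0          # harmonic bond spring, eps/Å²
EPSILON = 1.0          # native-contact well depth
K_DIHEDRAL = 2.0       # native virtual-torsion stiffness, eps
SIGMA_EV = 4.0         # excluded-volume diameter, Å
EPS_NONNATIVE = 0.25   # depth of the weak non-native well, eps (see ToyModel)
SIGMA_MOVE = 0.3       # Gaussian single-bead proposal, Å
CONTACT_CUTOFF = 8.0   # native-contact distance cutoff, Å
Q_TOLERANCE = 1.2      # contact counted as formed below 1.2 x native distance
Q_UNFOLD = 0.2         # denaturation target
HOT_TEMPERATURE = 5.0  # reduced temperature of the denaturation stage


@dataclass
class ToyModel:
    """Gō-style structure-based chain model built from a native CA trace.

    Besides bonds, native-contact wells and excluded volume, the model
    carries a native virtual-torsion term, k_dih·(1 − cos(θ − θ_nat)) per
    four consecutive beads: pairwise distances alone cannot distinguish a
    fold from its mirror image, and without a chirality-resolving term
    the chain anneals into mixed-handedness traps instead of the
    reference fold.
    """

    native: np.ndarray                 # (N, 3) reference bead positions
    contacts: np.ndarray               # (M, 2) native-contact index pairs
    native_distances: np.ndarray       # (M,) native contact distances, Å
    bond_b0: float                     # virtual bond rest length, Å
    native_torsions: np.ndarray | None = None  # (N-3,) radians
    k_bond: float = K_BOND
    epsilon: float = EPSILON
    k_dih: float = K_DIHEDRAL
    sigma_ev: float = SIGMA_EV
    eps_nonnative: float = EPS_NONNATIVE

    @property
    def n_beads(self) -> int:
        return len(self.native)

    def __post_init__(self) -> None:
        # per-bead interaction tables for O(N) single-move energies
        n = self.n_beads
        self._contact_of = [[] for _ in range(n)]
        for (i, j), r0 in zip(self.contacts, self.native_distances):
            self._contact_of[i].append((int(j), float(r0)))
            self._contact_of[j].append((int(i), float(r0)))
        contact_set = {(int(i), int(j)) for i, j in self.contacts}
        self._repulsive_of = []
        for i in range(n):
            part = [
                j for j in range(n)
                if abs(i - j) >= 3
                and (min(i, j), max(i, j)) not in contact_set
            ]
            self._repulsive_of.append(np.array(part, dtype=int))
        self._contact_idx = [
            (np.array([j for j, _ in lst], dtype=int),
             np.array([r for _, r in lst], dtype=float))
            for lst in self._contact_of
        ]
        if self.native_torsions is None:
            self.native_torsions = _bead_torsions(self.native)


def build_go_model(reference: CATrace, contact_cutoff: float = CONTACT_CUTOFF) -> ToyModel:
    """Build the structure-based model from a native CA trace.

    Native contacts are pairs with |i-j| >= 3 whose native CA distance is
    below *contact_cutoff*; the virtual-bond rest length is the mean
    native consecutive-CA distance.
    """
    pts = np.asarray(reference.coords if isinstance(reference, CATrace) else reference,
                     dtype=float)
    n = len(pts)
    if n < 10:
        raise ValueError("structure-based model needs a reference of >= 10 residues")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    ii, jj = np.triu_indices(n, k=3)
    mask = d[ii, jj] < contact_cutoff
    contacts = np.stack([ii[mask], jj[mask]], axis=1)
    b0 = float(np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return ToyModel(
        native=pts.copy(),
        contacts=contacts,
        native_distances=d[ii[mask], jj[mask]],
        bond_b0=b0,
    )


def _bead_torsions(pts: np.ndarray) -> np.ndarray:
    """Signed virtual torsions (radians) of all four-bead windows."""
    b1 = pts[1:-2] - pts[:-3]
    b2 = pts[2:-1] - pts[1:-2]
    b3 = pts[3:] - pts[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    return np.arctan2(np.einsum("ij,ij->i", m, n2), np.einsum("ij,ij->i", n1, n2))


def _bond_energy(model: ToyModel, positions: np.ndarray) -> float:
    b = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    return float(model.k_bond * np.sum((b - model.bond_b0) ** 2))


def _lj_well(r: np.ndarray, r0: np.ndarray, eps: float) -> np.ndarray:
    x = (r0 / r) ** 6
    return eps * (x * x - 2.0 * x)


def total_energy(model: ToyModel, positions: np.ndarray) -> float:
    """Full from-scratch energy: bonds + torsions + native wells +
    excluded volume."""
    e = _bond_energy(model, positions)
    if model.n_beads >= 4 and model.k_dih:
        th = _bead_torsions(positions)
        e += float(model.k_dih * np.sum(1.0 - np.cos(th - model.native_torsions)))
    if len(model.contacts):
        i, j = model.contacts[:, 0], model.contacts[:, 1]
        r = np.linalg.norm(positions[i] - positions[j], axis=1)
        e += float(np.sum(_lj_well(r, model.native_distances, model.epsilon)))
    # non-native pairs: excluded volume plus optional weak attraction
    n = model.n_beads
    for i in range(n):
        js = model._repulsive_of[i]
        js = js[js > i]
        if len(js):
            r = np.linalg.norm(positions[js] - positions[i], axis=1)
            e += float(np.sum(_nonnative_energy(model, r)))
    return e


def _nonnative_energy(model: ToyModel, r: np.ndarray) -> np.ndarray:
    """Non-native pair energy: a 12-6 well of depth eps_nonnative at
    sigma_ev, reducing to pure (sigma/r)^12 repulsion when the depth is
    zero."""
    x = (model.sigma_ev / r) ** 6
    if model.eps_nonnative:
        return model.epsilon * x * x - 2.0 * model.eps_nonnative * x
    return model.epsilon * x * x


def _torsion_scalar(p0, p1, p2, p3) -> float:
    # scalar torsion (radians); hot path of the Monte-Carlo move
    b1x, b1y, b1z = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
    b2x, b2y, b2z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b3x, b3y, b3z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    n1x, n1y, n1z = b1y * b2z - b1z * b2y, b1z * b2x - b1x * b2z, b1x * b2y - b1y * b2x
    n2x, n2y, n2z = b2y * b3z - b2z * b3y, b2z * b3x - b2x * b3z, b2x * b3y - b2y * b3x
    nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    mx, my, mz = (
        (n1y * b2z - n1z * b2y) / nb2,
        (n1z * b2x - n1x * b2z) / nb2,
        (n1x * b2y - n1y * b2x) / nb2,
    )
    return math.atan2(mx * n2x + my * n2y + mz * n2z,
                      n1x * n2x + n1y * n2y + n1z * n2z)


def _torsion_energy_local(model: ToyModel, positions: np.ndarray, i: int,
                          xyz) -> float:
    n = model.n_beads
    lo = max(0, i - 3)
    hi = min(n - 4, i)
    if hi < lo:
        return 0.0
    e = 0.0
    nat = model.native_torsions
    for d in range(lo, hi + 1):
        pts = [xyz if d + k == i else positions[d + k] for k in range(4)]
        th = _torsion_scalar(*pts)
        e += 1.0 - math.cos(th - nat[d])
    return model.k_dih * e


def _bead_energy(model: ToyModel, positions: np.ndarray, i: int,
                 xyz: np.ndarray) -> float:
    """Energy of all interactions involving bead i when it sits at xyz."""
    e = 0.0
    if model.k_dih and model.n_beads >= 4:
        e += _torsion_energy_local(model, positions, i, xyz)
    if i > 0:
        b = np.linalg.norm(xyz - positions[i - 1])
        e += model.k_bond * (b - model.bond_b0) ** 2
    if i < model.n_beads - 1:
        b = np.linalg.norm(xyz - positions[i + 1])
        e += model.k_bond * (b - model.bond_b0) ** 2
    js, r0 = model._contact_idx[i]
    if len(js):
        r = np.linalg.norm(positions[js] - xyz, axis=1)
        e += float(np.sum(_lj_well(r, r0, model.epsilon)))
    js = model._repulsive_of[i]
    if len(js):
        r = np.linalg.norm(positions[js] - xyz, axis=1)
        e += float(np.sum(_nonnative_energy(model, r)))
    return e


def acceptance_probability(delta_e: float, reduced_t: float) -> float:
    """Metropolis rule: min(1, exp(-dE/T))."""
    if reduced_t <= 0:
        raise ValueError("reduced temperature must be positive")
    if delta_e <= 0:
        return 1.0
    return float(np.exp(-delta_e / reduced_t))


def mc_run(
    model: ToyModel,
    positions: np.ndarray,
    reduced_t: float,
    n_steps: int,
    seed: int,
    sigma_move: float = SIGMA_MOVE,
    return_energy: bool = False,
):
    """Metropolis Monte Carlo: *n_steps* single-bead Gaussian moves.

    Fully deterministic in *seed*.  The running total energy is updated
    incrementally from per-move differences; with ``return_energy=True``
    the (positions, incremental energy) pair is returned so callers can
    audit the bookkeeping against :func:`total_energy`.
    """
    if reduced_t <= 0:
        raise ValueError("reduced temperature must be positive")
    rng = np.random.default_rng(seed)
    pos = np.array(positions, dtype=float)
    energy = total_energy(model, pos)
    n = model.n_beads
    beads = rng.integers(0, n, size=n_steps)
    moves = rng.normal(0.0, sigma_move, size=(n_steps, 3))
    unif = rng.random(n_steps)
    for step in range(n_steps):
        i = int(beads[step])
        old = pos[i].copy()
        new = old + moves[step]
        de = _bead_energy(model, pos, i, new) - _bead_energy(model, pos, i, old)
        if de <= 0 or unif[step] < np.exp(-de / reduced_t):
            pos[i] = new
            energy += de
    if return_energy:
        return pos, energy
    return pos


def native_contact_fraction(model: ToyModel, positions: np.ndarray) -> float:
    """Fraction Q of native contacts currently within 1.2 x their native
    distance; 1 at the native state, near 0 when fully denatured."""
    if len(model.contacts) == 0:
        raise ValueError("model has no native contacts")
    i, j = model.contacts[:, 0], model.contacts[:, 1]
    r = np.linalg.norm(positions[i] - positions[j], axis=1)
    return float(np.mean(r < Q_TOLERANCE * model.native_distances))


# ---------------------------------------------------------------------------
# Protocol controller
# ---------------------------------------------------------------------------

@dataclass
class LadderStage:
    """One cooling stage: nominal label (°C), reduced temperature, and a
    maximum duration in snapshots."""

    label_c: float
    reduced_t: float
    max_snapshots: int

    def __post_init__(self) -> None:
        if self.max_snapshots <= 0:
            raise ValueError("stage duration must be positive")


@dataclass
class TemperatureLadder:
    """Ordered cooling stages plus the sampling interval.

    Stage labels and reduced temperatures must be strictly decreasing.
    ``snapshot_interval`` is the number of Monte-Carlo moves between
    saved snapshots.
    """

    stages: list[LadderStage]
    snapshot_interval: int = 1200

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("ladder must have at least one stage")
        labels = [s.label_c for s in self.stages]
        temps = [s.reduced_t for s in self.stages]
        if labels != sorted(labels, reverse=True) or len(set(labels)) != len(labels):
            raise ValueError("stage labels must be strictly decreasing")
        if temps != sorted(temps, reverse=True) or len(set(temps)) != len(temps):
            raise ValueError("reduced temperatures must be strictly decreasing")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot interval must be positive")


@dataclass
class InstabilityRule:
    """Packing-instability trigger: step down when the chosen metric has
    risen by more than *threshold* (relative) above its minimum over the
    trailing *window* snapshots."""

    window: int = 5
    threshold: float = 0.10
    metric: str = "either"  # mean_area | mean_volume | either

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2 snapshots")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.metric not in ("mean_area", "mean_volume", "either"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class ProtocolEvent:
    snapshot: int
    action: str   # "step_down" | "stop"
    reason: str


@dataclass
class ProtocolTrace:
    """Full record of a protocol run: positions, metrics and events."""

    snapshots: list[tuple[int, float, np.ndarray]] = field(default_factory=list)
    metrics: pd.DataFrame | None = None
    events: list[ProtocolEvent] = field(default_factory=list)
    completed: bool = True

    def final_positions(self) -> np.ndarray:
        return self.snapshots[-1][2]

    def final_q(self) -> float:
        return float(self.metrics["Q"].iloc[-1])


# The default ladder shape: one hot denaturation stage is handled by
# unfold_stage; the three cooling stages keep the classic 1.2 : 3.7 : 0.1
# duration proportions (here in snapshot counts) and map the nominal
# 300/200/100 °C labels onto reduced temperatures spanning the toy model's
# folding transition.
DEFAULT_LADDER = TemperatureLadder(
    stages=[
        LadderStage(300.0, 1.2, 24),
        LadderStage(200.0, 0.35, 74),
        LadderStage(100.0, 0.02, 2),
    ],
    snapshot_interval=1200,
)

DEFAULT_RULE = InstabilityRule(window=5, threshold=0.30, metric="mean_area")


def detect_instability(metric_series: Sequence[float], rule: InstabilityRule) -> bool:
    """True iff the metric's latest value exceeds the minimum over the
    trailing window by more than the rule's relative threshold."""
    series = np.asarray(metric_series, dtype=float)
    if len(series) < rule.window:
        raise ValueError(
            f"series of length {len(series)} shorter than window {rule.window}"
        )
    window = series[-rule.window:]
    lo = float(window.min())
    if lo <= 0:
        return False
    return (float(window[-1]) - lo) / lo > rule.threshold


def _snapshot_metrics(model: ToyModel, pos: np.ndarray) -> tuple[float, float, float]:
    prof = darvols_profile(pos, variant="cog")
    return native_contact_fraction(model, pos), prof.mean_area, prof.mean_volume


def unfold_stage(
    model: ToyModel,
    hot_t: float = HOT_TEMPERATURE,
    max_snapshots: int = 60,
    seed: int = 0,
    snapshot_interval: int = 1200,
    q_unfold: float = Q_UNFOLD,
) -> ProtocolTrace:
    """Thermal denaturation: run at the ladder-topping temperature until
    the native-contact fraction drops below *q_unfold* or the snapshot
    budget is exhausted (flagged via ``completed=False``)."""
    pos = model.native.copy()
    rows = []
    snaps = []
    trace = ProtocolTrace()
    for k in range(1, max_snapshots + 1):
        pos = mc_run(model, pos, hot_t, snapshot_interval, seed=seed + k)
        q, ma, mv = _snapshot_metrics(model, pos)
        rows.append({"snapshot": k, "temperature": hot_t, "label": "hot",
                     "Q": q, "mean_area": ma, "mean_volume": mv})
        snaps.append((k, hot_t, pos.copy()))
        if q < q_unfold:
            trace.events.append(ProtocolEvent(k, "stop", "unfolded"))
            break
    else:
        trace.completed = False
        trace.events.append(ProtocolEvent(max_snapshots, "stop", "budget_exhausted"))
        logger.warning("unfolding budget exhausted before Q < %.2f", q_unfold)
    trace.snapshots = snaps
    trace.metrics = pd.DataFrame(rows)
    return trace


def run_refolding_protocol(
    model: ToyModel,
    unfolded_positions: np.ndarray,
    ladder: TemperatureLadder = DEFAULT_LADDER,
    rule: InstabilityRule = DEFAULT_RULE,
    seed: int = 0,
    plateau_tol: float = 0.005,
) -> ProtocolTrace:
    """Staged-cooling recovery run.

    Simulation starts at the first (hottest) ladder stage.  After every
    snapshot the packing metrics are checked against the instability
    rule; a trigger — or expiry of the stage's snapshot budget — steps
    the temperature down exactly one stage and logs the event.  The run
    terminates when the ladder is exhausted or when the area metric
    plateaus (relative change below *plateau_tol* over the rule window on
    the final stage).  Deterministic in (model, positions, ladder, seed).
    """
    if len(ladder.stages) < 2:
        raise ValueError("refolding ladder needs at least 2 stages")
    pos = np.array(unfolded_positions, dtype=float)
    rows: list[dict] = []
    snaps: list[tuple[int, float, np.ndarray]] = []
    events: list[ProtocolEvent] = []
    snap_no = 0
    stage_idx = 0
    stage_series_a: list[float] = []
    stage_series_v: list[float] = []
    stage_snaps = 0

    while stage_idx < len(ladder.stages):
        stage = ladder.stages[stage_idx]
        snap_no += 1
        stage_snaps += 1
        pos = mc_run(model, pos, stage.reduced_t, ladder.snapshot_interval,
                     seed=seed + snap_no)
        q, ma, mv = _snapshot_metrics(model, pos)
        rows.append({"snapshot": snap_no, "temperature": stage.reduced_t,
                     "label": f"{stage.label_c:g}", "Q": q,
                     "mean_area": ma, "mean_volume": mv})
        snaps.append((snap_no, stage.reduced_t, pos.copy()))
        stage_series_a.append(ma)
        stage_series_v.append(mv)

        unstable = False
        if stage_snaps >= rule.window:
            if rule.metric in ("mean_area", "either"):
                unstable |= detect_instability(stage_series_a, rule)
            if rule.metric in ("mean_volume", "either"):
                unstable |= detect_instability(stage_series_v, rule)

        last_stage = stage_idx == len(ladder.stages) - 1
        if last_stage and stage_snaps >= rule.window:
            window = np.asarray(stage_series_a[-rule.window:])
            if window.min() > 0 and (window.max() - window.min()) / window.min() < plateau_tol:
                events.append(ProtocolEvent(snap_no, "stop", "plateau"))
                break

        if not last_stage and (unstable or stage_snaps >= stage.max_snapshots):
            reason = "instability" if unstable else "stage_duration"
            events.append(ProtocolEvent(snap_no, "step_down", reason))
            stage_idx += 1
            stage_series_a, stage_series_v = [], []
            stage_snaps = 0
        elif last_stage and stage_snaps >= stage.max_snapshots:
            events.append(ProtocolEvent(snap_no, "stop", "ladder_exhausted"))
            break

    trace = ProtocolTrace(snapshots=snaps, metrics=pd.DataFrame(rows), events=events)
    return trace
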