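"""Lipid binding-site analysis: contact events, residence times, clustering.

Contacts between a lipid molecule and a protein residue are detected with a
dual-cutoff (hysteresis) scheme: an event opens at the first frame where the
minimum interparticle distance drops below ``r_on`` and closes at the first
subsequent frame where it exceeds ``r_off``. The looser closing cutoff
suppresses flicker from boundary noise, so a brief excursion between the two
cutoffs does not split an event.

Per-residue residence times come from a single-exponential fit to the
survival curve of event durations (mean duration below 5 events). Residues
are clustered into sites through a co-occurrence graph: two residues are
joined when the same lipid contacts both in at least half of the frames in
which either is contacted, and connected components of two or more residues
become binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from memallo.errors import InsufficientDataError, ParameterError, SelectionError
from memallo.trajectory import (
    Selection,
    Trajectory,
    as_selection,
    pairwise_min_image_distances,
)
from memallo import constants

ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class ContactEvent:
    """One continuous lipid–residue contact (times in ns, frames 0-based)."""

    lipid_id: int
    residue: ResidueKey
    start: float
    end: float
    start_frame: int
    end_frame: int  # exclusive

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class SurvivalCurve:
    """Fraction of contact events still intact at each lag (ns)."""

    lags: np.ndarray
    survival: np.ndarray
    n_events: int


@dataclass
class ResidueStats:
    residence_time: float  # ns, 1/koff from the survival fit
    mean_duration: float
    max_duration: float
    occupancy_fraction: float
    n_events: int
    survival: SurvivalCurve | None = None


@dataclass
class BindingSite:
    """A residue cluster with site-level contact kinetics."""

    residues: frozenset[ResidueKey]
    residence_time: float
    max_duration: float
    occupancy_fraction: float
    representative_pose: tuple[int, int] | None  # (frame index, lipid_id)
    events: list[ContactEvent] = field(default_factory=list)
    long_lived: bool = False


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

def _frame_durations(times: np.ndarray) -> np.ndarray:
    """Per-frame time credit; the last frame inherits the previous spacing."""
    n = len(times)
    if n == 1:
        return np.array([1.0])
    d = np.diff(times)
    return np.append(d, d[-1])


def detect_contacts(
    traj: Trajectory,
    protein_sel: Selection | str,
    lipid_sel: Selection | str,
    r_on: float = constants.R_ON,
    r_off: float = constants.R_OFF,
    gap_frames: int = constants.GAP_STITCH_FRAMES,
) -> list[ContactEvent]:
    """Dual-cutoff contact events for every (lipid molecule, protein residue).

    Distances are minimum-image minima over all atom pairs of the lipid
    molecule and the residue. Events separated by at most ``gap_frames``
    frames are stitched (0 disables). An event still open at the last frame
    is closed there (right-censored).
    """
    if r_off < r_on or r_on <= 0:
        raise ParameterError(f"need r_off >= r_on > 0, got r_on={r_on}, r_off={r_off}")
    psel = as_selection(protein_sel)
    lsel = as_selection(lipid_sel)
    p_idx = psel.resolve(traj.topology)
    l_idx = lsel.resolve(traj.topology)
    if len(p_idx) == 0 or len(l_idx) == 0:
        raise SelectionError("protein or lipid selection matches no atoms")

    res_keys = traj.topology.residue_keys(p_idx)
    res_atoms = {k: [] for k in res_keys}
    for i in p_idx:
        res_atoms[(str(traj.topology.chains[i]), int(traj.topology.resids[i]))].append(i)
    lip_keys = traj.topology.residue_keys(l_idx)
    lip_atoms = {k: [] for k in lip_keys}
    for i in l_idx:
        lip_atoms[(str(traj.topology.chains[i]), int(traj.topology.resids[i]))].append(i)

    durations = _frame_durations(traj.times)
    n_frames = traj.n_frames

    # flatten atoms grouped by molecule/residue so a single distance matrix
    # per frame can be min-reduced into the (lipid, residue) distance table
    l_flat = np.concatenate([lip_atoms[k] for k in lip_keys])
    l_bounds = np.cumsum([0] + [len(lip_atoms[k]) for k in lip_keys])[:-1]
    p_flat = np.concatenate([res_atoms[k] for k in res_keys])
    p_bounds = np.cumsum([0] + [len(res_atoms[k]) for k in res_keys])[:-1]

    n_pairs = len(lip_keys) * len(res_keys)
    dmin = np.empty((n_frames, len(lip_keys), len(res_keys)))
    for f in range(n_frames):
        box = None if traj.box is None else traj.box[f]
        atom_d = pairwise_min_image_distances(
            traj.frames[f][l_flat], traj.frames[f][p_flat], box
        )
        atom_d = np.minimum.reduceat(atom_d, l_bounds, axis=0)
        dmin[f] = np.minimum.reduceat(atom_d, p_bounds, axis=1)

    # hysteresis as a forward-filled three-state code: 1 below r_on,
    # 0 above r_off, carry-forward in between (initial state: no contact)
    flat = dmin.reshape(n_frames, n_pairs)
    code = np.full(flat.shape, -1, dtype=np.int8)
    code[flat < r_on] = 1
    code[flat > r_off] = 0
    valid = code >= 0
    idx = np.where(valid, np.arange(n_frames)[:, None], -1)
    idx = np.maximum.accumulate(idx, axis=0)
    state = np.take_along_axis(code, np.maximum(idx, 0), axis=0)
    state[idx < 0] = 0

    raw: list[tuple[int, ResidueKey, int, int]] = []
    padded_cols = np.concatenate(
        [np.zeros((1, n_pairs), np.int8), state, np.zeros((1, n_pairs), np.int8)]
    )
    for p in range(n_pairs):
        edges = np.flatnonzero(np.diff(padded_cols[:, p]))
        if len(edges) == 0:
            continue
        lk = lip_keys[p // len(res_keys)]
        rk = res_keys[p % len(res_keys)]
        for s, e in zip(edges[::2], edges[1::2]):
            raw.append((lk[1], rk, int(s), int(e)))

    # stitch small gaps, then convert frames to times
    raw.sort(key=lambda e: (e[0], e[1], e[2]))
    stitched: list[tuple[int, ResidueKey, int, int]] = []
    for ev in raw:
        if (
            stitched
            and stitched[-1][0] == ev[0]
            and stitched[-1][1] == ev[1]
            and ev[2] - stitched[-1][3] <= gap_frames
        ):
            prev = stitched.pop()
            ev = (prev[0], prev[1], prev[2], ev[3])
        stitched.append(ev)

    cum = np.concatenate([[0.0], np.cumsum(durations)])
    events = [
        ContactEvent(
            lipid, rk,
            start=float(traj.times[s]),
            end=float(traj.times[s] + (cum[e] - cum[s])),
            start_frame=s, end_frame=e,
        )
        for lipid, rk, s, e in stitched
    ]
    events.sort(key=lambda ev: (ev.residue, ev.lipid_id, ev.start_frame))
    return events


# ---------------------------------------------------------------------------
# Residence-time estimation
# ---------------------------------------------------------------------------

def survival_curve(durations: np.ndarray) -> SurvivalCurve:
    """Empirical survival S(t) = fraction of events with duration > t."""
    durations = np.asarray(durations, dtype=float)
    n = len(durations)
    lags = np.concatenate([[0.0], np.unique(durations)])
    survival = np.array([(durations > lag).sum() / n for lag in lags])
    survival[0] = 1.0
    return SurvivalCurve(lags, survival, n)


def fit_residence_time(
    durations: np.ndarray,
    min_events_for_fit: int = constants.MIN_EVENTS_FOR_FIT,
) -> float:
    """Residence time 1/koff from a log-linear least-squares survival fit.

    Falls back to the mean duration when there are too few events for a
    stable fit, or when the fitted decay rate is non-positive.
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) == 0:
        return 0.0
    if len(durations) < min_events_for_fit:
        return float(durations.mean())
    curve = survival_curve(durations)
    keep = curve.survival > 0
    lags, surv = curve.lags[keep], curve.survival[keep]
    if len(lags) < 2:
        return float(durations.mean())
    slope = np.polyfit(lags, np.log(surv), 1)[0]
    if slope >= 0:
        return float(durations.mean())
    return float(-1.0 / slope)


def _interval_union_length(intervals: list[tuple[float, float]]) -> float:
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total, cur_start, cur_end = 0.0, *intervals[0]
    for s, e in intervals[1:]:
        if s > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    return total + (cur_end - cur_start)


def residue_residence_times(
    events: list[ContactEvent],
    total_time: float,
    min_events_for_fit: int = constants.MIN_EVENTS_FOR_FIT,
) -> dict[ResidueKey, ResidueStats]:
    """Per-residue residence time, duration stats, and occupancy fraction.

    Occupancy counts the union of contact intervals over all lipids, so two
    lipids covering the same residue simultaneously are not double-counted.
    """
    if total_time <= 0:
        raise ParameterError("total_time must be positive")
    by_res: dict[ResidueKey, list[ContactEvent]] = {}
    for ev in events:
        by_res.setdefault(ev.residue, []).append(ev)
    out: dict[ResidueKey, ResidueStats] = {}
    for rk, evs in by_res.items():
        durations = np.array([e.duration for e in evs])
        occ = _interval_union_length([(e.start, e.end) for e in evs]) / total_time
        out[rk] = ResidueStats(
            residence_time=fit_residence_time(durations, min_events_for_fit),
            mean_duration=float(durations.mean()),
            max_duration=float(durations.max()),
            occupancy_fraction=min(occ, 1.0),
            n_events=len(evs),
            survival=survival_curve(durations),
        )
    return out


# ---------------------------------------------------------------------------
# Site clustering
# ---------------------------------------------------------------------------

def _contact_frames(
    events: list[ContactEvent], n_frames: int
) -> dict[tuple[int, ResidueKey], np.ndarray]:
    table: dict[tuple[int, ResidueKey], np.ndarray] = {}
    for ev in events:
        key = (ev.lipid_id, ev.residue)
        arr = table.setdefault(key, np.zeros(n_frames, dtype=bool))
        arr[ev.start_frame:ev.end_frame] = True
    return table


def _site_level_events(
    site_residues: frozenset[ResidueKey],
    table: dict[tuple[int, ResidueKey], np.ndarray],
    n_frames: int,
    times: np.ndarray,
) -> list[ContactEvent]:
    """Maximal segments where one lipid contacts >= 2 site residues at once."""
    durations = _frame_durations(times)
    cum = np.concatenate([[0.0], np.cumsum(durations)])
    lipids = {lip for (lip, rk) in table if rk in site_residues}
    out: list[ContactEvent] = []
    for lip in sorted(lipids):
        count = np.zeros(n_frames, dtype=int)
        for rk in site_residues:
            arr = table.get((lip, rk))
            if arr is not None:
                count += arr
        active = count >= 2
        if not active.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(ContactEvent(
                lip, min(site_residues),
                start=float(times[s]), end=float(times[s] + (cum[e] - cum[s])),
                start_frame=int(s), end_frame=int(e),
            ))
    return out


def cluster_sites(
    events: list[ContactEvent],
    n_frames: int,
    times: np.ndarray,
    co_occurrence_min: float = constants.CO_OCCURRENCE_MIN,
    min_events_for_fit: int = constants.MIN_EVENTS_FOR_FIT,
) -> list[BindingSite]:
    """Group residues into binding sites via the lipid co-occurrence graph.

    Edge rule: among frames where either residue is in contact with some
    lipid, the same lipid must contact both in at least
    ``co_occurrence_min`` of them. Components with >= 2 residues become
    sites, ordered by descending residence time (ties: smallest residue
    number first). Deterministic and independent of event ordering.
    """
    if not events:
        raise InsufficientDataError("no contact events to cluster")
    table = _contact_frames(events, n_frames)
    residues = sorted({rk for (_, rk) in table})
    any_contact = {
        rk: np.any([table[k] for k in table if k[1] == rk], axis=0) for rk in residues
    }
    lipids = sorted({lip for (lip, _) in table})

    g = nx.Graph()
    g.add_nodes_from(residues)
    for a_i, ra in enumerate(residues):
        for rb in residues[a_i + 1:]:
            either = any_contact[ra] | any_contact[rb]
            denom = int(either.sum())
            if denom == 0:
                continue
            both_same = np.zeros(n_frames, dtype=bool)
            for lip in lipids:
                ta = table.get((lip, ra))
                tb = table.get((lip, rb))
                if ta is not None and tb is not None:
                    both_same |= ta & tb
            if both_same.sum() / denom >= co_occurrence_min:
                g.add_edge(ra, rb)

    total_time = float(_frame_durations(times).sum())
    sites: list[BindingSite] = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        comp = frozenset(comp)
        site_events = _site_level_events(comp, table, n_frames, times)
        if site_events:
            durs = np.array([e.duration for e in site_events])
            rt = fit_residence_time(durs, min_events_for_fit)
            max_dur = float(durs.max())
            occ_frames = np.zeros(n_frames, dtype=bool)
            for ev in site_events:
                occ_frames[ev.start_frame:ev.end_frame] = True
            occ = float(occ_frames.sum() / n_frames)
            pose = representative_pose_from_events(site_events)
        else:
            rt, max_dur, occ, pose = 0.0, 0.0, 0.0, None
        sites.append(BindingSite(comp, rt, max_dur, occ, pose, site_events))
    sites.sort(key=lambda s: (-s.residence_time, min(rk[1] for rk in s.residues)))
    return sites


def representative_pose_from_events(
    events: list[ContactEvent],
) -> tuple[int, int]:
    """Midpoint frame and lipid of the longest event; ties pick the earliest."""
    if not events:
        raise InsufficientDataError("site has no qualifying events")
    best = max(events, key=lambda e: (e.n_frames, -e.start_frame, -e.lipid_id))
    return (best.start_frame + best.end_frame) // 2, best.lipid_id


def representative_pose(site: BindingSite, traj: Trajectory | None = None
                        ) -> tuple[int, int]:
    """(frame index, lipid_id) of the site's representative bound pose."""
    return representative_pose_from_events(site.events)


def flag_long_lived(
    sites: list[BindingSite], threshold_ns: float = constants.SITE_FLAG_NS
) -> list[BindingSite]:
    """Set the display flag for long-lived sites; the site list is unchanged."""
    for s in sites:
        s.long_lived = s.residence_time >= threshold_ns
    return sites
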