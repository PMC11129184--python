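"""Perturbation response scanning (PRS) for allosteric hotspot ranking.

The method treats each Cα atom as a node of a fluctuating network. Linear
response theory relates a static external force F applied at one node to the
expected coordinate shift ΔR = C·F, where C is the 3N×3N positional
covariance of the nodes estimated from a trajectory (the 1/kT prefactor is
omitted: the overlap score below is invariant to it). Each node is probed
with many random force directions; the response is scored against a target
displacement ΔS — typically the difference between two experimental end
states after superposition — by the absolute cosine overlap

    O = |ΔR · ΔS| / (|ΔR| |ΔS|)  ∈ [0, 1].

The absolute value is taken because the force sign is arbitrary (±F give
opposite responses with identical information). Nodes whose best overlap
exceeds a threshold (default 0.6) are reported as putative allosteric
hotspots. A closed-form optimal-force solution is provided alongside the
random scan and serves as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from memallo.errors import (
    IllPosedError,
    InsufficientDataError,
    SelectionError,
)
from memallo.trajectory import (
    Selection,
    Structure,
    Trajectory,
    apply_transform,
    as_selection,
    superpose_kabsch,
)
from memallo import constants


@dataclass
class CovarianceMatrix:
    """3N×3N positional covariance (Å²) over selected nodes."""

    matrix: np.ndarray
    node_resids: list[tuple[str, int]]
    n_frames_used: int
    alignment_reference: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.node_resids)

    def node_block_columns(self, node_index: int) -> np.ndarray:
        """The 3N×3 columns of C belonging to one node."""
        j = 3 * node_index
        return self.matrix[:, j:j + 3]


@dataclass
class DisplacementField:
    """A 3N vector (Å) over the same node list as a covariance matrix."""

    vector: np.ndarray
    node_resids: list[tuple[str, int]]

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass
class ForcePerturbation:
    """A unit-direction point force applied at one node."""

    residue_index: int
    direction: np.ndarray
    magnitude: float = 1.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            if n == 0:
                raise IllPosedError("force direction must be nonzero")
            d = d / n
        self.direction = d
        if self.magnitude <= 0:
            raise IllPosedError("force magnitude must be positive")


@dataclass
class OverlapProfile:
    """Per-node best overlap with the target displacement."""

    best_overlap: np.ndarray  # (N,)
    best_direction: np.ndarray  # (N, 3)
    node_resids: list[tuple[str, int]]
    n_directions_sampled: int
    threshold: float = constants.OVERLAP_THRESHOLD


# ---------------------------------------------------------------------------
# Covariance estimation
# ---------------------------------------------------------------------------

def _iterative_mean_align(coords: np.ndarray, n_iterations: int = 2) -> np.ndarray:
    """Superpose frames onto an iteratively refined mean structure.

    Two iterations (align to the frame-0-seeded mean, recompute, realign)
    are enough for fluctuation ensembles; the count is configurable.
    """
    aligned = coords.copy()
    mean = aligned[0]
    for _ in range(n_iterations):
        for i in range(len(aligned)):
            rot, trans, _ = superpose_kabsch(aligned[i], mean)
            aligned[i] = apply_transform(aligned[i], rot, trans)
        mean = aligned.mean(axis=0)
    return aligned


def compute_covariance(
    traj: Trajectory,
    selection: Selection | str = "name CA",
    align: bool = True,
    n_align_iterations: int = 2,
) -> CovarianceMatrix:
    """Estimate the 3N×3N node covariance from a trajectory.

    Frames are optionally rigid-body superposed (Kabsch on the selection,
    iterated mean reference) before the population covariance
    C = <(x − <x>)(x − <x>)ᵀ> is accumulated with the frame-count
    denominator.
    """
    sel = as_selection(selection)
    idx = sel.resolve(traj.topology)
    if len(idx) < 4:
        raise SelectionError(
            f"selection {sel.expression!r} resolves to {len(idx)} nodes; "
            "need at least 4"
        )
    if traj.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames for a covariance")
    coords = traj.frames[:, idx, :]
    if align:
        coords = _iterative_mean_align(coords, n_align_iterations)
    flat = coords.reshape(traj.n_frames, -1)
    dev = flat - flat.mean(axis=0)
    cov = dev.T @ dev / traj.n_frames
    node_resids = traj.topology.residue_keys(idx)
    if 3 * len(node_resids) != flat.shape[1]:
        raise SelectionError(
            "selection must resolve to exactly one atom per residue node"
        )
    return CovarianceMatrix(
        cov, node_resids, traj.n_frames,
        alignment_reference="iterative mean" if align else "none",
    )


# ---------------------------------------------------------------------------
# Linear response, overlap, optimal force
# ---------------------------------------------------------------------------

def linear_response(C: CovarianceMatrix, f: ForcePerturbation) -> DisplacementField:
    """Predicted displacement ΔR = C·F for a point force at one node."""
    n = C.n_nodes
    if not 0 <= f.residue_index < n:
        raise IllPosedError(f"node index {f.residue_index} out of range [0, {n})")
    block = C.node_block_columns(f.residue_index)
    vec = block @ (f.magnitude * f.direction)
    return DisplacementField(vec, C.node_resids)


def overlap(dR: DisplacementField, dS: DisplacementField) -> float:
    """Absolute cosine overlap between response and target displacement."""
    if dR.node_resids != dS.node_resids:
        raise SelectionError("displacement fields are over different node sets")
    ns = dS.norm
    if ns == 0:
        raise IllPosedError("target displacement has zero norm")
    nr = dR.norm
    if nr == 0:
        return 0.0
    return float(abs(dR.vector @ dS.vector) / (nr * ns))


def analytic_best_force(
    C: CovarianceMatrix, node_index: int, dS: DisplacementField
) -> tuple[np.ndarray, float]:
    """Closed-form force direction maximizing |cos| overlap at one node.

    With B = C_blockᵀ C_block and a = C_blockᵀ ΔS, the maximizer of
    |aᵀf| / sqrt(fᵀBf) over unit f is f* ∝ B⁻¹a and the achieved overlap is
    sqrt(aᵀB⁻¹a)/|ΔS| (pseudo-inverse when B is singular). Serves as the
    oracle for the random scan.
    """
    block = C.node_block_columns(node_index)
    ns = dS.norm
    if ns == 0:
        raise IllPosedError("target displacement has zero norm")
    a = block.T @ dS.vector
    if np.allclose(a, 0.0):
        return np.array([1.0, 0.0, 0.0]), 0.0
    b = block.T @ block
    try:
        sol = np.linalg.solve(b, a)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(b) @ a
    best = float(np.sqrt(max(a @ sol, 0.0)) / ns)
    direction = sol / np.linalg.norm(sol)
    return direction, min(best, 1.0)


def scan(
    C: CovarianceMatrix,
    dS: DisplacementField,
    n_directions: int = constants.N_DIRECTIONS,
    n_repeats: int = constants.N_REPEATS,
    seed: int | None = None,
    aggregate: str = "max",
) -> OverlapProfile:
    """Random perturbation scan: best overlap per node over sampled forces.

    Per repeat, ``n_directions`` uniform unit force directions (normalized
    standard 3D normals) are applied at every node. By default the best
    overlap across all repeats is recorded per node ("max"); "mean"
    averages the per-repeat bests.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError("aggregate must be 'max' or 'mean'")
    if dS.node_resids != C.node_resids:
        raise SelectionError("target field node set differs from covariance nodes")
    ns = dS.norm
    if ns == 0:
        raise IllPosedError("target displacement has zero norm")
    rng = np.random.default_rng(seed)
    n = C.n_nodes
    best = np.zeros(n)
    best_dir = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    repeat_best = np.zeros((n_repeats, n))
    for rep in range(n_repeats):
        dirs = rng.standard_normal((n_directions, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for node in range(n):
            block = C.node_block_columns(node)  # 3N×3
            responses = block @ dirs.T  # 3N×M
            dots = np.abs(dS.vector @ responses)
            norms = np.linalg.norm(responses, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ov = np.where(norms > 0, dots / (norms * ns), 0.0)
            j = int(np.argmax(ov))
            repeat_best[rep, node] = ov[j]
            if ov[j] > best[node]:
                best[node] = ov[j]
                best_dir[node] = dirs[j]
    if aggregate == "mean":
        best = repeat_best.mean(axis=0)
    return OverlapProfile(
        best, best_dir, C.node_resids, n_directions * n_repeats
    )


def rank_hotspots(
    profile: OverlapProfile, threshold: float | None = None
) -> list[tuple[str, int, float]]:
    """Nodes above threshold, highest overlap first; ties by residue number."""
    thr = profile.threshold if threshold is None else threshold
    rows = [
        (chain, resid, float(o))
        for (chain, resid), o in zip(profile.node_resids, profile.best_overlap)
        if o >= thr
    ]
    rows.sort(key=lambda r: (-r[2], r[1], r[0]))
    return rows


def converged_start(
    traj: Trajectory,
    selection: Selection | str = "name CA",
    rmsd_bound: float = 1.0,
) -> int:
    """First frame of the converged trajectory interval.

    The converged interval is the longest suffix of the trajectory whose
    per-frame Cα RMSD to the final frame stays below ``rmsd_bound`` (Å).
    PRS needs a relaxed starting conformation; this picks one
    automatically when no explicit frame index is configured.
    """
    sel = as_selection(selection)
    idx = sel.resolve(traj.topology)
    if len(idx) < 3:
        raise SelectionError("selection too small for RMSD convergence check")
    ref = traj.frames[-1, idx, :]
    start = traj.n_frames - 1
    for i in range(traj.n_frames - 1, -1, -1):
        _, _, rmsd = superpose_kabsch(traj.frames[i, idx, :], ref)
        if rmsd < rmsd_bound:
            start = i
        else:
            break
    return start


def target_displacement(
    initial: Structure,
    target: Structure,
    selection: Selection | str = "name CA",
    superpose: bool = True,
) -> DisplacementField:
    """Per-node displacement from ``initial`` to ``target`` (3N vector, Å).

    The target is Kabsch-superposed onto the initial structure over the
    selection first (disable for pre-aligned toys), removing the arbitrary
    rigid-body component of the conformational change.
    """
    sel = as_selection(selection)
    idx_i = sel.resolve(initial)
    idx_t = sel.resolve(target)
    if len(idx_i) != len(idx_t):
        raise SelectionError(
            f"selection resolves to {len(idx_i)} atoms in initial but "
            f"{len(idx_t)} in target"
        )
    ci = initial.coordinates[idx_i]
    ct = target.coordinates[idx_t]
    if superpose:
        rot, trans, _ = superpose_kabsch(ct, ci)
        ct = apply_transform(ct, rot, trans)
    return DisplacementField((ct - ci).ravel(), initial.residue_keys(idx_i))
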