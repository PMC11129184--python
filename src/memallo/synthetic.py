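"""Synthetic trajectory generators with planted, recoverable ground truth.

Three generators cover the statistical structure the analysis stages assume:

* a Gaussian fluctuation ensemble with a prescribed 3N×3N covariance
  (isotropic, rank-one "spiked", or elastic-network) standing in for Cα
  fluctuations of a long equilibrium simulation;
* a coarse-grained lipid random walk around a fixed toy protein with planted
  sticky sites whose dwell times are exponential — the kinetics behind
  residence-time and occupancy analysis;
* a four-atom hydrogen-bond fixture with exactly prescribed donor–acceptor
  distance and D–H–A angle.

All generators are bit-reproducible given their spec (which includes the
seed). The module also hosts the leaflet mole-percent calculator for the
asymmetric neuronal membrane recipe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from memallo.errors import SpecError
from memallo.trajectory import Structure, Trajectory

# ---------------------------------------------------------------------------
# Covariance builders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Isotropic:
    """sigma2 * identity: independent equal fluctuations on every coordinate."""

    sigma2: float


@dataclass(frozen=True)
class Spiked:
    """sigma2 * I + lam * u u^T with unit 3N-vector u (a planted soft mode)."""

    sigma2: float
    lam: float
    u: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        norm = np.linalg.norm(u)
        if norm == 0:
            raise SpecError("spiked builder requires a nonzero direction u")
        object.__setattr__(self, "u", u / norm)


@dataclass(frozen=True)
class ElasticNetwork:
    """Gaussian-network covariance from a distance-cutoff Kirchhoff matrix.

    C = (1/spring_constant) * pinv(Gamma) ⊗ I3, with Gamma built from the
    mean coordinates: off-diagonal -1 for pairs within ``cutoff`` Å.
    """

    cutoff: float = 10.0
    spring_constant: float = 1.0


def _build_covariance(builder, mean_coords: np.ndarray) -> np.ndarray:
    n3 = mean_coords.size
    if isinstance(builder, Isotropic):
        if builder.sigma2 < 0:
            raise SpecError("isotropic sigma2 must be >= 0")
        return builder.sigma2 * np.eye(n3)
    if isinstance(builder, Spiked):
        u = np.asarray(builder.u, dtype=float)
        if u.shape != (n3,):
            raise SpecError(f"spiked u has length {u.size}, expected {n3}")
        return builder.sigma2 * np.eye(n3) + builder.lam * np.outer(u, u)
    if isinstance(builder, ElasticNetwork):
        n = len(mean_coords)
        delta = mean_coords[:, None, :] - mean_coords[None, :, :]
        dist = np.sqrt((delta**2).sum(axis=2))
        gamma = -(dist <= builder.cutoff).astype(float)
        np.fill_diagonal(gamma, 0.0)
        np.fill_diagonal(gamma, -gamma.sum(axis=1))
        ginv = np.linalg.pinv(gamma, hermitian=True)
        return np.kron(ginv / builder.spring_constant, np.eye(3))
    raise SpecError(f"unknown covariance builder {builder!r}")


@dataclass
class GaussianEnsembleSpec:
    """Recipe for a multivariate-normal Cα fluctuation ensemble."""

    n_residues: int
    mean_coords: np.ndarray  # (N, 3) Å
    covariance_builder: Isotropic | Spiked | ElasticNetwork
    n_frames: int
    seed: int

    def __post_init__(self):
        self.mean_coords = np.asarray(self.mean_coords, dtype=float)
        if self.mean_coords.shape != (self.n_residues, 3):
            raise SpecError(
                f"mean_coords shape {self.mean_coords.shape} != "
                f"({self.n_residues}, 3)"
            )
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")


def _ca_chain_topology(n: int) -> Structure:
    return Structure(
        np.array(["CA"] * n),
        np.array(["C"] * n),
        np.arange(1, n + 1),
        np.array(["ALA"] * n),
        np.array(["A"] * n),
        np.zeros((n, 3)),
    )


def generate_gaussian_ensemble(
    spec: GaussianEnsembleSpec,
) -> tuple[Trajectory, np.ndarray]:
    """Sample i.i.d. frames from N(mean, C) and return (trajectory, C).

    The returned covariance is the exact population truth, so downstream
    estimators can be validated against it. The PSD check tolerates
    eigenvalues down to -1e-8 times the largest (round-off from the
    elastic-network pseudo-inverse).
    """
    cov = _build_covariance(spec.covariance_builder, spec.mean_coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals.size and evals[0] < -1e-8 * max(evals[-1], 1.0):
        raise SpecError(f"covariance builder produced a non-PSD matrix "
                        f"(min eigenvalue {evals[0]:.3e})")
    evals = np.clip(evals, 0.0, None)
    factor = evecs * np.sqrt(evals)  # C = factor @ factor.T

    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, cov.shape[0]))
    samples = z @ factor.T
    frames = spec.mean_coords[None, :, :] + samples.reshape(spec.n_frames, -1, 3)

    topo = _ca_chain_topology(spec.n_residues)
    topo.coordinates = spec.mean_coords.copy()
    traj = Trajectory(topo, frames, np.arange(spec.n_frames, dtype=float))
    return traj, cov


# ---------------------------------------------------------------------------
# Lipid random walk with planted sticky sites
# ---------------------------------------------------------------------------


@dataclass
class LipidKineticsSpec:
    """Recipe for a reflecting lipid random walk with exponential-dwell sites.

    ``diffusion_step`` is the mean displacement magnitude per frame (Å); the
    per-axis Gaussian step width is scaled so the expected 3D step length
    equals it. A lipid entering within ``r_bind`` of a site center freezes
    for Exponential(``mean_dwell``) ns (quantized up to whole frames), then
    resumes and cannot rebind until it has diffused beyond ``r_release``
    (default 2.5 × r_bind). The escape shell keeps consecutive planted
    events separable by dual-cutoff contact detection: without it a
    released walker re-enters the capture sphere with high probability
    before its contacts have broken, merging adjacent dwells.
    """

    box: np.ndarray  # 3 lengths, Å
    n_lipids: int
    diffusion_step: float  # Å per frame (mean displacement)
    site_centers: np.ndarray  # (n_sites, 3) Å
    r_bind: float  # Å
    mean_dwell: float  # ns
    frame_dt: float  # ns
    n_frames: int
    seed: int
    r_release: float | None = None  # Å; default 2.5 * r_bind

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        if self.r_release is None:
            self.r_release = 2.5 * self.r_bind
        if self.r_release < self.r_bind:
            raise SpecError("r_release must be >= r_bind")
        self.site_centers = np.atleast_2d(np.asarray(self.site_centers, dtype=float))
        if self.r_bind <= 0:
            raise SpecError("r_bind must be > 0")
        if self.mean_dwell <= 0:
            raise SpecError("mean_dwell must be > 0")
        if np.any(self.site_centers < 0) or np.any(self.site_centers > self.box):
            raise SpecError("site centers must lie inside the box")


@dataclass(frozen=True)
class BoundSegment:
    """One planted binding event: lipid ``lipid_resid`` immobile at a site."""

    lipid_resid: int
    site_index: int
    start_frame: int
    end_frame: int  # exclusive
    dwell_ns: float  # the exact exponential draw before frame quantization


@dataclass
class LipidWalkResult:
    trajectory: Trajectory
    bound_segments: list[BoundSegment]
    spec: LipidKineticsSpec

    def segment_durations_ns(self) -> np.ndarray:
        """Realized (frame-quantized) bound durations in ns."""
        return np.array(
            [(s.end_frame - s.start_frame) * self.spec.frame_dt
             for s in self.bound_segments]
        )


# E|N(0, s^2 I_3)| = s * sqrt(8/pi); invert so diffusion_step is the mean step
_STEP_SCALE = math.sqrt(math.pi / 8.0)


def generate_lipid_walk(spec: LipidKineticsSpec, protein: Structure) -> LipidWalkResult:
    """Simulate the lipid walk around a fixed protein; returns planted truth.

    One seeded RNG stream governs initial placement, every step, and every
    dwell draw, in a fixed order (steps for all lipids each frame, then
    capture checks in lipid order), so replays are bit-identical.
    """
    if np.any(protein.coordinates < 0) or np.any(protein.coordinates > spec.box):
        raise SpecError("protein must sit inside the box interior")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lipids
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * spec.box
    step_sigma = spec.diffusion_step * _STEP_SCALE

    bound_until = np.full(n, -1, dtype=int)  # exclusive release frame
    refractory_site = np.full(n, -1, dtype=int)
    open_segment: dict[int, tuple[int, int, float]] = {}  # lipid -> (site, start, dwell)
    segments: list[BoundSegment] = []

    lipid_frames = np.empty((spec.n_frames, n, 3))
    for t in range(spec.n_frames):
        if t > 0:
            steps = rng.normal(0.0, step_sigma, size=(n, 3))
            free = bound_until <= t
            pos[free] = pos[free] + steps[free]
            # reflecting boundaries
            for _ in range(2):  # a large step can overshoot both walls once
                pos = np.where(pos < 0, -pos, pos)
                pos = np.where(pos > spec.box, 2 * spec.box - pos, pos)
        # release bookkeeping
        for i in list(open_segment):
            if bound_until[i] <= t:
                site, start, dwell = open_segment.pop(i)
                segments.append(BoundSegment(i + 1, site, start, int(bound_until[i]), dwell))
        # capture checks, lipid order
        dists = np.linalg.norm(
            pos[:, None, :] - spec.site_centers[None, :, :], axis=2
        )
        for i in range(n):
            if bound_until[i] > t:
                continue
            nearest = int(np.argmin(dists[i]))
            if refractory_site[i] >= 0:
                if dists[i, refractory_site[i]] > spec.r_release:
                    refractory_site[i] = -1
                else:
                    lipid_frames[t, i] = pos[i]
                    continue
            if dists[i, nearest] <= spec.r_bind:
                dwell = rng.exponential(spec.mean_dwell)
                n_bound = max(1, math.ceil(dwell / spec.frame_dt))
                bound_until[i] = t + n_bound
                refractory_site[i] = nearest
                open_segment[i] = (nearest, t, dwell)
                pos[i] = spec.site_centers[nearest]  # settle into the bound pose
        lipid_frames[t] = pos
    # close segments still open at the end (censored at the last frame)
    for i, (site, start, dwell) in open_segment.items():
        end = min(int(bound_until[i]), spec.n_frames)
        segments.append(BoundSegment(i + 1, site, start, end, dwell))

    topo = _merge_protein_lipids(protein, n)
    n_p = protein.n_atoms
    frames = np.empty((spec.n_frames, n_p + n, 3))
    frames[:, :n_p] = protein.coordinates
    frames[:, n_p:] = lipid_frames
    times = np.arange(spec.n_frames) * spec.frame_dt
    traj = Trajectory(topo, frames, times, np.tile(spec.box, (spec.n_frames, 1)))
    segments.sort(key=lambda s: (s.start_frame, s.lipid_resid))
    return LipidWalkResult(traj, segments, spec)


def _merge_protein_lipids(protein: Structure, n_lipids: int) -> Structure:
    lip = Structure(
        np.array(["ROH"] * n_lipids),
        np.array(["O"] * n_lipids),
        np.arange(1, n_lipids + 1),
        np.array(["CHOL"] * n_lipids),
        np.array(["L"] * n_lipids),
        np.zeros((n_lipids, 3)),
    )
    return Structure(
        np.concatenate([protein.atom_names, lip.atom_names]),
        np.concatenate([protein.elements, lip.elements]),
        np.concatenate([protein.resids, lip.resids]),
        np.concatenate([protein.resnames, lip.resnames]),
        np.concatenate([protein.chains, lip.chains]),
        np.vstack([protein.coordinates, lip.coordinates]),
    )


def toy_protein(
    site_center: np.ndarray,
    n_near: int = 4,
    near_radius: float = 2.5,
    n_far: int = 4,
    far_offset: float = 15.0,
) -> Structure:
    """A minimal pseudo-protein: ``n_near`` one-bead residues ringed around a
    binding-site center plus ``n_far`` decoy residues displaced along +x.

    Residues are numbered 1..n_near for the site ring and onward for decoys,
    all on chain P, so planted-site recovery tests know the answer.
    """
    site_center = np.asarray(site_center, dtype=float)
    coords = []
    for k in range(n_near):
        theta = 2 * math.pi * k / max(n_near, 1)
        coords.append(site_center + near_radius * np.array(
            [math.cos(theta), math.sin(theta), 0.0]))
    for k in range(n_far):
        coords.append(site_center + np.array([far_offset + 3.0 * k, 0.0, 0.0]))
    n = n_near + n_far
    return Structure(
        np.array(["BB"] * n),
        np.array(["C"] * n),
        np.arange(1, n + 1),
        np.array(["GLY"] * n),
        np.array(["P"] * n),
        np.asarray(coords),
    )


# ---------------------------------------------------------------------------
# Hydrogen-bond geometry fixture
# ---------------------------------------------------------------------------

_OH_BOND = 0.96  # Å, serine O-H
_CO_BOND = 1.43  # Å, sterol C3-O3


def hbond_fixture(distance: float, angle: float) -> Structure:
    """Four-atom fixture: serine O-H donor and sterol hydroxyl acceptor.

    Places SER OG at the origin and HG1 along +x, then positions the
    acceptor O3 so the donor-heavy-atom-to-acceptor distance and the
    D-H-A angle are exactly as requested; C3 extends the H→O3 direction.
    Residue/atom names follow CHARMM conventions (SER, CHL1).
    """
    if distance <= 0:
        raise SpecError("distance must be > 0")
    if not 0.0 <= angle <= 180.0:
        raise SpecError("angle must be within [0, 180] degrees")
    og = np.zeros(3)
    hg1 = np.array([_OH_BOND, 0.0, 0.0])
    alpha = math.radians(angle)
    direction = np.array([-math.cos(alpha), math.sin(alpha), 0.0])
    # |hg1 + t*direction| = distance, smallest positive root
    b = float(hg1 @ direction)
    disc = b * b - (_OH_BOND**2 - distance**2)
    if disc < 0:
        raise SpecError(
            f"no acceptor placement with distance {distance} Å and angle {angle}°"
        )
    t = -b + math.sqrt(disc)
    if t <= 0:
        raise SpecError(
            f"degenerate acceptor placement for distance {distance} Å, angle {angle}°"
        )
    o3 = hg1 + t * direction
    c3 = o3 + _CO_BOND * direction

    return Structure(
        np.array(["OG", "HG1", "O3", "C3"]),
        np.array(["O", "H", "O", "C"]),
        np.array([283, 283, 1, 1]),
        np.array(["SER", "SER", "CHL1", "CHL1"]),
        np.array(["A", "A", "L", "L"]),
        np.vstack([og, hg1, o3, c3]),
    )


# ---------------------------------------------------------------------------
# Membrane leaflet composition calculator
# ---------------------------------------------------------------------------

#: Lipid counts of the asymmetric neuronal membrane mimic, per leaflet.
NEURONAL_OUTER_LEAFLET: Mapping[str, int] = {
    "CHOL": 528, "POPC": 288, "POPE": 132, "DOPS": 0, "PIP2": 0, "SM": 228,
}
NEURONAL_INNER_LEAFLET: Mapping[str, int] = {
    "CHOL": 504, "POPC": 156, "POPE": 252, "DOPS": 192, "PIP2": 24, "SM": 36,
}


@dataclass
class LeafletComposition:
    """Lipid counts for one bilayer leaflet."""

    counts: Mapping[str, int]
    leaflet: str = "inner"

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise SpecError("lipid counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def _round_half_away(x: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def mole_percents(composition: LeafletComposition) -> dict[str, float]:
    """Mole percent per lipid type, rounded half-away-from-zero to 1 decimal.

    Rounding is stated explicitly because published composition tables are
    often internally inconsistent at the last digit; the calculator reports
    from counts only.
    """
    total = composition.total
    if total == 0:
        raise SpecError("composition has zero total lipids")
    return {
        lipid: _round_half_away(100.0 * count / total, 1)
        for lipid, count in composition.counts.items()
    }
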