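"""Atomistic interaction analyses: fingerprints, distances, RMSD, pore radius.

Hydrogen bonds use the donor-heavy-atom-to-acceptor distance (<= 3.5 Å,
inclusive) plus a D-H-A angle criterion (>= 130°); hydrophobic contacts use
a 4.5 Å carbon/sulfur atom-pair cutoff. Boundary inclusivity (<= d_max,
>= angle_min) is uniform across detectors, and all distances respect the
minimum-image convention when a box is present.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from memallo.errors import ParameterError, SelectionError
from memallo.trajectory import (
    Selection,
    Structure,
    Trajectory,
    as_selection,
    minimum_image,
    pairwise_min_image_distances,
    superpose_kabsch,
)
from memallo import constants

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int]

#: Maximum covalent O-H / N-H bond length used to pair a donor heavy atom
#: with its hydrogen when no bond table exists.
_DONOR_H_MAX = 1.25

#: Numeric guard so fixtures built exactly at a cutoff stay inclusive despite
#: floating-point reconstruction error.
_EDGE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _attached_hydrogens(structure: Structure, donor_idx: int,
                        box: np.ndarray | None) -> list[int]:
    """Hydrogens of the donor's residue within covalent range of the donor."""
    mask = (
        (structure.chains == structure.chains[donor_idx])
        & (structure.resids == structure.resids[donor_idx])
        & (structure.elements == "H")
    )
    hyd = np.flatnonzero(mask)
    if len(hyd) == 0:
        return []
    delta = minimum_image(
        structure.coordinates[hyd] - structure.coordinates[donor_idx], box
    )
    dist = np.linalg.norm(delta, axis=1)
    return [int(h) for h, d in zip(hyd, dist) if d <= _DONOR_H_MAX]


def hbond_contacts(
    frame: Structure,
    donors: Selection | str,
    acceptors: Selection | str,
    d_max: float = constants.HBOND_DISTANCE,
    angle_min: float = constants.HBOND_ANGLE,
    box: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Hydrogen-bonded (donor heavy atom, acceptor atom) index pairs.

    ``donors`` selects donor heavy atoms (O/N); each must have a hydrogen in
    the same residue within covalent range, resolved geometrically. Donors
    without a resolvable hydrogen are skipped with a logged count.
    """
    dsel = as_selection(donors)
    asel = as_selection(acceptors)
    d_idx = dsel.resolve(frame)
    a_idx = asel.resolve(frame)
    pairs: list[tuple[int, int]] = []
    skipped = 0
    for d in d_idx:
        hydrogens = _attached_hydrogens(frame, int(d), box)
        if not hydrogens:
            skipped += 1
            continue
        for a in a_idx:
            if a == d:
                continue
            da = minimum_image(frame.coordinates[a] - frame.coordinates[d], box)
            if np.linalg.norm(da) > d_max + _EDGE_TOL:
                continue
            for h in hydrogens:
                hd = minimum_image(frame.coordinates[d] - frame.coordinates[h], box)
                ha = minimum_image(frame.coordinates[a] - frame.coordinates[h], box)
                cosang = float(hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if angle >= angle_min - _EDGE_TOL:
                    pairs.append((int(d), int(a)))
                    break
    if skipped:
        logger.warning("hbond_contacts: %d donors had no resolvable hydrogen", skipped)
    return pairs


# ---------------------------------------------------------------------------
# Hydrophobic contacts
# ---------------------------------------------------------------------------

def hydrophobic_contacts(
    frame: Structure,
    sel_a: Selection | str,
    sel_b: Selection | str,
    d_max: float = constants.HYDROPHOBIC_DISTANCE,
    box: np.ndarray | None = None,
    elements: tuple[str, ...] = ("C", "S"),
) -> list[tuple[ResidueKey, ResidueKey]]:
    """Residue pairs with any qualifying atom pair within ``d_max`` (inclusive).

    Selections are restricted to apolar elements (carbon/sulfur by default).
    """
    ia = as_selection(sel_a).resolve(frame)
    ib = as_selection(sel_b).resolve(frame)
    ia = ia[np.isin(frame.elements[ia], elements)]
    ib = ib[np.isin(frame.elements[ib], elements)]
    if len(ia) == 0 or len(ib) == 0:
        return []
    dist = pairwise_min_image_distances(
        frame.coordinates[ia], frame.coordinates[ib], box
    )
    close = np.argwhere(dist <= d_max + _EDGE_TOL)
    out: set[tuple[ResidueKey, ResidueKey]] = set()
    for i, j in close:
        ra = (str(frame.chains[ia[i]]), int(frame.resids[ia[i]]))
        rb = (str(frame.chains[ib[j]]), int(frame.resids[ib[j]]))
        if ra != rb:
            out.add((ra, rb))
    return sorted(out)


# ---------------------------------------------------------------------------
# Interaction fingerprints
# ---------------------------------------------------------------------------

@dataclass
class FingerprintParams:
    hbond_distance: float = constants.HBOND_DISTANCE
    hbond_angle: float = constants.HBOND_ANGLE
    hydrophobic_distance: float = constants.HYDROPHOBIC_DISTANCE


def fingerprint(
    traj: Trajectory,
    ligand_sel: Selection | str,
    protein_sel: Selection | str,
    params: FingerprintParams | None = None,
) -> pd.DataFrame:
    """Per-residue interaction frequencies over all frames.

    Three interaction classes per protein residue: ``hbond_donor`` (protein
    donates the hydrogen), ``hbond_acceptor`` (ligand donates), and
    ``hydrophobic``. Values are fractions of analyzed frames in [0, 1].
    """
    params = params or FingerprintParams()
    lsel = as_selection(ligand_sel)
    psel = as_selection(protein_sel)
    if len(lsel.resolve(traj.topology)) == 0:
        raise SelectionError(f"ligand selection {lsel.expression!r} matches nothing")
    p_idx = psel.resolve(traj.topology)
    res_keys = traj.topology.residue_keys(p_idx)
    counts = {rk: {"hbond_donor": 0, "hbond_acceptor": 0, "hydrophobic": 0}
              for rk in res_keys}
    resname_of = {
        (str(traj.topology.chains[i]), int(traj.topology.resids[i])):
            str(traj.topology.resnames[i])
        for i in p_idx
    }

    n_used = 0
    for f in range(traj.n_frames):
        frame = traj.frame_structure(f)
        box = None if traj.box is None else traj.box[f]
        l_present = lsel.resolve(frame)
        if len(l_present) == 0:
            continue
        n_used += 1
        # protein-side donors/acceptors: O and N heavy atoms of the selection
        p_heavy = [i for i in p_idx if frame.elements[i] in ("O", "N")]
        l_heavy = [i for i in l_present if frame.elements[i] in ("O", "N")]
        seen: dict[ResidueKey, set[str]] = {}
        for pair_d, _ in _hbond_pairs(frame, p_heavy, l_heavy, params, box):
            rk = (str(frame.chains[pair_d]), int(frame.resids[pair_d]))
            seen.setdefault(rk, set()).add("hbond_donor")
        for _, pair_a in _hbond_pairs(frame, l_heavy, p_heavy, params, box):
            rk = (str(frame.chains[pair_a]), int(frame.resids[pair_a]))
            seen.setdefault(rk, set()).add("hbond_acceptor")
        for ra, _ in hydrophobic_contacts(
            frame, psel, lsel, params.hydrophobic_distance, box
        ):
            seen.setdefault(ra, set()).add("hydrophobic")
        for rk, classes in seen.items():
            if rk in counts:
                for c in classes:
                    counts[rk][c] += 1

    rows = []
    denom = max(n_used, 1)
    for rk in res_keys:
        rows.append({
            "chain": rk[0], "resid": rk[1], "resname": resname_of.get(rk, ""),
            "hbond_donor": counts[rk]["hbond_donor"] / denom,
            "hbond_acceptor": counts[rk]["hbond_acceptor"] / denom,
            "hydrophobic": counts[rk]["hydrophobic"] / denom,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_frames"] = n_used
    return df


def _hbond_pairs(frame, donor_idx, acceptor_idx, params, box):
    pairs = []
    for d in donor_idx:
        hydrogens = _attached_hydrogens(frame, int(d), box)
        if not hydrogens:
            continue
        for a in acceptor_idx:
            if a == d:
                continue
            da = minimum_image(frame.coordinates[a] - frame.coordinates[d], box)
            if np.linalg.norm(da) > params.hbond_distance + _EDGE_TOL:
                continue
            for h in hydrogens:
                hd = minimum_image(frame.coordinates[d] - frame.coordinates[h], box)
                ha = minimum_image(frame.coordinates[a] - frame.coordinates[h], box)
                cosang = float(hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= params.hbond_angle - _EDGE_TOL:
                    pairs.append((int(d), int(a)))
                    break
    return pairs


def pool_fingerprints(replicas: list[pd.DataFrame]) -> pd.DataFrame:
    """Frame-weighted mean of per-replica fingerprint tables."""
    if not replicas:
        raise ParameterError("no replica tables to pool")
    weights = np.array([df.attrs.get("n_frames", len(df)) for df in replicas], float)
    keys = ["chain", "resid", "resname"]
    base = replicas[0][keys].copy()
    cols = ["hbond_donor", "hbond_acceptor", "hydrophobic"]
    stacked = np.stack([df[cols].to_numpy() for df in replicas])
    pooled = np.tensordot(weights / weights.sum(), stacked, axes=1)
    out = base.assign(**{c: pooled[:, k] for k, c in enumerate(cols)})
    out.attrs["n_frames"] = int(weights.sum())
    return out


# ---------------------------------------------------------------------------
# Distance and RMSD series
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    values: np.ndarray  # Å per frame
    times: np.ndarray  # ns

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std())  # population SD


def pair_distance_series(
    traj: Trajectory,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
) -> DistanceSeries:
    """Per-frame minimum-image distance between two named atoms.

    Atoms are addressed as (chain, resid, atom_name); symmetric in its
    arguments.
    """
    ia = traj.topology.atom_index(*atom_a)
    ib = traj.topology.atom_index(*atom_b)
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        box = None if traj.box is None else traj.box[f]
        delta = minimum_image(traj.frames[f, ib] - traj.frames[f, ia], box)
        vals[f] = np.linalg.norm(delta)
    return DistanceSeries(vals, traj.times.copy())


def multi_copy_distance_series(
    traj: Trajectory,
    atom_a_per_copy: list[tuple[str, int, str]],
    atom_b_per_copy: list[tuple[str, int, str]],
) -> tuple[list[DistanceSeries], float, float]:
    """One series per ligand copy (e.g. five subunits) plus pooled mean ± SD."""
    if len(atom_a_per_copy) != len(atom_b_per_copy):
        raise ParameterError("copy lists must have equal length")
    series = [
        pair_distance_series(traj, a, b)
        for a, b in zip(atom_a_per_copy, atom_b_per_copy)
    ]
    pooled = np.concatenate([s.values for s in series])
    return series, float(pooled.mean()), float(pooled.std())


def rmsd_series(
    traj: Trajectory,
    selection: Selection | str,
    reference: Structure,
) -> np.ndarray:
    """Per-frame Kabsch-superposed RMSD (Å) to a reference structure."""
    sel = as_selection(selection)
    idx_t = sel.resolve(traj.topology)
    idx_r = sel.resolve(reference)
    if len(idx_t) != len(idx_r):
        raise SelectionError(
            f"selection resolves to {len(idx_t)} trajectory atoms but "
            f"{len(idx_r)} reference atoms"
        )
    ref = reference.coordinates[idx_r]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = superpose_kabsch(traj.frames[f, idx_t, :], ref)
    return out


# ---------------------------------------------------------------------------
# Pore radius profile
# ---------------------------------------------------------------------------

@dataclass
class PoreProfile:
    """Minimum accessible radius per slab along the pore axis.

    ``defined`` flags slabs that contained at least one atom inside the
    search cylinder; radii of undefined slabs are NaN, never zero.
    """

    z: np.ndarray  # slab centers, Å along the axis
    radius: np.ndarray  # Å, NaN where undefined
    defined: np.ndarray  # bool per slab
    slab: float


def pore_profile(
    structure: Structure,
    pore_selection: Selection | str | None = None,
    slab: float = constants.PORE_SLAB,
    search_radius: float = constants.PORE_SEARCH_RADIUS,
    radii_table: dict[str, float] | None = None,
    axis: np.ndarray | None = None,
) -> PoreProfile:
    """Simple straight-axis pore radius profile.

    The axis runs through the centroid of the pore-lining selection (whole
    structure when omitted); its direction defaults to the principal axis of
    the full coordinate set — right for tall membrane-spanning bundles — and
    can be given explicitly for squat geometries. Per slab the radius is min
    over atoms of (distance to axis − vdW radius); slabs with no atoms
    inside the search cylinder are flagged undefined.
    """
    radii_table = radii_table or constants.VDW_RADII
    coords = structure.coordinates
    if pore_selection is not None:
        idx = as_selection(pore_selection).resolve(structure)
        if len(idx) == 0:
            raise SelectionError("pore selection matches no atoms")
        center = coords[idx].mean(axis=0)
    else:
        center = coords.mean(axis=0)
    if axis is None:
        centered = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if axis[2] < 0:
        axis = -axis

    proj = (coords - center) @ axis
    radial = np.linalg.norm((coords - center) - proj[:, None] * axis, axis=1)
    vdw = np.array([radii_table.get(e, radii_table["X"]) for e in structure.elements])

    zmin, zmax = proj.min(), proj.max()
    n_slabs = max(1, int(np.ceil((zmax - zmin) / slab)))
    z_centers = zmin + (np.arange(n_slabs) + 0.5) * slab
    radius = np.full(n_slabs, np.nan)
    defined = np.zeros(n_slabs, dtype=bool)
    for k in range(n_slabs):
        lo, hi = zmin + k * slab, zmin + (k + 1) * slab
        in_slab = (proj >= lo) & (proj < hi) & (radial <= search_radius)
        if k == n_slabs - 1:
            in_slab |= (proj == hi) & (radial <= search_radius)
        if in_slab.any():
            radius[k] = float((radial[in_slab] - vdw[in_slab]).min())
            defined[k] = True
    return PoreProfile(z_centers, radius, defined, slab)
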