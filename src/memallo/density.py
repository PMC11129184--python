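"""Time-averaged 3D lipid occupancy grids and OpenDX export.

A voxel's occupancy is the fraction of trajectory frames in which at least
one selected lipid particle falls inside it (Volmap-style "occupancy" mode,
no Gaussian smearing). The grid resolution defaults to 1 Å. Reporting
keeps only voxels occupied in at least half of the frames, optionally
restricted to voxels near the protein surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from memallo.errors import ParameterError, SelectionError, TopologyError
from memallo.trajectory import Selection, Structure, Trajectory, as_selection
from memallo import constants


@dataclass
class OccupancyGrid:
    """Per-voxel occupancy fractions for one lipid type.

    Voxel (i,j,k) covers the half-open cube
    [origin + (i,j,k)*spacing, origin + (i+1,j+1,k+1)*spacing).
    """

    origin: np.ndarray  # 3-vector, Å
    spacing: float  # Å
    values: np.ndarray  # (nx, ny, nz) fractions in [0, 1]
    lipid_type: str = ""
    n_frames: int = 0

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [
            self.origin[d] + (np.arange(self.values.shape[d]) + 0.5) * self.spacing
            for d in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")


def compute_occupancy(
    traj: Trajectory,
    lipid_selection: Selection | str,
    spacing: float = constants.GRID_SPACING,
    lipid_type: str = "",
) -> OccupancyGrid:
    """Bin selected particles per frame; voxel value = occupied-frame fraction.

    Requires a constant orthorhombic box across frames; the grid origin is
    the box minimum corner (0, 0, 0) and particles are wrapped into the box
    by the minimum-image convention before binning.
    """
    if traj.box is None:
        raise TopologyError("occupancy analysis requires a periodic box")
    if not np.allclose(traj.box, traj.box[0]):
        raise TopologyError("occupancy analysis requires a constant box")
    box = traj.box[0]
    sel = as_selection(lipid_selection)
    idx = sel.resolve(traj.topology)
    if len(idx) == 0:
        raise SelectionError(f"selection {sel.expression!r} matches no atoms")
    dims = np.ceil(box / spacing).astype(int)
    counts = np.zeros(dims, dtype=np.int64)
    for f in range(traj.n_frames):
        pos = np.mod(traj.frames[f, idx, :], box)  # wrap into [0, L)
        vox = np.floor(pos / spacing).astype(int)
        vox = np.minimum(vox, dims - 1)  # guard float round-up at the edge
        uniq = np.unique(vox, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    values = counts / traj.n_frames
    return OccupancyGrid(
        np.zeros(3), spacing, values,
        lipid_type=lipid_type or sel.expression, n_frames=traj.n_frames,
    )


def protein_proximity_mask(
    grid: OccupancyGrid,
    protein_coords: np.ndarray,
    cutoff: float = constants.CONTACT_MASK_CUTOFF,
) -> np.ndarray:
    """Boolean grid: voxel centers within ``cutoff`` Å of any protein particle."""
    cx, cy, cz = grid.voxel_centers()
    centers = np.stack([cx, cy, cz], axis=-1).reshape(-1, 3)
    mask = np.zeros(len(centers), dtype=bool)
    c2 = cutoff * cutoff
    for p in np.asarray(protein_coords, dtype=float):
        d2 = ((centers - p) ** 2).sum(axis=1)
        mask |= d2 <= c2
    return mask.reshape(grid.values.shape)


def threshold_grid(
    grid: OccupancyGrid,
    min_occupancy: float = constants.MIN_OCCUPANCY,
    contact_mask: np.ndarray | None = None,
) -> OccupancyGrid:
    """Zero voxels below ``min_occupancy`` (inclusive keep) and outside the mask."""
    if not 0.0 <= min_occupancy <= 1.0:
        raise ParameterError("min_occupancy must be in [0, 1]")
    values = np.where(grid.values >= min_occupancy, grid.values, 0.0)
    if contact_mask is not None:
        if contact_mask.shape != grid.values.shape:
            raise ParameterError(
                f"contact mask shape {contact_mask.shape} != grid "
                f"shape {grid.values.shape}"
            )
        values = np.where(contact_mask, values, 0.0)
    return replace(grid, values=values)


def write_dx(grid: OccupancyGrid, path: str | Path) -> None:
    """Write the grid as an OpenDX scalar file (VMD/PyMOL-compatible)."""
    from gridData import Grid

    g = Grid(
        grid.values,
        origin=np.asarray(grid.origin, dtype=float) + grid.spacing / 2.0,
        delta=[grid.spacing] * 3,
    )
    g.export(str(path), file_format="dx")


def read_dx(path: str | Path) -> OccupancyGrid:
    """Read an OpenDX scalar file back into an OccupancyGrid."""
    from gridData import Grid

    g = Grid(str(path))
    spacing = float(g.delta[0])
    origin = np.asarray(g.origin, dtype=float) - spacing / 2.0
    return OccupancyGrid(origin, spacing, np.asarray(g.grid, dtype=float))
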