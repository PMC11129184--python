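"""Structure/trajectory data model, readers, selections, and superposition.

Units are Å for coordinates and box lengths and ns for times throughout the
package; nm/ps based formats (XTC) are converted at the boundary. Only
orthorhombic boxes are supported — triclinic input raises an explicit error.
Residue numbering is 1-based PDB style at the interface; atom indices are
0-based internally.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from memallo.errors import (
    IllPosedError,
    InsufficientDataError,
    ParseError,
    SelectionError,
    TopologyError,
)

# Two-letter element symbols that can appear at the start of an atom name in
# membrane/protein systems; everything else is resolved by first letter.
_TWO_LETTER_ELEMENTS = {"CL", "NA", "MG", "ZN", "FE", "BR", "CA2"}


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name when no element column exists."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in _TWO_LETTER_ELEMENTS:
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass
class Structure:
    """A static set of atoms with names, residue identity, and coordinates (Å).

    Lookup is by ``(chain_id, residue_number)``; no ordering of residue
    numbers within a chain is assumed.
    """

    atom_names: np.ndarray  # (N,) str
    elements: np.ndarray  # (N,) str
    resids: np.ndarray  # (N,) int, 1-based PDB numbering
    resnames: np.ndarray  # (N,) str
    chains: np.ndarray  # (N,) str
    coordinates: np.ndarray  # (N, 3) float, Å

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.atom_names)
        if self.coordinates.shape != (n, 3):
            raise TopologyError(
                f"coordinate array shape {self.coordinates.shape} does not "
                f"match atom count {n}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            self.atom_names[idx],
            self.elements[idx],
            self.resids[idx],
            self.resnames[idx],
            self.chains[idx],
            self.coordinates[idx],
        )

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        """Index of a single named atom; raises SelectionError if not unique."""
        mask = (self.chains == chain) & (self.resids == resid) & (self.atom_names == name)
        hits = np.flatnonzero(mask)
        if len(hits) == 0:
            raise SelectionError(f"no atom {name!r} in chain {chain!r} resid {resid}")
        if len(hits) > 1:
            raise SelectionError(
                f"atom {name!r} in chain {chain!r} resid {resid} is not unique"
            )
        return int(hits[0])

    def residue_keys(self, indices: Sequence[int] | None = None) -> list[tuple[str, int]]:
        """Unique (chain, resid) pairs in first-appearance order."""
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        seen: dict[tuple[str, int], None] = {}
        for i in idx:
            seen.setdefault((str(self.chains[i]), int(self.resids[i])), None)
        return list(seen)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``frames`` is (n_frames, N, 3) in Å, ``times`` in ns (strictly
    increasing; spacing may be irregular), ``box`` per-frame orthorhombic
    box lengths in Å or None for non-periodic systems.
    """

    topology: Structure
    frames: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frame atom count {self.frames.shape[1]} != topology atom "
                f"count {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise TopologyError("times length must equal frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TopologyError("frame times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape == (3,):
                self.box = np.tile(self.box, (len(self.frames), 1))
            if self.box.shape != (len(self.frames), 3):
                raise TopologyError("box must be per-frame 3 lengths")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __len__(self) -> int:
        return self.n_frames

    def frame_structure(self, i: int) -> Structure:
        s = self.topology.subset(np.arange(self.n_atoms))
        s.coordinates = self.frames[i].copy()
        return s


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[()]|[^\s()]+")
_KEYWORDS = {"name", "resid", "resname", "chain", "and", "or", "not", "(", ")"}


class Selection:
    """Boolean atom selection over name/resid/resname/chain.

    Grammar (``and`` binds tighter than ``or``)::

        expr     := or_expr
        or_expr  := and_expr ("or" and_expr)*
        and_expr := not_expr ("and" not_expr)*
        not_expr := "not" not_expr | "(" expr ")" | primitive
        primitive:= ("name"|"resname"|"chain") VALUE+
                  | "resid" (INT | INT:INT)+

    Resolving against a Structure yields a sorted, deterministic index array.
    """

    def __init__(self, expression: str):
        self.expression = expression
        tokens = _TOKEN_RE.findall(expression)
        if not tokens:
            raise SelectionError("empty selection expression")
        self._tokens = tokens
        self._pos = 0
        self._ast = self._parse_or()
        if self._pos != len(self._tokens):
            raise SelectionError(
                f"unexpected token {self._tokens[self._pos]!r} in "
                f"selection {expression!r}"
            )

    def __repr__(self) -> str:
        return f"Selection({self.expression!r})"

    # -- parser -------------------------------------------------------------
    def _peek(self) -> str | None:
        return self._tokens[self._pos] if self._pos < len(self._tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection {self.expression!r}")
        self._pos += 1
        return tok

    def _parse_or(self):
        node = self._parse_and()
        while self._peek() == "or":
            self._next()
            node = ("or", node, self._parse_and())
        return node

    def _parse_and(self):
        node = self._parse_not()
        while self._peek() == "and":
            self._next()
            node = ("and", node, self._parse_not())
        return node

    def _parse_not(self):
        tok = self._peek()
        if tok == "not":
            self._next()
            return ("not", self._parse_not())
        if tok == "(":
            self._next()
            node = self._parse_or()
            if self._next() != ")":
                raise SelectionError(f"unbalanced parentheses in {self.expression!r}")
            return node
        return self._parse_primitive()

    def _parse_primitive(self):
        key = self._next()
        if key not in ("name", "resname", "chain", "resid"):
            raise SelectionError(f"unknown selection keyword {key!r}")
        values: list[str] = []
        while self._peek() is not None and self._peek() not in _KEYWORDS:
            values.append(self._next())
        if not values:
            raise SelectionError(f"keyword {key!r} requires at least one value")
        if key == "resid":
            ranges: list[tuple[int, int]] = []
            for v in values:
                m = re.fullmatch(r"(-?\d+)(?::(-?\d+))?", v)
                if not m:
                    raise SelectionError(f"bad resid value {v!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                ranges.append((lo, hi))
            return ("resid", ranges)
        return (key, values)

    # -- evaluation ---------------------------------------------------------
    def _eval(self, node, structure: Structure) -> np.ndarray:
        op = node[0]
        if op == "or":
            return self._eval(node[1], structure) | self._eval(node[2], structure)
        if op == "and":
            return self._eval(node[1], structure) & self._eval(node[2], structure)
        if op == "not":
            return ~self._eval(node[1], structure)
        if op == "name":
            return np.isin(structure.atom_names, node[1])
        if op == "resname":
            return np.isin(structure.resnames, node[1])
        if op == "chain":
            return np.isin(structure.chains, node[1])
        if op == "resid":
            mask = np.zeros(structure.n_atoms, dtype=bool)
            for lo, hi in node[1]:
                mask |= (structure.resids >= lo) & (structure.resids <= hi)
            return mask
        raise SelectionError(f"internal: unknown node {op!r}")

    def resolve(self, structure: Structure) -> np.ndarray:
        """Sorted 0-based indices of atoms matching the expression."""
        return np.flatnonzero(self._eval(self._ast, structure))


def as_selection(sel: "Selection | str") -> Selection:
    return sel if isinstance(sel, Selection) else Selection(sel)


# ---------------------------------------------------------------------------
# PDB I/O (strict fixed-column reader; see docs/methods.md for rationale)
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records from a PDB file into a Structure.

    Insertion codes are rejected rather than silently merged; malformed
    records raise ParseError naming the offending line.
    """
    names, elements, resids, resnames, chains, coords = [], [], [], [], [], []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            try:
                name = line[12:16].strip()
                icode = line[26].strip() if len(line) > 26 else ""
                resname = line[17:21].strip()
                chain = line[21].strip() or "A"
                resid = int(line[22:26])
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: malformed record at line {lineno}: {exc}") from exc
            if icode:
                raise ParseError(
                    f"{path}: insertion code {icode!r} at line {lineno} is not "
                    "supported; renumber residues first"
                )
            element = line[76:78].strip() if len(line) >= 78 else ""
            names.append(name)
            elements.append(element or infer_element(name))
            resids.append(resid)
            resnames.append(resname)
            chains.append(chain)
            coords.append(xyz)
    if not names:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(
        np.array(names),
        np.array(elements),
        np.array(resids, dtype=int),
        np.array(resnames),
        np.array(chains),
        np.array(coords, dtype=float),
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as minimal ATOM records."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            name = structure.atom_names[i]
            # PDB convention: names of <4 chars start in column 14
            fname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            x, y, z = structure.coordinates[i]
            fh.write(
                f"ATOM  {(i + 1) % 100000:5d} {fname}{'':1s}{structure.resnames[i]:<4s}"
                f"{structure.chains[i]:1s}{structure.resids[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{structure.elements[i]:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectory I/O via MDAnalysis (XTC, DCD, GRO)
# ---------------------------------------------------------------------------

def _check_orthorhombic(dims: np.ndarray | None) -> np.ndarray | None:
    if dims is None or not np.any(dims[:3]):
        return None
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise TopologyError(
            f"triclinic box (angles {dims[3:6]}) is not supported; "
            "only orthorhombic boxes are handled"
        )
    return np.asarray(dims[:3], dtype=float)


def read_structure(path: str | Path) -> Structure:
    """Read a single-frame structure from PDB or GRO."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        return read_pdb(path)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    try:
        chains = np.array([str(s) for s in atoms.segids])
    except Exception:
        chains = np.array(["A"] * len(atoms))
    chains = np.where(np.char.str_len(chains) == 0, "A", chains)
    return Structure(
        np.array(atoms.names),
        np.array([infer_element(n) for n in atoms.names]),
        np.array(atoms.resids, dtype=int),
        np.array(atoms.resnames),
        chains,
        atoms.positions.astype(float),
    )


def read_trajectory(structure_path: str | Path, trajectory_path: str | Path) -> Trajectory:
    """Read an XTC/DCD trajectory against a PDB/GRO topology.

    Coordinates are returned in Å and times in ns regardless of the on-disk
    format. A truncated trajectory raises ParseError naming the last frame
    read successfully.
    """
    import MDAnalysis as mda

    topology = read_structure(structure_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(structure_path), str(trajectory_path))
        except (ValueError, IOError) as exc:
            raise TopologyError(
                f"cannot pair {trajectory_path} with {structure_path}: {exc}"
            ) from exc
    if u.atoms.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"trajectory atom count {u.atoms.n_atoms} != structure atom count "
            f"{topology.n_atoms}"
        )
    frames, times, boxes = [], [], []
    n_read = 0
    try:
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float).copy())
            times.append(float(ts.time) / 1000.0)  # ps -> ns
            boxes.append(_check_orthorhombic(ts.dimensions))
            n_read += 1
    except (EOFError, IOError, OSError) as exc:
        raise ParseError(
            f"{trajectory_path}: truncated after frame {n_read - 1} "
            f"(0-based): {exc}"
        ) from exc
    if n_read == 0:
        raise ParseError(f"{trajectory_path}: no frames readable")
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        # DCD files often carry no time metadata; fall back to frame index
        times_arr = np.arange(len(frames), dtype=float)
    box = None if boxes[0] is None else np.asarray(boxes)
    return Trajectory(topology, np.asarray(frames), times_arr, box)


def write_trajectory(traj: Trajectory, structure_path: str | Path,
                     trajectory_path: str | Path) -> None:
    """Write topology (PDB) and coordinates (XTC or DCD, by extension)."""
    import MDAnalysis as mda

    write_pdb(traj.topology, structure_path)
    n = traj.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(trajectory_path), n_atoms=n) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.frames[i]
                ts = u.trajectory.ts
                ts.time = traj.times[i] * 1000.0  # ns -> ps
                ts.frame = i
                if traj.box is not None:
                    ts.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Geometry: minimum image, Kabsch superposition, RMSD
# ---------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors (orthorhombic)."""
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def pairwise_min_image_distances(a: np.ndarray, b: np.ndarray,
                                 box: np.ndarray | None) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image distances."""
    delta = a[:, None, :] - b[None, :, :]
    delta = minimum_image(delta, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))


def superpose_kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD to
    ``reference``. The rotation is always proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise IllPosedError("mobile and reference must both be N×3")
    n = len(mobile)
    if n < 3:
        raise IllPosedError(f"need at least 3 points for superposition, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise IllPosedError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)

    sv = np.linalg.svd(ref_c * w[:, None], compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise IllPosedError("reference geometry is degenerate (collinear points)")

    h = (mob_c * w[:, None]).T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = (w[:, None] * reference).sum(axis=0) - rotation @ (
        (w[:, None] * mobile).sum(axis=0)
    )
    diff = mob_c @ rotation.T - ref_c
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation
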