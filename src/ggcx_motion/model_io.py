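"""Coordinate-model and trajectory I/O, atom selections, time-series export.

Containers are deliberately thin: a :class:`Structure` is an ordered list of
atoms with author numbering preserved, a :class:`Trajectory` is an ``F x N x 3``
coordinate array sharing one topology, and a :class:`TimeSeries` is a scalar
order parameter sampled on the frame times.  Parsing and writing of PDB/mmCIF
is delegated to :mod:`gemmi`; trajectories travel as multi-model PDB (the
always-available interchange dialect), with DCD/XTC readable through an
optional MDAnalysis adapter.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSelection",
    "TimeSeries",
    "FormatError",
    "SelectionError",
    "load_structure",
    "write_structure",
    "load_trajectory",
    "write_trajectory",
    "select",
    "write_timeseries",
    "read_timeseries",
]


class FormatError(ValueError):
    """Raised when a coordinate file cannot be parsed or is inconsistent."""


class SelectionError(ValueError):
    """Raised for malformed selection expressions or invalid selections."""


@dataclass(frozen=True)
class Atom:
    """One atom record; ``resid`` keeps the author numbering of the source."""

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    icode: str = ""

    @property
    def resid_key(self) -> str:
        """Residue number with any insertion code concatenated."""
        return f"{self.resid}{self.icode}"


@dataclass
class Structure:
    """An ordered collection of atoms from one coordinate model."""

    atoms: list[Atom]
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_positions(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise FormatError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        new_atoms = [
            Atom(a.serial, a.name, a.resname, a.resid, a.chain, a.element,
                 tuple(float(v) for v in xyz), a.occupancy, a.altloc, a.icode)
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(new_atoms, self.label if label is None else label)

    def find_atom(self, chain: str, resid: int, name: str) -> Atom:
        """Look up one atom by (chain, resid, name); altlocs already resolved."""
        for a in self.atoms:
            if a.chain == chain and a.resid == resid and a.name == name:
                return a
        raise SelectionError(
            f"no atom matching chain={chain!r} resid={resid} name={name!r}"
        )


@dataclass
class Trajectory:
    """Frames of coordinates over one topology, with frame times in ns."""

    topology: Structure
    frames: np.ndarray  # (F, N, 3), Angstrom
    times: np.ndarray  # (F,), ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise FormatError(f"frames must be (F, N, 3); got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology):
            raise FormatError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )
        if self.frames.shape[0] != self.times.shape[0]:
            raise FormatError("times length must equal number of frames")
        if self.frames.shape[0] < 1:
            raise FormatError("trajectory needs at least one frame")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_positions(self.frames[i])


@dataclass
class AtomSelection:
    """Ordered atom indices into a structure plus the expression that made them."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class TimeSeries:
    """A scalar order parameter per frame (cos theta, dr, RMSD...)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise FormatError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"non-finite values in series {self.label!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        """Sample interval in ns; raises if sampling is not uniform."""
        if len(self.times) < 2:
            raise ValueError("need at least two samples to define dt")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"series {self.label!r} is not uniformly sampled")
        return float(steps[0])


# ---------------------------------------------------------------------------
# structure / trajectory I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _read_gemmi(path: Path) -> gemmi.Structure:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    return st


def _model_to_structure(
    model: gemmi.Model, label: str, altloc_policy: str = "occupancy"
) -> Structure:
    if altloc_policy not in ("occupancy", "first", "all"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            # group altlocs by atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                if altloc_policy == "all" or len(group) == 1:
                    chosen = group
                elif altloc_policy == "first":
                    chosen = [group[0]]
                else:  # highest occupancy, ties broken toward altloc "A"/earliest
                    chosen = [min(group, key=lambda a: (-a.occ, a.altloc or "~"))]
                for at in chosen:
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            name=at.name,
                            resname=res.name,
                            resid=res.seqid.num,
                            chain=chain.name,
                            element=at.element.name,
                            position=(at.pos.x, at.pos.y, at.pos.z),
                            occupancy=at.occ,
                            altloc=at.altloc or "",
                            icode=(res.seqid.icode or "").strip(),
                        )
                    )
    return Structure(atoms, label)


def load_structure(
    path: str | Path, model_index: int = 0, altloc_policy: str = "occupancy"
) -> Structure:
    """Read one model from a PDB or mmCIF file.

    Parameters
    ----------
    path:
        Coordinate file; dialect auto-detected by gemmi from extension/content.
    model_index:
        Zero-based model number within the file.
    altloc_policy:
        ``"occupancy"`` (default) keeps the highest-occupancy alternate
        location, ties resolved toward altloc ``A``; ``"first"`` keeps the
        first record; ``"all"`` keeps every altloc.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = _read_gemmi(path)
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model_index {model_index} out of range; {path} has {len(st)} model(s)"
        )
    label = f"{path.name}[model {model_index}]"
    return _model_to_structure(st[model_index], label, altloc_policy)


def _structure_to_gemmi(structure: Structure, name: str = "model") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        chain = chains[a.chain]
        res_key = (a.resid, a.icode)
        if len(chain) == 0 or (chain[-1].seqid.num, (chain[-1].seqid.icode or "").strip()) != res_key or chain[-1].name != a.resname:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resid, a.icode or " ")
            chain.add_residue(res)
        res = chain[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.altloc = a.altloc or "\0"
        at.serial = a.serial
        res.add_atom(at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as PDB (``.pdb``) or mmCIF (``.cif``/``.mmcif``)."""
    path = Path(path)
    st = _structure_to_gemmi(structure, path.stem)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def load_trajectory(
    topology_path: str | Path,
    frames_path: str | Path | None = None,
    frame_dt_ns: float = 1.0,
) -> Trajectory:
    """Read a trajectory from multi-model PDB (or DCD/XTC via MDAnalysis).

    ``frames_path`` may be omitted when the topology file itself is the
    multi-model trajectory.  Frame times are ``i * frame_dt_ns`` unless the
    format carries its own times.
    """
    if frame_dt_ns <= 0:
        raise ValueError("frame_dt_ns must be positive")
    topology_path = Path(topology_path)
    frames_path = Path(frames_path) if frames_path is not None else topology_path

    topology = load_structure(topology_path, model_index=0)

    if frames_path.suffix.lower() in (".dcd", ".xtc", ".trr"):
        return _load_binary_trajectory(topology, topology_path, frames_path, frame_dt_ns)

    st = _read_gemmi(frames_path)
    frames = []
    for model in st:
        coords = [
            (at.pos.x, at.pos.y, at.pos.z)
            for chain in model
            for res in chain
            for at in res
        ]
        frames.append(coords)
    frames_arr = np.array(frames, dtype=float)
    if frames_arr.shape[1] != len(topology):
        raise FormatError(
            f"atom count mismatch: topology has {len(topology)} atoms but "
            f"frames have {frames_arr.shape[1]}"
        )
    times = np.arange(frames_arr.shape[0]) * frame_dt_ns
    return Trajectory(topology, frames_arr, times)


def _load_binary_trajectory(
    topology: Structure, topology_path: Path, frames_path: Path, frame_dt_ns: float
) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise FormatError(
            f"binary trajectory {frames_path.suffix} requires MDAnalysis"
        ) from exc
    u = mda.Universe(str(topology_path), str(frames_path))
    if len(u.atoms) != len(topology):
        raise FormatError(
            f"atom count mismatch: topology has {len(topology)} atoms but "
            f"trajectory has {len(u.atoms)}"
        )
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    times = np.arange(frames.shape[0]) * frame_dt_ns
    return Trajectory(topology, frames, times)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    path = Path(path)
    st = _structure_to_gemmi(traj.topology, path.stem)
    base_model = st[0]
    # replace models with one per frame
    st2 = gemmi.Structure()
    st2.name = st.name
    for fi in range(traj.n_frames):
        model = gemmi.Model(fi + 1)
        coords = traj.frames[fi]
        ai = 0
        for chain in base_model:
            new_chain = gemmi.Chain(chain.name)
            for res in chain:
                new_res = gemmi.Residue()
                new_res.name = res.name
                new_res.seqid = res.seqid
                for at in res:
                    new_at = gemmi.Atom()
                    new_at.name = at.name
                    new_at.element = at.element
                    new_at.occ = at.occ
                    new_at.altloc = at.altloc
                    new_at.serial = at.serial
                    new_at.pos = gemmi.Position(*coords[ai])
                    ai += 1
                    new_res.add_atom(new_at)
                new_chain.add_residue(new_res)
            model.add_chain(new_chain)
        st2.add_model(model)
    st2.setup_entities()
    st2.write_pdb(str(path))


# ---------------------------------------------------------------------------
# selection grammar: clauses joined by "and"
#   chain A [B ...] | resid 220-246 [7 9-12 ...] | name CA [CB ...]
# ---------------------------------------------------------------------------

_RESID_TOKEN = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _parse_expression(expression: str) -> list[tuple[str, object]]:
    clauses = []
    pos = 0
    for part in expression.split(" and "):
        stripped = part.strip()
        if not stripped:
            raise SelectionError(
                f"empty clause at position {pos} in {expression!r}"
            )
        tokens = stripped.split()
        keyword, args = tokens[0].lower(), tokens[1:]
        if not args:
            raise SelectionError(
                f"clause {stripped!r} at position {pos} has no arguments"
            )
        if keyword == "chain":
            clauses.append(("chain", set(args)))
        elif keyword == "name":
            clauses.append(("name", {a.upper() for a in args}))
        elif keyword == "resid":
            ranges: list[tuple[int, int]] = []
            for tok in args:
                m = _RESID_TOKEN.match(tok)
                if not m:
                    raise SelectionError(
                        f"bad resid token {tok!r} at position "
                        f"{expression.find(tok)} in {expression!r}"
                    )
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                if hi < lo:
                    raise SelectionError(f"inverted resid range {tok!r}")
                ranges.append((lo, hi))
            clauses.append(("resid", ranges))
        else:
            raise SelectionError(
                f"unknown keyword {keyword!r} at position {expression.find(keyword)} "
                f"in {expression!r}; expected chain/resid/name"
            )
        pos += len(part) + len(" and ")
    return clauses


def select(structure: Structure, expression: str) -> AtomSelection:
    """Resolve a selection expression against a structure.

    The grammar supports ``chain``, ``resid`` (single numbers and inclusive
    ranges) and ``name`` clauses joined by ``and``, e.g.
    ``"chain A and resid 220-246 and name CA"``.  Indices come back in
    topology order; an empty result is allowed but warned about.
    """
    clauses = _parse_expression(expression)
    indices = []
    for i, atom in enumerate(structure.atoms):
        ok = True
        for kind, arg in clauses:
            if kind == "chain" and atom.chain not in arg:
                ok = False
            elif kind == "name" and atom.name.upper() not in arg:
                ok = False
            elif kind == "resid" and not any(lo <= atom.resid <= hi for lo, hi in arg):
                ok = False
            if not ok:
                break
        if ok:
            indices.append(i)
    if not indices:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return AtomSelection(np.array(indices, dtype=int), expression)


# ---------------------------------------------------------------------------
# time-series CSV export (long format: time_ns, metric, value)
# ---------------------------------------------------------------------------

def write_timeseries(series: Sequence[TimeSeries], path: str | Path) -> None:
    """Write series as long-format CSV, time-major then metric-name ordered.

    The ordering is bit-stable: rewriting a read-back file reproduces it
    byte for byte.
    """
    rows: list[tuple[float, str, float]] = []
    for s in series:
        label = s.label or "value"
        for t, v in zip(s.times, s.values):
            rows.append((float(t), label, float(v)))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ns", "metric", "value"])
        for t, label, v in rows:
            w.writerow([repr(t), label, repr(v)])


def read_timeseries(path: str | Path) -> list[TimeSeries]:
    """Read back a long-format CSV written by :func:`write_timeseries`."""
    by_metric: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["time_ns", "metric", "value"]:
            raise FormatError(f"unexpected header {header} in {path}")
        for t, metric, v in reader:
            by_metric.setdefault(metric, []).append((float(t), float(v)))
    out = []
    for metric in sorted(by_metric):
        pts = sorted(by_metric[metric])
        out.append(
            TimeSeries(
                np.array([p[0] for p in pts]),
                np.array([p[1] for p in pts]),
                label=metric,
            )
        )
    return out
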