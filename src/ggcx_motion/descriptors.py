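"""Per-frame order parameters and per-residue fluctuation profiles.

These are the quantities that summarize helix/cap conformational dynamics in
an aligned trajectory:

* ``cos_theta_series`` — cosine of the angle between the helix axis in each
  frame and its reference-frame orientation (1 means unchanged);
* ``dr_series`` — displacement (Å) of a selection's center of mass from its
  reference-frame position;
* ``rmsf_per_residue`` — root-mean-square fluctuation of each residue's CA
  about its time-mean (or a fixed-frame) position;
* ``rmsd_series`` — per-frame RMSD to a reference frame, fitted or not.

All of them assume the trajectory has already been superposed on a rigid
core (see :func:`ggcx_motion.geometry.align_trajectory`); the reference frame
defaults to frame 0, the "initial" conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DegeneracyError, center_of_mass, helix_axis, kabsch
from .model_io import AtomSelection, Structure, TimeSeries, Trajectory

__all__ = [
    "RmsfProfile",
    "cos_theta_series",
    "dr_series",
    "rmsf_per_residue",
    "rmsd_series",
    "summarize_replicates",
]


@dataclass
class RmsfProfile:
    """Per-residue RMSF with an exclusion mask for summaries.

    Excluded residues (N-terminal stubs, ill-defined loops) keep their values
    but are masked out of aggregate statistics.
    """

    residues: list[tuple[str, int]]  # ordered (chain, resid)
    rmsf: np.ndarray  # Angstrom
    excluded: np.ndarray  # boolean mask, True = excluded
    ref: str | int = "mean"
    spread: np.ndarray | None = None  # min-max spread across replicates

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not (len(self.residues) == len(self.rmsf) == len(self.excluded)):
            raise ValueError("residues, rmsf and excluded must align")
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf values must be non-negative")

    @property
    def included_rmsf(self) -> np.ndarray:
        return self.rmsf[~self.excluded]

    def subset(self, resids: set[int]) -> np.ndarray:
        """RMSF values of the given residue numbers (mask ignored)."""
        return np.array(
            [v for (ch, ri), v in zip(self.residues, self.rmsf) if ri in resids]
        )


def cos_theta_series(
    traj: Trajectory, helix: AtomSelection, ref_frame: int = 0
) -> TimeSeries:
    """cos θ(t): dot product of the helix axis in frame t with the reference axis.

    The helix selection must be CA atoms in N→C order.  Values lie in [−1, 1]
    and equal 1 exactly at the reference frame.
    """
    idx = helix.indices
    try:
        ref_axis = helix_axis(traj.frames[ref_frame][idx])
    except (DegeneracyError, ValueError) as exc:
        raise DegeneracyError(f"degenerate helix in frame {ref_frame}: {exc}") from exc
    values = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        if fi == ref_frame:
            values[fi] = 1.0
            continue
        try:
            ax = helix_axis(traj.frames[fi][idx])
        except (DegeneracyError, ValueError) as exc:
            raise DegeneracyError(f"degenerate helix in frame {fi}: {exc}") from exc
        values[fi] = np.clip(np.dot(ax, ref_axis), -1.0, 1.0)
    return TimeSeries(traj.times.copy(), values, label="cos_theta", units="")


def dr_series(
    traj: Trajectory,
    cap: AtomSelection,
    ref_frame: int = 0,
    mass_weighted: bool = False,
) -> TimeSeries:
    """dr(t): displacement of the selection's center of mass from the reference frame."""
    if len(cap) == 0:
        raise ValueError("empty cap selection")
    ref_com = center_of_mass(
        traj.frames[ref_frame], cap, traj.topology, mass_weighted=mass_weighted
    )
    values = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        if fi == ref_frame:
            values[fi] = 0.0
            continue
        com = center_of_mass(
            traj.frames[fi], cap, traj.topology, mass_weighted=mass_weighted
        )
        values[fi] = np.linalg.norm(com - ref_com)
    return TimeSeries(traj.times.copy(), values, label="dr", units="Angstrom")


def rmsf_per_residue(
    traj: Trajectory,
    atoms: AtomSelection,
    reference: str | int = "mean",
    exclude: list[tuple[str, int]] | None = None,
    exclude_first_n: int = 0,
) -> RmsfProfile:
    """Per-residue RMSF over the trajectory for a one-atom-per-residue selection.

    ``reference="mean"`` (default) measures fluctuation about each atom's
    time-mean position; an integer measures deviation from that frame.
    ``exclude`` lists (chain, resid) pairs to mask; ``exclude_first_n``
    additionally masks the first n residues of the selection (terminal stubs).
    Masked residues keep their values but are dropped from summaries.
    """
    idx = atoms.indices
    residues: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for i in idx:
        a = traj.topology.atoms[i]
        key = (a.chain, a.resid)
        if key in seen:
            raise ValueError(f"residue {key} contributes more than one selected atom")
        seen.add(key)
        residues.append(key)

    coords = traj.frames[:, idx, :]  # (F, R, 3)
    if reference == "mean":
        ref = coords.mean(axis=0)
    else:
        ref = coords[int(reference)]
    rmsf = np.sqrt(((coords - ref) ** 2).sum(axis=2).mean(axis=0))

    excl_set = set(exclude or [])
    excluded = np.array(
        [
            (key in excl_set) or (k < exclude_first_n)
            for k, key in enumerate(residues)
        ]
    )
    return RmsfProfile(residues, rmsf, excluded, ref=reference)


def rmsd_series(
    traj: Trajectory,
    atoms: AtomSelection,
    ref_frame: int = 0,
    fit: bool = False,
) -> TimeSeries:
    """Per-frame RMSD to the reference frame over a selection.

    With ``fit=True`` each frame is first superposed on the reference using
    the same selection (the conventional "fitted RMSD").
    """
    idx = atoms.indices
    ref = traj.frames[ref_frame][idx]
    values = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        coords = traj.frames[fi][idx]
        if fit and fi != ref_frame:
            try:
                sup = kabsch(coords, ref)
            except DegeneracyError as exc:
                raise DegeneracyError(
                    f"degenerate selection in frame {fi} for fitted RMSD: {exc}"
                ) from exc
            values[fi] = sup.rmsd
        else:
            values[fi] = np.sqrt(((coords - ref) ** 2).sum(axis=1).mean())
    values[ref_frame] = 0.0
    label = "rmsd_fit" if fit else "rmsd"
    return TimeSeries(traj.times.copy(), values, label=label, units="Angstrom")


def summarize_replicates(profiles: list[RmsfProfile]) -> RmsfProfile:
    """Mean RMSF and min–max spread per residue across replicate runs.

    All profiles must share the same residue keys; a residue masked in any
    replicate stays masked in the summary.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    keys = profiles[0].residues
    for p in profiles[1:]:
        if p.residues != keys:
            a, b = set(keys), set(p.residues)
            raise ValueError(
                f"residue keys differ between replicates: "
                f"only-first={sorted(a - b)[:5]} only-other={sorted(b - a)[:5]}"
            )
    stacked = np.vstack([p.rmsf for p in profiles])
    mean = stacked.mean(axis=0)
    spread = stacked.max(axis=0) - stacked.min(axis=0)
    excluded = np.any(np.vstack([p.excluded for p in profiles]), axis=0)
    return RmsfProfile(list(keys), mean, excluded, ref=profiles[0].ref, spread=spread)
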