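"""Rigid-body superposition and geometric comparisons between conformations.

The building blocks here underlie every downstream measurement: weighted
Kabsch superposition (via scipy's quaternion solver, reflection-corrected),
core-based trajectory alignment, principal-axis helix orientation, centers of
mass, the domain-rotation angle between two static structures, and plain
atom-atom distances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import AtomSelection, Structure, Trajectory, select

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpositionResult",
    "RotationResult",
    "DegeneracyError",
    "PairingError",
    "ELEMENT_MASSES",
    "kabsch",
    "align_trajectory",
    "helix_axis",
    "center_of_mass",
    "domain_rotation",
    "atom_distance",
]


class DegeneracyError(ValueError):
    """Point set is too degenerate (collinear / isotropic) for the operation."""


class PairingError(ValueError):
    """Atoms could not be paired across two structures."""


# Standard atomic weights; a fixed internal table keeps mass-weighted results
# reproducible across environments.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "MN": 54.938, "NA": 22.990, "K": 39.098, "CL": 35.45,
}


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation mapping mobile onto reference.

    ``apply(x)`` returns ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class RotationResult:
    """Domain rotation between two structures after core superposition."""

    angle_deg: float
    axis: np.ndarray | None  # unit vector; None when angle ~ 0 (undefined)
    core_rmsd: float
    domain_rmsd_before: float
    domain_rmsd_after: float
    n_core_pairs: int
    n_domain_pairs: int


def _check_nondegenerate(coords: np.ndarray, what: str = "point set") -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    # collinear points have at most one nonzero singular value
    if len(s) < 2 or s[1] < 1e-8 * max(s[0], 1.0):
        raise DegeneracyError(f"{what} is collinear or degenerate")


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Uses the quaternion formulation (scipy ``align_vectors``), which excludes
    reflections by construction; RMSD is recomputed explicitly from the
    transformed coordinates.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (M, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    if weights is None:
        w = np.ones(mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    _check_nondegenerate(mobile, "mobile point set")
    _check_nondegenerate(reference, "reference point set")

    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_c = (w[:, None] * reference).sum(axis=0) / wsum
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c, weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum() / wsum))
    return SuperpositionResult(R, t, rmsd)


def align_trajectory(
    traj: Trajectory, core: AtomSelection, ref_frame: int = 0
) -> Trajectory:
    """Superpose every frame on ``ref_frame`` using the core atoms only.

    All atoms are transformed rigidly; the reference frame itself is left
    unchanged.  Raises :class:`DegeneracyError` naming the offending frame if
    the core atoms are degenerate anywhere.
    """
    if not 0 <= ref_frame < traj.n_frames:
        raise IndexError(f"ref_frame {ref_frame} out of range")
    idx = core.indices
    ref_coords = traj.frames[ref_frame][idx]
    aligned = np.empty_like(traj.frames)
    for fi in range(traj.n_frames):
        if fi == ref_frame:
            aligned[fi] = traj.frames[fi]
            continue
        try:
            sup = kabsch(traj.frames[fi][idx], ref_coords)
        except DegeneracyError as exc:
            raise DegeneracyError(f"degenerate core in frame {fi}: {exc}") from exc
        aligned[fi] = sup.apply(traj.frames[fi])
    return Trajectory(traj.topology, aligned, traj.times.copy())


def helix_axis(coords: np.ndarray) -> np.ndarray:
    """Orientation axis of a helix from its CA coordinates in N->C order.

    The axis is the principal axis (largest-variance direction) of the
    centered coordinates; for an ideal alpha-helix this coincides with the
    screw axis.  The sign is fixed so the vector points from the centroid of
    the N-terminal half toward the centroid of the C-terminal half.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (K, 3)")
    k = coords.shape[0]
    if k < 4:
        raise ValueError(f"need at least 4 CA positions for a helix axis; got {k}")
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12 or (s[0] - s[1]) / s[0] < 1e-6:
        raise DegeneracyError("no unique principal axis (isotropic point set)")
    axis = vt[0]
    half = k // 2
    direction = coords[k - half :].mean(axis=0) - coords[:half].mean(axis=0)
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def center_of_mass(
    coords: np.ndarray,
    selection: AtomSelection | None = None,
    structure: Structure | None = None,
    mass_weighted: bool = False,
) -> np.ndarray:
    """Mean position of the selected atoms, optionally mass-weighted.

    ``coords`` is the full frame (N, 3); ``selection`` picks the subset
    (all atoms when omitted).  Mass weighting needs ``structure`` to supply
    elements; an element missing from the mass table is an error, never a
    silent default.
    """
    coords = np.asarray(coords, dtype=float)
    if selection is not None:
        if len(selection) == 0:
            raise ValueError("empty selection has no center of mass")
        sub = coords[selection.indices]
    else:
        sub = coords
    if sub.shape[0] == 0:
        raise ValueError("no atoms to average")
    if not mass_weighted:
        return sub.mean(axis=0)
    if structure is None:
        raise ValueError("mass_weighted=True requires the structure for elements")
    atoms = (
        [structure.atoms[i] for i in selection.indices]
        if selection is not None
        else structure.atoms
    )
    masses = []
    for a in atoms:
        key = a.element.upper()
        if key not in ELEMENT_MASSES:
            raise KeyError(f"unknown element {a.element!r} for atom {a.name} {a.resid}")
        masses.append(ELEMENT_MASSES[key])
    m = np.asarray(masses)
    return (m[:, None] * sub).sum(axis=0) / m.sum()


def _pair_atoms(
    a: Structure, b: Structure, expression: str, name: str = "CA"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair atoms across two structures by (chain, resid, name) within a selection."""
    sel_a = select(a, expression)
    sel_b = select(b, expression)
    key = lambda at: (at.chain, at.resid, at.icode, at.name)
    map_a = {key(a.atoms[i]): i for i in sel_a.indices}
    map_b = {key(b.atoms[i]): i for i in sel_b.indices}
    common = [k for k in map_a if k in map_b]
    dropped = (set(map_a) | set(map_b)) - set(common)
    if dropped:
        logger.info("dropped %d unpaired atoms for selection %r", len(dropped), expression)
    if len(common) < 3:
        unmatched = sorted(dropped)[:10]
        raise PairingError(
            f"only {len(common)} atoms pair for {expression!r}; "
            f"unmatched examples: {unmatched}"
        )
    common.sort(key=lambda k: map_a[k])
    ia = np.array([map_a[k] for k in common])
    ib = np.array([map_b[k] for k in common])
    return a.positions[ia], b.positions[ib], len(common)


def domain_rotation(
    struct_a: Structure,
    struct_b: Structure,
    core: str,
    domain: str,
    angle_tol_deg: float = 1e-4,
) -> RotationResult:
    """Rotation angle of a domain between two structures.

    Protocol: superpose ``struct_b`` on ``struct_a`` using the core atoms,
    then run Kabsch on the domain atoms alone; the angle comes from the trace
    of that domain rotation matrix.  Atoms are paired by (chain, resid, name);
    unpaired residues are dropped with a logged count.  Below ``angle_tol_deg``
    the rotation axis is reported as undefined (``None``).
    """
    core_a, core_b, n_core = _pair_atoms(struct_a, struct_b, core)
    dom_a, dom_b, n_dom = _pair_atoms(struct_a, struct_b, domain)

    core_sup = kabsch(core_b, core_a)
    dom_b_aligned = core_sup.apply(dom_b)

    before = float(np.sqrt(((dom_b_aligned - dom_a) ** 2).sum(axis=1).mean()))
    dom_sup = kabsch(dom_b_aligned, dom_a)
    after = dom_sup.rmsd

    R = dom_sup.rotation
    cos_angle = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle_deg = math.degrees(math.acos(cos_angle))
    if angle_deg < angle_tol_deg:
        axis = None
    else:
        rotvec = Rotation.from_matrix(R).as_rotvec()
        axis = rotvec / np.linalg.norm(rotvec)
    return RotationResult(
        angle_deg=angle_deg,
        axis=axis,
        core_rmsd=core_sup.rmsd,
        domain_rmsd_before=before,
        domain_rmsd_after=after,
        n_core_pairs=n_core,
        n_domain_pairs=n_dom,
    )


def atom_distance(
    structure: Structure,
    spec_a: tuple[str, int, str],
    spec_b: tuple[str, int, str],
) -> float:
    """Euclidean distance in Angstrom between two atoms given as (chain, resid, name)."""
    a = structure.find_atom(*spec_a)
    b = structure.find_atom(*spec_b)
    return float(np.linalg.norm(np.subtract(a.position, b.position)))
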