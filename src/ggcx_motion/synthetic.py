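"""Synthetic trajectories and structure pairs with known ground truth.

The generator emulates the structural situation the analysis assumes: a
rigid core, a helix that reorients by a time-varying angle θ(t), and a cap
whose center-of-mass displacement follows the helix signal after a temporal
delay, with tunable correlation and coordinate noise.  Every analysis stage
can therefore be validated against implanted truth without any external
trajectory data.

Construction of the coupled signals
-----------------------------------
A standardized Ornstein–Uhlenbeck (OU) latent process ``s(t)`` drives the
helix.  Rather than rotating by an angle proportional to ``s`` directly —
which would make the *measured* cos θ an even function of ``s`` and destroy
its linear correlation with the cap signal — the latent value is mapped
through the normal CDF to an opening coordinate ``u = Φ(s) ∈ (0, 1)`` and
the helix angle is chosen so that

    cos θ(t) = 1 − (1 − cos A) · u(t)

is *linear* in ``u`` (A is the maximum opening angle).  The cap is
translated along a fixed direction by a displacement that is likewise
linear in the mixed signal

    c(t) = −sign(ρ) · |ρ| · z(t − lag) + sqrt(1 − ρ²) · ε(t)

where ``z`` is the standardized opening coordinate and ``ε`` an independent
standardized process, so the population Pearson correlation between the
measured cos θ and dr series is exactly ρ at the implanted lag.  The
displacement is kept non-negative and frame 0 is the undisturbed template,
so dr(t) measured against frame 0 equals the implanted displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from .model_io import Atom, Structure, TimeSeries, Trajectory

__all__ = [
    "SyntheticTruth",
    "gen_template",
    "gen_coupled_trajectory",
    "gen_rotated_pair",
    "CORE_EXPR",
    "HELIX_EXPR",
    "CAP_EXPR",
]

# selection expressions valid for any gen_template output
CORE_EXPR = "chain A and resid 1-199 and name CA"
HELIX_EXPR = "chain A and resid 500-599 and name CA"
CAP_EXPR = "chain A and resid 200-260 and name CA"

_HELIX_RISE = 1.5  # Angstrom per residue
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # Angstrom, CA radius of an ideal alpha-helix


@dataclass
class SyntheticTruth:
    """Ground-truth parameters implanted by the trajectory generator."""

    lag_ns: float = 45.0
    coupling_rho: float = -0.7
    theta_amplitude_deg: float = 40.0
    dr_amplitude: float = 12.0
    noise_sigma: float = 0.3
    core_jitter_sigma: float = 0.3
    n_frames: int = 1600
    frame_dt_ns: float = 0.1
    seed: int = 0
    tau_ns: float = 0.5  # OU relaxation time of the latent signal
    domain_rotation_deg: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [-1, 1]")
        if min(self.noise_sigma, self.core_jitter_sigma) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.frame_dt_ns <= 0 or self.tau_ns <= 0:
            raise ValueError("frame_dt_ns and tau_ns must be positive")
        if self.lag_ns >= self.n_frames * self.frame_dt_ns / 2:
            raise ValueError("lag_ns must be below half the trajectory span")


def large_motion_truth(seed: int = 0) -> SyntheticTruth:
    """Preset emulating the large-amplitude regime: strong helix swings and
    cap excursions over a quiet core, so mobile residues show RMSF well above
    5 A while the jittering core stays near 1 A."""
    return SyntheticTruth(
        theta_amplitude_deg=60.0,
        dr_amplitude=20.0,
        core_jitter_sigma=0.5,
        seed=seed,
    )


def _make_atom(serial: int, resid: int, pos: np.ndarray) -> Atom:
    return Atom(
        serial=serial,
        name="CA",
        resname="ALA",
        resid=resid,
        chain="A",
        element="C",
        position=tuple(float(v) for v in pos),
    )


def _ideal_helix(n: int, base: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """CA coordinates of an ideal alpha-helix starting at ``base`` along ``axis``."""
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    i = np.arange(n)
    phase = np.radians(_HELIX_TWIST * i)
    return (
        base[None, :]
        + np.outer(i * _HELIX_RISE, axis)
        + _HELIX_RADIUS * (np.outer(np.cos(phase), e1) + np.outer(np.sin(phase), e2))
    )


def gen_template(
    n_core: int = 60, n_helix: int = 20, n_cap: int = 27, seed: int = 0
) -> Structure:
    """One-chain CA template: globular core, ideal helix, compact cap cluster.

    Residue numbering mirrors the GGCX layout: core residues start at 1,
    the cap ends at residue 246 (so a 27-residue cap spans 220–246, the
    D220–S246 range), and the helix occupies the 500s.  All three regions
    answer the module-level selection expressions ``CORE_EXPR``,
    ``HELIX_EXPR`` and ``CAP_EXPR``.
    """
    if n_helix < 6:
        raise ValueError("n_helix must be at least 6")
    if not 5 <= n_cap <= 47:
        raise ValueError("n_cap must be in [5, 47] to stay inside residues 200-246")
    if n_helix > 100:
        raise ValueError("n_helix must be at most 100 to stay inside residues 500-599")
    if n_core < 4 or n_core > 199:
        raise ValueError("n_core must be in [4, 199] to keep numbering disjoint")
    rng = np.random.default_rng(seed)

    # globular core: Gaussian cloud rescaled to ~15 A radius, centered at origin
    core = rng.normal(size=(n_core, 3))
    core *= 15.0 / np.abs(core).max()
    core -= core.mean(axis=0)

    # helix attached at the core surface, initially along +z
    helix_base = np.array([16.0, 0.0, 0.0])
    helix = _ideal_helix(n_helix, helix_base, np.array([0.0, 0.0, 1.0]))

    # cap: compact cluster sitting near the helix but off the core
    cap_center = np.array([14.0, 10.0, 6.0])
    cap = cap_center + 2.5 * rng.normal(size=(n_cap, 3))

    atoms: list[Atom] = []
    serial = 1
    for k in range(n_core):
        atoms.append(_make_atom(serial, 1 + k, core[k]))
        serial += 1
    cap_start = 247 - n_cap
    for k in range(n_cap):
        atoms.append(_make_atom(serial, cap_start + k, cap[k]))
        serial += 1
    for k in range(n_helix):
        atoms.append(_make_atom(serial, 500 + k, helix[k]))
        serial += 1
    return Structure(atoms, label=f"synthetic-template(seed={seed})")


def _standardized_ou(rng: np.random.Generator, n: int, dt: float, tau: float) -> np.ndarray:
    """Stationary OU path with zero mean and unit variance."""
    decay = math.exp(-dt / tau)
    innov = math.sqrt(1.0 - decay * decay)
    s = np.empty(n)
    s[0] = rng.standard_normal()
    noise = rng.standard_normal(n - 1)
    for i in range(1, n):
        s[i] = decay * s[i - 1] + innov * noise[i - 1]
    return s


def _template_regions(template: Structure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays for core, cap and helix atoms of a gen_template structure."""
    resids = np.array([a.resid for a in template.atoms])
    core = np.where(resids < 200)[0]
    cap = np.where((resids >= 200) & (resids < 300))[0]
    helix = np.where(resids >= 500)[0]
    return core, cap, helix


def gen_coupled_trajectory(
    template: Structure, truth: SyntheticTruth
) -> tuple[Trajectory, TimeSeries, TimeSeries]:
    """Trajectory with an implanted helix/cap coupling, plus the true signals.

    Returns ``(trajectory, theta_true, d_true)`` where ``theta_true`` is the
    implanted helix opening angle in degrees and ``d_true`` the implanted cap
    displacement in Angstrom, both per frame.  Frame 0 is the undisturbed
    template, the natural reference for cos θ and dr.  Fully deterministic
    given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_frames
    dt = truth.frame_dt_ns
    lag_exact = truth.lag_ns / dt
    lag = int(round(lag_exact))
    if abs(lag_exact - lag) > 1e-9:
        import warnings

        warnings.warn(
            f"lag {truth.lag_ns} ns is not a whole number of frames; "
            f"rounded to {lag * dt} ns",
            stacklevel=2,
        )
    rho = truth.coupling_rho

    # latent OU paths; s is generated back to index -lag to drive the cap
    s = _standardized_ou(rng, n + lag, dt, truth.tau_ns)
    w = _standardized_ou(rng, n, dt, truth.tau_ns)

    # opening coordinate u in (0,1); frame 0 pinned to the template (u=0)
    u = norm.cdf(s)  # index j corresponds to frame j - lag
    u[lag] = 0.0
    z = math.sqrt(12.0) * (u - 0.5)  # standardized opening signal
    eps = math.sqrt(12.0) * (norm.cdf(w) - 0.5)

    # helix angle linear in u through cos: cos(theta) = 1 - kappa * u
    kappa = 1.0 - math.cos(math.radians(truth.theta_amplitude_deg))
    u_frames = u[lag:]
    theta = np.degrees(np.arccos(np.clip(1.0 - kappa * u_frames, -1.0, 1.0)))

    # cap signal: mixes the lagged opening signal with independent noise
    abs_rho = abs(rho)
    c = -np.sign(rho) * abs_rho * z[:n] + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    m = math.sqrt(3.0) * (abs_rho + math.sqrt(max(0.0, 1.0 - rho * rho)))
    g = truth.dr_amplitude * (c + m) / (2.0 * m) if m > 0 else np.zeros(n)
    g = np.clip(g, 0.0, truth.dr_amplitude)
    g[0] = 0.0  # frame 0 is the undisturbed template

    core_idx, cap_idx, helix_idx = _template_regions(template)
    base = template.positions
    helix_coords = base[helix_idx]
    attach = helix_coords[0].copy()
    # swing exactly perpendicular to the measured principal axis, so the
    # implanted angle equals the angle between frame axes to machine precision
    from .geometry import helix_axis as _helix_axis

    axis0 = _helix_axis(helix_coords)
    swing_axis = np.array([0.0, 1.0, 0.0]) - axis0[1] * axis0
    swing_axis /= np.linalg.norm(swing_axis)
    cap_dir = np.array([0.0, 1.0, 0.0])

    frames = np.empty((n, len(template), 3))
    for i in range(n):
        coords = base.copy()
        if theta[i] != 0.0:
            rot = Rotation.from_rotvec(np.radians(theta[i]) * swing_axis)
            coords[helix_idx] = rot.apply(helix_coords - attach) + attach
        coords[cap_idx] = base[cap_idx] + g[i] * cap_dir
        if i > 0:
            if truth.core_jitter_sigma > 0:
                coords[core_idx] += rng.normal(
                    scale=truth.core_jitter_sigma, size=(len(core_idx), 3)
                )
            if truth.noise_sigma > 0:
                mobile = np.concatenate([helix_idx, cap_idx])
                coords[mobile] += rng.normal(
                    scale=truth.noise_sigma, size=(len(mobile), 3)
                )
        frames[i] = coords

    times = np.arange(n) * dt
    traj = Trajectory(template, frames, times)
    theta_series = TimeSeries(times.copy(), theta, label="theta_true", units="deg")
    d_series = TimeSeries(times.copy(), g, label="d_true", units="Angstrom")
    return traj, theta_series, d_series


def gen_rotated_pair(
    template: Structure,
    domain: str,
    angle_deg: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, Structure]:
    """A structure pair whose second member has one domain rotated by a known angle.

    The rotation axis passes through the domain centroid (direction fixed by
    the seed); optional Gaussian noise perturbs every atom of both copies.
    Test bed for domain-rotation measurements between static models.
    """
    from .model_io import select

    rng = np.random.default_rng(seed)
    sel = select(template, domain)
    if len(sel) < 3:
        raise ValueError(f"domain {domain!r} selects fewer than 3 atoms")
    coords_a = template.positions
    coords_b = coords_a.copy()

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    centroid = coords_a[sel.indices].mean(axis=0)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    coords_b[sel.indices] = rot.apply(coords_a[sel.indices] - centroid) + centroid

    if noise_sigma > 0:
        coords_a = coords_a + rng.normal(scale=noise_sigma, size=coords_a.shape)
        coords_b = coords_b + rng.normal(scale=noise_sigma, size=coords_b.shape)

    a = template.with_positions(coords_a, label=f"{template.label}|pair-a")
    b = template.with_positions(coords_b, label=f"{template.label}|rotated{angle_deg}deg")
    return a, b
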