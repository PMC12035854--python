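"""Brownian-dynamics force-ramp pulling of the SOP model.

The overdamped Langevin update at 298 K in water-like friction,

    r(t+dt) = r(t) + F dt / gamma + sqrt(2 k_B T dt / gamma) N(0,1),

is integrated with a numba kernel.  The load is applied through a virtual
cantilever spring moving at constant speed: the spring force is
k_sp * (v t - x_att), where x_att is the displacement of the pulled-bead
centroid along the pulling direction, and is shared equally by the pulled
beads.  Constrained beads never move (infinite-mass contract).  Native
contacts are monitored along the way, which lets unfolding force peaks be
attributed to structural transition types by residue region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numba import njit
from scipy.signal import find_peaks

from .constants import (
    ANG_PER_NM,
    KJ_MOL_ANG_TO_PN,
    speed_um_s_to_ang_ps,
    spring_pn_nm_to_internal,
    stokes_friction,
    thermal_energy,
)
from .sop import SOPParams, SOPTopology
from .structure import CAStructure

__all__ = [
    "PullProtocol",
    "SimConfig",
    "RegionDef",
    "Trajectory",
    "TransitionEvent",
    "TransitionReport",
    "run_pull",
    "classify_transitions",
]


@dataclass(frozen=True)
class PullProtocol:
    """Constraint/pull geometry and the dynamic force ramp.

    ``direction`` may be an explicit 3-vector, ``"longitudinal"`` (along
    the end-to-end vector, the end-pull geometry) or ``"transverse"``
    (perpendicular to it, the geometry where both ends are held and an
    interior interface is pulled sideways).  The loading rate is
    k_sp * v: the defaults 110 pN/nm and 1 um/s give 110 nN/s.
    """

    constrained: frozenset[int]
    pulled: frozenset[int]
    direction: np.ndarray | Literal["transverse", "longitudinal"] = "longitudinal"
    spring_k: float = 110.0  # pN/nm
    speed: float = 1.0  # um/s

    def __post_init__(self) -> None:
        object.__setattr__(self, "constrained", frozenset(self.constrained))
        object.__setattr__(self, "pulled", frozenset(self.pulled))
        if self.constrained & self.pulled:
            raise ValueError("constrained and pulled residue sets overlap")
        if not self.pulled:
            raise ValueError("pulled set is empty")
        if self.spring_k <= 0 or self.speed <= 0:
            raise ValueError("spring_k and speed must be positive")

    @property
    def loading_rate(self) -> float:
        """nN/s = (pN/nm) * (um/s)."""
        return self.spring_k * self.speed

    def resolve_direction(self, coords: np.ndarray) -> np.ndarray:
        if isinstance(self.direction, str):
            e2e = coords[-1] - coords[0]
            if np.linalg.norm(e2e) < 1e-9:
                e2e = np.array([1.0, 0.0, 0.0])
            e2e = e2e / np.linalg.norm(e2e)
            if self.direction == "longitudinal":
                return e2e
            # transverse: any unit vector perpendicular to the end-to-end axis
            trial = np.array([0.0, 0.0, 1.0])
            if abs(trial @ e2e) > 0.9:
                trial = np.array([0.0, 1.0, 0.0])
            perp = trial - (trial @ e2e) * e2e
            return perp / np.linalg.norm(perp)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            raise ValueError("direction vector has zero norm")
        return d / norm


@dataclass(frozen=True)
class SimConfig:
    """Integrator settings.

    The default timestep (0.02 ps) keeps the stiffest interaction (the
    FENE bond, ~84 kJ mol^-1 A^-2) relaxing over >= 20 steps for the
    default friction; :func:`run_pull` enforces that criterion as a hard
    check.
    """

    timestep: float = 0.02  # ps
    temperature: float = 298.0  # K
    viscosity: float = 1e-3  # Pa s
    bead_radius: float = 3.8  # A
    max_extension: float = 20.0  # nm
    max_steps: int | None = None
    output_stride: int = 200
    seed: int = 0
    contact_break_factor: float = 1.5  # contact intact while r < factor * r0

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.output_stride < 1:
            raise ValueError("timestep and output_stride must be positive")

    @property
    def friction(self) -> float:
        """gamma in kJ mol^-1 ps A^-2."""
        return stokes_friction(self.viscosity, self.bead_radius)

    @property
    def kt(self) -> float:
        return thermal_energy(self.temperature)


@dataclass(frozen=True)
class RegionDef:
    """Residue region whose contact rupture defines one transition type,
    e.g. the gamma380-392 beta-strand pull-out (type 1)."""

    label: int
    chain: str
    residue_ranges: tuple[tuple[int, int], ...]

    def indices(self, structure: CAStructure) -> np.ndarray:
        idx = [structure.indices_for(self.chain, rng) for rng in self.residue_ranges]
        out = np.unique(np.concatenate(idx)) if idx else np.empty(0, dtype=int)
        if out.size == 0:
            raise ValueError(
                f"region {self.label} ({self.chain} {self.residue_ranges}) "
                "matches no residues"
            )
        return out


_STATUS_OK = 0
_STATUS_FENE = 1
_STATUS_NAN = 2


@njit(cache=True)
def _integrate(
    coords0,
    bonds,
    bond_r0,
    angles,
    natives,
    native_r0,
    native_eps,
    rep_pairs,
    mobile,
    pulled,
    direction,
    k_fene,
    big_r,
    eps_ang,
    sigma_ang,
    eps_rep,
    sigma_rep,
    k_sp,
    speed,
    dt,
    gamma,
    kt,
    n_steps,
    stride,
    seed,
    break_factor,
    max_ext,
):  # pragma: no cover - exercised through run_pull
    np.random.seed(seed)
    n = coords0.shape[0]
    coords = coords0.copy()
    n_pulled = pulled.shape[0]
    nc = natives.shape[0]
    n_frames = n_steps // stride + 1
    t_out = np.zeros(n_frames)
    f_out = np.zeros(n_frames)
    x_out = np.zeros(n_frames)
    intact_out = np.zeros((n_frames, nc), dtype=np.uint8)
    coords_out = np.zeros((n_frames, n, 3))
    noise = np.sqrt(2.0 * kt * dt / gamma)
    inv_gamma_dt = dt / gamma
    frame = 0
    status = _STATUS_OK
    bad_step = -1
    forces = np.zeros((n, 3))
    for step in range(n_steps):
        t = step * dt
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        # FENE bonds
        for b in range(bonds.shape[0]):
            i, j = bonds[b, 0], bonds[b, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            d = r - bond_r0[b]
            if abs(d) >= big_r:
                status = _STATUS_FENE
                bad_step = step
                break
            fr = -k_fene * d / (1.0 - (d / big_r) ** 2) / r
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
        if status != _STATUS_OK:
            break
        # 1-3 soft repulsion
        for b in range(angles.shape[0]):
            i, j = angles[b, 0], angles[b, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            s6 = (sigma_ang * sigma_ang / r2) ** 3
            fr = 6.0 * eps_ang * s6 / r2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
        # native LJ
        for b in range(nc):
            i, j = natives[b, 0], natives[b, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            s6 = (native_r0[b] * native_r0[b] / r2) ** 3
            fr = 12.0 * native_eps[b] * (s6 * s6 - s6) / r2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
        # non-native repulsion
        for b in range(rep_pairs.shape[0]):
            i, j = rep_pairs[b, 0], rep_pairs[b, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            s6 = (sigma_rep * sigma_rep / r2) ** 3
            fr = 6.0 * eps_rep * s6 / r2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
        # cantilever spring on the pulled centroid
        x_att = 0.0
        for p in range(n_pulled):
            i = pulled[p]
            x_att += (
                (coords[i, 0] - coords0[i, 0]) * direction[0]
                + (coords[i, 1] - coords0[i, 1]) * direction[1]
                + (coords[i, 2] - coords0[i, 2]) * direction[2]
            )
        x_att /= n_pulled
        f_spring = k_sp * (speed * t - x_att)
        per_bead = f_spring / n_pulled
        for p in range(n_pulled):
            i = pulled[p]
            forces[i, 0] += per_bead * direction[0]
            forces[i, 1] += per_bead * direction[1]
            forces[i, 2] += per_bead * direction[2]
        # record before the update so frame 0 is the reference state
        if step % stride == 0:
            t_out[frame] = t
            f_out[frame] = f_spring
            x_out[frame] = x_att
            for b in range(nc):
                i, j = natives[b, 0], natives[b, 1]
                dx = coords[i, 0] - coords[j, 0]
                dy = coords[i, 1] - coords[j, 1]
                dz = coords[i, 2] - coords[j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                intact_out[frame, b] = 1 if r < break_factor * native_r0[b] else 0
            for i in range(n):
                coords_out[frame, i, 0] = coords[i, 0]
                coords_out[frame, i, 1] = coords[i, 1]
                coords_out[frame, i, 2] = coords[i, 2]
            ok = True
            for i in range(n):
                if not (
                    np.isfinite(coords[i, 0])
                    and np.isfinite(coords[i, 1])
                    and np.isfinite(coords[i, 2])
                ):
                    ok = False
            if not ok:
                status = _STATUS_NAN
                bad_step = step
                break
            frame += 1
            if x_att >= max_ext:
                break
        # overdamped update, constrained beads immobile
        if noise > 0.0:
            for i in range(n):
                if mobile[i]:
                    coords[i, 0] += forces[i, 0] * inv_gamma_dt + noise * np.random.standard_normal()
                    coords[i, 1] += forces[i, 1] * inv_gamma_dt + noise * np.random.standard_normal()
                    coords[i, 2] += forces[i, 2] * inv_gamma_dt + noise * np.random.standard_normal()
        else:
            for i in range(n):
                if mobile[i]:
                    coords[i, 0] += forces[i, 0] * inv_gamma_dt
                    coords[i, 1] += forces[i, 1] * inv_gamma_dt
                    coords[i, 2] += forces[i, 2] * inv_gamma_dt
    return status, bad_step, frame, t_out, f_out, x_out, intact_out, coords_out


@dataclass
class Trajectory:
    """Per-frame telemetry of a pulling run."""

    times_ps: np.ndarray
    force_pN: np.ndarray  # spring force
    extension_nm: np.ndarray  # pulled-centroid displacement along the pull
    contact_intact: np.ndarray  # (frames, n_native) uint8
    coords: np.ndarray  # (frames, n, 3) A
    structure: CAStructure
    topology: SOPTopology
    protocol: PullProtocol
    config: SimConfig

    @property
    def n_frames(self) -> int:
        return len(self.times_ps)

    def fx_curve(self):
        from .synthetic import FXCurve

        return FXCurve(self.extension_nm.copy(), self.force_pN.copy())


def run_pull(
    structure: CAStructure,
    topology: SOPTopology,
    protocol: PullProtocol,
    config: SimConfig,
    params: SOPParams | None = None,
) -> Trajectory:
    """Integrate the force ramp and return the recorded trajectory.

    Deterministic for a fixed config seed.  Aborts with diagnostics on a
    FENE domain violation or non-finite coordinates (symptoms of an
    unstable timestep).
    """
    params = params or SOPParams()
    n = structure.n_residues
    if topology.n_residues != n:
        raise ValueError("topology does not match structure")
    for i in protocol.constrained | protocol.pulled:
        if not (0 <= i < n):
            raise ValueError(f"protocol residue {i} outside structure (n={n})")
    gamma = config.friction
    k_fene = params.k_fene_internal
    tau = gamma / k_fene
    if config.timestep > tau / 20.0:
        raise ValueError(
            f"timestep {config.timestep} ps too large: the stiffest "
            f"interaction relaxes in {tau:.3f} ps; require dt <= tau/20"
        )
    direction = protocol.resolve_direction(structure.coords)
    speed = speed_um_s_to_ang_ps(protocol.speed)
    k_sp = spring_pn_nm_to_internal(protocol.spring_k)
    max_ext_ang = config.max_extension * ANG_PER_NM
    if config.max_steps is not None:
        n_steps = config.max_steps
    else:
        # time for the ramp to sweep max_extension, with 50% headroom
        n_steps = int(1.5 * max_ext_ang / (speed * config.timestep)) + 1
    mobile = np.ones(n, dtype=np.bool_)
    mobile[list(protocol.constrained)] = False
    pulled = np.array(sorted(protocol.pulled), dtype=np.int64)
    # explicit repulsive pair list
    iu, ju = np.triu_indices(n, k=1)
    mask = ~topology.exclusion[iu, ju]
    rep_pairs = np.column_stack([iu[mask], ju[mask]]).astype(np.int64)

    status, bad_step, n_frames, t, f, x, intact, coords = _integrate(
        structure.coords.astype(np.float64),
        topology.bonds.astype(np.int64),
        topology.bond_r0.astype(np.float64),
        topology.angles.astype(np.int64),
        topology.native.astype(np.int64),
        topology.native_r0.astype(np.float64),
        topology.native_eps.astype(np.float64),
        rep_pairs,
        mobile,
        pulled,
        direction,
        k_fene,
        params.r0_tol,
        params.eps_ang,
        params.sigma_ang,
        params.eps_rep,
        params.sigma_rep,
        k_sp,
        speed,
        config.timestep,
        gamma,
        config.kt,
        n_steps,
        config.output_stride,
        config.seed,
        config.contact_break_factor,
        max_ext_ang,
    )
    if status == _STATUS_FENE:
        raise RuntimeError(
            f"FENE domain violation at step {bad_step} "
            f"(t={bad_step * config.timestep:.1f} ps); reduce the timestep "
            "or the pulling speed"
        )
    if status == _STATUS_NAN:
        raise RuntimeError(f"non-finite coordinates at step {bad_step}")
    return Trajectory(
        times_ps=t[:n_frames],
        force_pN=f[:n_frames] * KJ_MOL_ANG_TO_PN,
        extension_nm=x[:n_frames] / ANG_PER_NM,
        contact_intact=intact[:n_frames],
        coords=coords[:n_frames],
        structure=structure,
        topology=topology,
        protocol=protocol,
        config=config,
    )


# ---------------------------------------------------------------------------
# transition classification


@dataclass(frozen=True)
class TransitionEvent:
    """One classified unfolding event in a trajectory."""

    time_ps: float
    extension_nm: float
    label: int  # transition type; 4 = mixed
    strand: str  # chain id, or "mixed"
    constituents: tuple[int, ...]  # constituent single-transition labels


@dataclass
class TransitionReport:
    events: list[TransitionEvent]
    single_fraction: float
    mixed_fraction: float
    alternation_score: float  # NaN when < 2 single events


def classify_transitions(
    trajectory: Trajectory,
    regions: Sequence[RegionDef],
    threshold: float = 0.5,
    merge_window_nm: float = 2.0,
) -> TransitionReport:
    """Attribute contact-rupture events to transition types and strands.

    A region unfolds at the first frame where the intact fraction of its
    native contacts drops below ``threshold``.  Unfold events are grouped
    into peak-to-peak windows of the recorded force trace (each event is
    assigned to its nearest force peak; absent usable peaks, events
    within ``merge_window_nm`` of extension are grouped).  A window with
    events in more than one strand becomes one mixed (type-4) event.
    """
    if trajectory.contact_intact.size == 0:
        raise ValueError("trajectory carries no contact telemetry")
    structure = trajectory.structure
    natives = trajectory.topology.native
    raw: list[tuple[float, float, int, str]] = []  # (time, ext, label, strand)
    for region in regions:
        idx = set(region.indices(structure).tolist())
        touch = np.array(
            [a in idx or b in idx for a, b in natives], dtype=bool
        )
        if not touch.any():
            continue
        frac = trajectory.contact_intact[:, touch].mean(axis=1)
        below = np.flatnonzero(frac < threshold)
        if below.size == 0 or frac[0] < threshold:
            continue
        fr = below[0]
        raw.append(
            (
                float(trajectory.times_ps[fr]),
                float(trajectory.extension_nm[fr]),
                region.label,
                region.chain,
            )
        )
    raw.sort(key=lambda e: e[0])

    # group by force-trace peak-to-peak window
    force = trajectory.force_pN
    noise = np.median(np.abs(np.diff(force))) / 0.6745 if len(force) > 2 else 0.0
    peaks, _ = find_peaks(force, prominence=max(3 * noise, 1e-9))
    groups: dict[int, list[tuple[float, float, int, str]]] = {}
    if peaks.size:
        peak_ext = trajectory.extension_nm[peaks]
        for ev in raw:
            k = int(np.argmin(np.abs(peak_ext - ev[1])))
            groups.setdefault(k, []).append(ev)
    else:
        gid = -1
        last_ext = None
        for ev in raw:
            if last_ext is None or ev[1] - last_ext > merge_window_nm:
                gid += 1
            groups.setdefault(gid, []).append(ev)
            last_ext = ev[1]

    events: list[TransitionEvent] = []
    for _, grp in sorted(groups.items(), key=lambda kv: kv[1][0][0]):
        strands = {e[3] for e in grp}
        labels = tuple(sorted(e[2] for e in grp))
        if len(strands) > 1:
            events.append(
                TransitionEvent(grp[0][0], grp[0][1], 4, "mixed", labels)
            )
        else:
            for e in grp:
                events.append(TransitionEvent(e[0], e[1], e[2], e[3], (e[2],)))
    events.sort(key=lambda e: e.time_ps)

    singles = [e for e in events if e.strand != "mixed"]
    n_ev = len(events)
    single_fraction = len(singles) / n_ev if n_ev else float("nan")
    mixed_fraction = 1.0 - single_fraction if n_ev else float("nan")
    if len(singles) >= 2:
        flips = sum(
            1 for a, b in zip(singles[:-1], singles[1:]) if a.strand != b.strand
        )
        alternation = flips / (len(singles) - 1)
    else:
        alternation = float("nan")
    return TransitionReport(events, single_fraction, mixed_fraction, alternation)
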