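"""Self-organized polymer (SOP) model: topology construction and the
four-term potential.

One bead per residue at the C-alpha position.  The potential is

    U = U_FENE + U_ANG + U_NB_att + U_NB_rep

with finite-extensible-nonlinear-elastic bonds between consecutive (and
cross-linked) beads, a soft eps*(sigma/r)^6 repulsion on 1-3 pairs, a
Lennard-Jones 12-6 well of depth eps_n on native contacts (reference
distance < 8 A, sequence separation >= 3 or inter-chain), and the same
soft repulsion on all remaining pairs.  Internal units: angstrom, kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import N_PER_M_TO_KJ_MOL_ANG2
from .structure import CAStructure, CA_CA_BOND


@dataclass(frozen=True)
class SOPParams:
    """Force-field constants.

    ``k_fene`` is given in N/m as conventionally quoted (14 N/m ~ 84.3
    kJ mol^-1 A^-2); everything else is in kJ/mol and angstrom.
    ``eps_native`` defaults to 4.2 kJ/mol, the midpoint of the 2.5-5.4
    range spanned by residue-type-dependent contact energies.
    """

    k_fene: float = 14.0  # N/m
    r0_tol: float = 2.0  # A, FENE tolerance R0
    eps_ang: float = 4.2  # kJ/mol
    sigma_ang: float = 3.8  # A
    eps_native: float = 4.2  # kJ/mol
    eps_native_range: tuple[float, float] = (2.5, 5.4)
    eps_rep: float = 4.2  # kJ/mol
    sigma_rep: float = 3.8  # A
    r_cut: float = 8.0  # A, native-contact cutoff

    def __post_init__(self) -> None:
        vals = [
            self.k_fene, self.r0_tol, self.eps_ang, self.sigma_ang,
            self.eps_native, self.eps_rep, self.sigma_rep, self.r_cut,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all SOP parameters must be positive")
        lo, hi = self.eps_native_range
        if not (lo <= self.eps_native <= hi):
            raise ValueError(
                f"eps_native={self.eps_native} outside the allowed range [{lo}, {hi}]"
            )

    @property
    def k_fene_internal(self) -> float:
        """FENE spring constant in kJ mol^-1 A^-2."""
        return self.k_fene * N_PER_M_TO_KJ_MOL_ANG2


@dataclass
class SOPTopology:
    """Interaction lists partitioning all bead pairs.

    ``bonds``/``angles``/``native_contacts`` carry (i, j) index pairs with
    their reference distances; every remaining pair is repulsive, recorded
    implicitly through ``exclusion`` (True where a pair is NOT repulsive:
    self, bonded, 1-3, or native).
    """

    n_residues: int
    bonds: np.ndarray  # (nb, 2) int
    bond_r0: np.ndarray  # (nb,) A
    angles: np.ndarray  # (na, 2) int, the 1-3 pair
    angle_r0: np.ndarray  # (na,) A (reference, kept for bookkeeping)
    native: np.ndarray  # (nc, 2) int
    native_r0: np.ndarray  # (nc,) A
    native_eps: np.ndarray  # (nc,) kJ/mol
    exclusion: np.ndarray  # (n, n) bool

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_native(self) -> int:
        return len(self.native)

    @property
    def n_repulsive(self) -> int:
        n = self.n_residues
        return n * (n - 1) // 2 - self.n_bonds - self.n_angles - self.n_native


def build_topology(
    structure: CAStructure,
    params: SOPParams | None = None,
    crosslinks: Sequence[tuple[int, int]] = (),
) -> SOPTopology:
    """Partition all bead pairs of the reference structure into the four
    interaction classes.

    Consecutive beads of one chain become FENE bonds; beads two apart
    become 1-3 angle pairs; pairs with sequence separation >= 3 (or on
    different chains) closer than ``r_cut`` in the reference become native
    contacts; everything else is repulsive.  ``crosslinks`` (internal
    0-based index pairs, e.g. disulfides or gamma-gamma cross-links) are
    added as extra FENE bonds at their reference distance and removed from
    any other class.
    """
    params = params or SOPParams()
    n = structure.n_residues
    if n < 4:
        raise ValueError("structure must have >= 4 residues")
    coords = structure.coords
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    chains = structure.chain_ids
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)

    bonds: list[tuple[int, int]] = []
    for i in range(n - 1):
        if chains[i] == chains[i + 1]:
            if dist[i, i + 1] > CA_CA_BOND + params.r0_tol:
                raise ValueError(
                    f"chain break: consecutive C-alpha {i}-{i + 1} are "
                    f"{dist[i, i + 1]:.2f} A apart (> {CA_CA_BOND + params.r0_tol:.1f} A); "
                    "FENE is undefined at the reference state"
                )
            bonds.append((i, i + 1))
    for i, j in crosslinks:
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValueError(f"invalid crosslink pair ({i}, {j})")
        if (i, j) not in bonds:
            bonds.append((i, j))
    bond_set = set(bonds)

    angles: list[tuple[int, int]] = []
    for i in range(n - 2):
        if chains[i] == chains[i + 1] == chains[i + 2] and (i, i + 2) not in bond_set:
            angles.append((i, i + 2))
    angle_set = set(angles)

    native: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bond_set or (i, j) in angle_set:
                continue
            same_chain = chains[i] == chains[j]
            if same_chain and j - i < 3:
                continue
            if dist[i, j] < params.r_cut:
                native.append((i, j))

    exclusion = np.eye(n, dtype=bool)
    for cls in (bonds, angles, native):
        for i, j in cls:
            exclusion[i, j] = exclusion[j, i] = True

    def _pairs(lst: list[tuple[int, int]]) -> np.ndarray:
        return np.array(lst, dtype=np.int64).reshape(-1, 2)

    b = _pairs(bonds)
    a = _pairs(angles)
    c = _pairs(native)
    return SOPTopology(
        n_residues=n,
        bonds=b,
        bond_r0=dist[b[:, 0], b[:, 1]] if len(b) else np.empty(0),
        angles=a,
        angle_r0=dist[a[:, 0], a[:, 1]] if len(a) else np.empty(0),
        native=c,
        native_r0=dist[c[:, 0], c[:, 1]] if len(c) else np.empty(0),
        native_eps=np.full(len(c), params.eps_native),
        exclusion=exclusion,
    )


# ---------------------------------------------------------------------------
# pair potentials (vectorized; energies in kJ/mol, forces in kJ mol^-1 A^-1,
# force = -dU/dr, so negative values pull the pair together)


def fene_energy(r, r0, params: SOPParams | None = None):
    """FENE bond energy and radial force.

    U = -(k R0^2 / 2) ln(1 - (r - r0)^2 / R0^2); diverges as |r - r0|
    approaches the tolerance R0.  Outside the domain the bond would have
    ruptured, which the model excludes, so this is a hard error.
    """
    params = params or SOPParams()
    r = np.asarray(r, dtype=float)
    d = r - r0
    big_r = params.r0_tol
    if np.any(np.abs(d) >= big_r):
        raise ValueError(
            f"FENE domain violation: |r - r0| >= R0 = {big_r} A (chain rupture "
            "is outside the model)"
        )
    k = params.k_fene_internal
    u = -0.5 * k * big_r**2 * np.log1p(-((d / big_r) ** 2))
    f = -k * d / (1.0 - (d / big_r) ** 2)
    return u, f


def native_energy(r, r0, eps):
    """Lennard-Jones 12-6 native-contact energy and radial force.

    Minimum of exactly -eps at r = r0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    s6 = (r0 / r) ** 6
    u = eps * (s6**2 - 2.0 * s6)
    f = 12.0 * eps / r * (s6**2 - s6)
    return u, f


def repulsive_energy(r, eps, sigma):
    """Soft eps*(sigma/r)^6 repulsion and its (always >= 0) radial force.

    Used both for 1-3 angle pairs (eps_ang, sigma_ang) and non-native
    pairs (eps_rep, sigma_rep).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    s6 = (sigma / r) ** 6
    return eps * s6, 6.0 * eps * s6 / r


def angle_energy(r, params: SOPParams | None = None):
    """1-3 repulsion eps_ang*(sigma_ang/r)^6."""
    params = params or SOPParams()
    return repulsive_energy(r, params.eps_ang, params.sigma_ang)


def _pair_distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    if len(pairs) == 0:
        return np.empty(0)
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.linalg.norm(d, axis=1)


def total_energy(
    coords: np.ndarray, topology: SOPTopology, params: SOPParams | None = None
) -> dict[str, float]:
    """Per-term and total potential energy (kJ/mol) of a configuration."""
    params = params or SOPParams()
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    out: dict[str, float] = {}
    r = _pair_distances(coords, topology.bonds)
    out["fene"] = float(np.sum(fene_energy(r, topology.bond_r0, params)[0])) if len(r) else 0.0
    r = _pair_distances(coords, topology.angles)
    out["angle"] = float(np.sum(angle_energy(r, params)[0])) if len(r) else 0.0
    r = _pair_distances(coords, topology.native)
    out["native"] = (
        float(np.sum(native_energy(r, topology.native_r0, topology.native_eps)[0]))
        if len(r)
        else 0.0
    )
    # repulsive: all pairs not excluded
    n = topology.n_residues
    iu, ju = np.triu_indices(n, k=1)
    mask = ~topology.exclusion[iu, ju]
    if mask.any():
        rr = np.linalg.norm(coords[iu[mask]] - coords[ju[mask]], axis=1)
        out["repulsive"] = float(
            np.sum(repulsive_energy(rr, params.eps_rep, params.sigma_rep)[0])
        )
    else:
        out["repulsive"] = 0.0
    out["total"] = out["fene"] + out["angle"] + out["native"] + out["repulsive"]
    return out


def forces(
    coords: np.ndarray, topology: SOPTopology, params: SOPParams | None = None
) -> np.ndarray:
    """Analytic forces (kJ mol^-1 A^-1), -grad of :func:`total_energy`."""
    params = params or SOPParams()
    coords = np.asarray(coords, dtype=float)
    out = np.zeros_like(coords)

    def _accumulate(pairs: np.ndarray, fr: np.ndarray) -> None:
        # fr is the radial force (positive = pushes the pair apart)
        d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        unit = d / r[:, None]
        vec = fr[:, None] * unit
        np.add.at(out, pairs[:, 0], vec)
        np.add.at(out, pairs[:, 1], -vec)

    if topology.n_bonds:
        r = _pair_distances(coords, topology.bonds)
        _accumulate(topology.bonds, fene_energy(r, topology.bond_r0, params)[1])
    if topology.n_angles:
        r = _pair_distances(coords, topology.angles)
        _accumulate(topology.angles, angle_energy(r, params)[1])
    if topology.n_native:
        r = _pair_distances(coords, topology.native)
        _accumulate(
            topology.native,
            native_energy(r, topology.native_r0, topology.native_eps)[1],
        )
    n = topology.n_residues
    iu, ju = np.triu_indices(n, k=1)
    mask = ~topology.exclusion[iu, ju]
    if mask.any():
        pairs = np.column_stack([iu[mask], ju[mask]])
        r = _pair_distances(coords, pairs)
        _accumulate(pairs, repulsive_energy(r, params.eps_rep, params.sigma_rep)[1])
    return out
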