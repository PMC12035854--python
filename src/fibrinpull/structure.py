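"""C-alpha structures: reading, writing and toy fixtures.

A :class:`CAStructure` is an ordered list of C-alpha records (chain id,
source residue number, xyz in angstrom).  Real structures are read from
PDB/mmCIF files through :mod:`gemmi`; desk-scale fixtures are generated by
:func:`make_toy_chain`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np

#: Canonical C-alpha / C-alpha virtual bond length, angstrom.
CA_CA_BOND = 3.8


@dataclass
class CAStructure:
    """Ordered C-alpha records of a folded reference state.

    Residues are indexed 0..n-1 internally (in file order); ``res_ids``
    keeps the source numbering so regions can be referenced by labels such
    as gamma380-392.
    """

    chain_ids: np.ndarray  # (n,) unicode chain identifiers
    res_ids: np.ndarray  # (n,) int, source residue numbers
    coords: np.ndarray  # (n, 3) float, angstrom

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.res_ids = np.asarray(self.res_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not (len(self.chain_ids) == len(self.res_ids) == len(self.coords)):
            raise ValueError("chain_ids, res_ids and coords must have equal length")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    def chain_of(self, i: int) -> str:
        return str(self.chain_ids[i])

    def indices_for(self, chain: str, res_range: tuple[int, int]) -> np.ndarray:
        """Internal indices of residues ``res_range=(start, stop)`` (inclusive,
        source numbering) on ``chain``."""
        lo, hi = res_range
        mask = (self.chain_ids == chain) & (self.res_ids >= lo) & (self.res_ids <= hi)
        return np.flatnonzero(mask)


def read_ca_structure(path: str | Path) -> CAStructure:
    """Read all C-alpha atoms from a PDB or mmCIF file (first model)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    chains, resids, xyz = [], [], []
    for chain in st[0]:
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is not None:
                chains.append(chain.name)
                resids.append(res.seqid.num)
                xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not xyz:
        raise ValueError(f"no C-alpha atoms found in {path}")
    return CAStructure(np.array(chains), np.array(resids), np.array(xyz))


def write_ca_structure(structure: CAStructure, path: str | Path) -> None:
    """Write a C-alpha-only PDB file."""
    st = gemmi.Structure()
    st.name = "ca_model"
    model = gemmi.Model("1")
    for cid in dict.fromkeys(structure.chain_ids.tolist()):
        chain = gemmi.Chain(str(cid))
        for i in np.flatnonzero(structure.chain_ids == cid):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(structure.res_ids[i]), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*structure.coords[i])
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


Geometry = Literal["linear", "helix", "two_strand"]


def make_toy_chain(
    n_residues: int,
    geometry: Geometry = "linear",
    seed: int = 0,
    jitter_sd: float = 0.0,
) -> CAStructure:
    """Build a small C-alpha polymer with consecutive spacing ~3.8 A.

    Parameters
    ----------
    n_residues:
        Total bead count (>= 4; below that no 1-3 angle pair exists).
    geometry:
        ``linear`` — a straight chain with no native contacts;
        ``helix`` — ideal alpha-helical trace (2.3 A radius, 1.5 A rise,
        100 deg/residue) rich in i,i+3 / i,i+4 contacts;
        ``two_strand`` — two parallel straight chains (ids A and B) 5 A
        apart, mimicking the inter-strand contacts of a double-stranded
        oligomer.
    seed:
        Seeds the optional Gaussian jitter; with ``jitter_sd=0`` the
        coordinates are fully deterministic.
    """
    if n_residues < 4:
        raise ValueError("n_residues must be >= 4 (angle term undefined below)")
    rng = np.random.default_rng(seed)
    if geometry == "linear":
        coords = np.zeros((n_residues, 3))
        coords[:, 0] = CA_CA_BOND * np.arange(n_residues)
        chains = np.full(n_residues, "A")
        resids = np.arange(1, n_residues + 1)
    elif geometry == "helix":
        radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
        t = np.arange(n_residues)
        coords = np.column_stack(
            [radius * np.cos(twist * t), radius * np.sin(twist * t), rise * t]
        )
        chains = np.full(n_residues, "A")
        resids = np.arange(1, n_residues + 1)
    elif geometry == "two_strand":
        n_a = n_residues // 2
        n_b = n_residues - n_a
        xa = CA_CA_BOND * np.arange(n_a)
        xb = CA_CA_BOND * np.arange(n_b)
        coords = np.zeros((n_residues, 3))
        coords[:n_a, 0] = xa
        coords[n_a:, 0] = xb
        coords[n_a:, 1] = 5.0  # inter-strand separation < 8 A cutoff
        chains = np.array(["A"] * n_a + ["B"] * n_b)
        resids = np.concatenate([np.arange(1, n_a + 1), np.arange(1, n_b + 1)])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
    return CAStructure(chains, resids, coords)
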