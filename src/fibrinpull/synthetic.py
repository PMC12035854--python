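"""Synthetic inputs: (force, distance) event samples from the bivariate
Gamma mixture, sawtooth force-extension curves, and toy structures.

The default five-component table carries the per-transition-type statistics
of the pulling simulations on double-stranded fibrin oligomers: mean peak
forces relative to baseline (36.3, 50.9, 80.2, 63.4, 80.1 pN), mean
peak-to-peak distances (4.2, 13.8, 13.1, 15.2, 17.7 nm), force SDs (13.6,
28.5, 17.8, 16.2, 27.9 pN) and simulation priors (0.11, 0.35, 0.10, 0.09,
0.35) for types 0-4.  Distance SDs are set to a 30% coefficient of
variation and the force-distance correlation to 0.25 per component; see
docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bigamma
from .structure import CAStructure, make_toy_chain  # noqa: F401  (re-export)

__all__ = [
    "ComponentSpec",
    "SawtoothSpec",
    "default_components",
    "sample_mixture",
    "make_sawtooth",
    "make_toy_chain",
    "write_events",
    "read_events",
    "write_curve",
    "read_curve",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component: moments of peak force (pN, relative to
    baseline) and peak-to-peak distance (nm) for a transition type."""

    type_id: int
    mean_force: float  # pN
    sd_force: float  # pN
    mean_dist: float  # nm
    sd_dist: float  # nm
    cov_fx: float = 0.0  # pN nm
    prior: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_force <= 0 or self.sd_dist <= 0:
            raise ValueError(f"type {self.type_id}: SDs must be positive")
        if not (0.0 <= self.prior <= 1.0):
            raise ValueError(f"type {self.type_id}: prior must be in [0, 1]")
        if abs(self.cov_fx) > self.sd_force * self.sd_dist * (1 + 1e-12):
            raise ValueError(
                f"type {self.type_id}: |cov_fx| exceeds sd_force*sd_dist"
            )

    @property
    def correlation(self) -> float:
        return self.cov_fx / (self.sd_force * self.sd_dist)

    def shapes(self) -> bigamma.GammaShapes:
        return bigamma.moments_to_shapes(
            self.mean_force,
            self.mean_dist,
            self.sd_force,
            self.sd_dist,
            self.cov_fx,
            label=f"type {self.type_id}",
        )


# Per-type (mean_dist nm, mean_force pN, sd_force pN, prior) of the
# double-stranded oligomer pulling simulations (study 1, transverse pull).
_DEFAULT_ROWS = [
    (0, 4.2, 36.3, 13.6, 0.11),
    (1, 13.8, 50.9, 28.5, 0.35),
    (2, 13.1, 80.2, 17.8, 0.10),
    (3, 15.2, 63.4, 16.2, 0.09),
    (4, 17.7, 80.1, 27.9, 0.35),
]

#: distance SDs are not reported; use a 30% CV (see docs/methods.md)
DIST_CV = 0.30
#: default per-component force-distance correlation
DEFAULT_RHO = 0.25


def default_components(rho: float = DEFAULT_RHO) -> list[ComponentSpec]:
    """The five-component table for transition types 0-4."""
    comps = []
    for tid, mx, mf, sf, pi in _DEFAULT_ROWS:
        sx = DIST_CV * mx
        comps.append(
            ComponentSpec(
                type_id=tid,
                mean_force=mf,
                sd_force=sf,
                mean_dist=mx,
                sd_dist=sx,
                cov_fx=rho * sf * sx,
                prior=pi,
            )
        )
    return comps


def _check_priors(components: Sequence[ComponentSpec]) -> np.ndarray:
    priors = np.array([c.prior for c in components], dtype=float)
    if abs(priors.sum() - 1.0) > 1e-9:
        raise ValueError(f"priors sum to {priors.sum():.12g}, expected 1")
    return priors


def sample_mixture(
    components: Sequence[ComponentSpec], n: int, seed: int = 0
) -> pd.DataFrame:
    """Sample ``n`` (force, distance, true_type) rows from the mixture.

    Component membership is drawn from the priors; each component draws
    from the shared-component bivariate Gamma, so forces and distances are
    strictly positive and each marginal is Gamma.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    priors = _check_priors(components)
    shapes = [c.shapes() for c in components]  # validates feasibility
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(components), size=n, p=priors)
    force = np.empty(n)
    dist = np.empty(n)
    types = np.empty(n, dtype=int)
    for k, (comp, s) in enumerate(zip(components, shapes)):
        idx = np.flatnonzero(labels == k)
        if idx.size:
            f, x = bigamma.sample(s, idx.size, rng)
            force[idx] = f
            dist[idx] = x
            types[idx] = comp.type_id
    return pd.DataFrame(
        {"force_pN": force, "distance_nm": dist, "true_type": types}
    )


@dataclass(frozen=True)
class SawtoothSpec:
    """Piecewise-linear sawtooth force-extension curve.

    Each peak rises from the baseline at ``rise_stiffness`` to its peak
    force at its peak position, then drops back to the baseline over
    ``drop_width``; the curve ends flat at the baseline out to
    ``total_extension``.
    """

    peak_forces: tuple[float, ...]  # pN, absolute
    peak_positions: tuple[float, ...]  # nm, strictly increasing
    baseline: float = 0.0  # pN
    rise_stiffness: float = 10.0  # pN/nm
    noise_sd: float = 0.0  # pN
    total_extension: float | None = None  # nm
    drop_width: float = 0.2  # nm
    sample_dx: float = 0.02  # nm

    def __post_init__(self) -> None:
        if len(self.peak_forces) != len(self.peak_positions):
            raise ValueError("peak_forces and peak_positions differ in length")
        if len(self.peak_forces) == 0:
            raise ValueError("need at least one peak")
        pos = np.asarray(self.peak_positions, dtype=float)
        if not np.all(np.diff(pos) > 0):
            raise ValueError("peak_positions must be strictly increasing")
        if self.rise_stiffness <= 0:
            raise ValueError("rise_stiffness must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(f <= self.baseline for f in self.peak_forces):
            raise ValueError("peak forces must exceed the baseline")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_forces)


@dataclass
class FXCurve:
    """Paired extension (nm) and force (pN) arrays."""

    extension_nm: np.ndarray
    force_pN: np.ndarray

    def __post_init__(self) -> None:
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.extension_nm.shape != self.force_pN.shape:
            raise ValueError("extension and force arrays must match")

    @property
    def total_extension(self) -> float:
        return float(self.extension_nm[-1] - self.extension_nm[0])


def make_sawtooth(spec: SawtoothSpec, seed: int = 0) -> FXCurve:
    """Render a sawtooth curve from its spec.

    The sample grid always contains the exact rise-start, peak and
    drop-end breakpoints, so with ``noise_sd=0`` peak detection recovers
    the peak list exactly.
    """
    knots_x: list[float] = [0.0]
    knots_f: list[float] = [spec.baseline]
    prev_end = 0.0
    for fpk, xpk in zip(spec.peak_forces, spec.peak_positions):
        rise = (fpk - spec.baseline) / spec.rise_stiffness
        x_start = xpk - rise
        if x_start < prev_end - 1e-12:
            raise ValueError(
                f"peak at {xpk} nm overlaps the previous peak's drop; "
                "increase spacing or stiffness"
            )
        knots_x += [x_start, xpk, xpk + spec.drop_width]
        knots_f += [spec.baseline, fpk, spec.baseline]
        prev_end = xpk + spec.drop_width
    end = spec.total_extension if spec.total_extension is not None else prev_end + 5.0
    if end > prev_end:
        knots_x.append(end)
        knots_f.append(spec.baseline)
    # dense sampling per segment, endpoints included exactly
    xs: list[np.ndarray] = []
    for a, b in zip(knots_x[:-1], knots_x[1:]):
        if b <= a + 1e-12:
            continue
        n_seg = max(int(np.ceil((b - a) / spec.sample_dx)), 1)
        xs.append(np.linspace(a, b, n_seg + 1)[:-1])
    x = np.concatenate(xs + [np.array([knots_x[-1]])])
    f = np.interp(x, knots_x, knots_f)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, spec.noise_sd, f.shape)
    return FXCurve(x, f)


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"force_pN", "distance_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_curve(curve: FXCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"extension_nm": curve.extension_nm, "force_pN": curve.force_pN}
    ).to_csv(path, sep="\t", index=False)


def read_curve(path: str | Path) -> FXCurve:
    df = pd.read_csv(path, sep="\t")
    missing = {"extension_nm", "force_pN"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return FXCurve(df["extension_nm"].to_numpy(), df["force_pN"].to_numpy())
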