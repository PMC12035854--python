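"""Force-extension curve analysis: unfolding-event extraction, selection
rules, summary statistics, histograms and kernel density estimates.

Event selection follows the single-molecule conventions for sawtooth
curves: peak forces are reported relative to the baseline (the force level
the curve drops to after the peak); peaks above 500 pN absolute or 200 pN
over baseline are attributed to surface detachment rather than unfolding;
peak-to-peak distances above 30 nm and curves shorter than 100 nm total
extension are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import norm

from .synthetic import FXCurve

__all__ = [
    "SelectionRules",
    "UnfoldingEvent",
    "EventDetection",
    "detect_events",
    "events_frame",
    "summarize",
    "fd_histogram",
    "kde",
]


@dataclass(frozen=True)
class SelectionRules:
    """Thresholds that decide which detected peaks count as unfolding."""

    max_abs_force: float = 500.0  # pN
    max_rel_force: float = 200.0  # pN over baseline
    max_peak_to_peak: float = 30.0  # nm
    min_total_extension: float = 100.0  # nm
    min_unfolding_peaks: int = 2

    def __post_init__(self) -> None:
        if min(
            self.max_abs_force,
            self.max_rel_force,
            self.max_peak_to_peak,
            self.min_total_extension,
            self.min_unfolding_peaks,
        ) <= 0:
            raise ValueError("all selection thresholds must be positive")


@dataclass
class UnfoldingEvent:
    """One force peak.

    ``peak_to_peak`` is NaN for the first detected peak (no predecessor).
    ``flags`` is a subset of {"desorption", "detachment", "excluded_force",
    "excluded_distance"}; an event is retained iff flags is empty.
    """

    peak_force_abs: float  # pN
    baseline: float  # pN
    extension_at_peak: float  # nm
    peak_to_peak: float  # nm
    stiffness: float  # pN/nm
    flags: frozenset[str] = frozenset()
    label: int | None = None

    @property
    def peak_force_rel(self) -> float:
        return self.peak_force_abs - self.baseline

    @property
    def retained(self) -> bool:
        return not self.flags


@dataclass
class EventDetection:
    events: list[UnfoldingEvent]
    curve_accepted: bool
    rejection_reason: str | None = None

    @property
    def retained(self) -> list[UnfoldingEvent]:
        return [e for e in self.events if e.retained]


def _robust_noise_sd(force: np.ndarray) -> float:
    """Noise SD from the median absolute first difference (detrends the
    sawtooth ramps, which vary slowly between samples)."""
    d = np.diff(force)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0))


def detect_events(curve: FXCurve, rules: SelectionRules | None = None) -> EventDetection:
    """Extract unfolding events from a force-extension curve.

    Peaks are local maxima with prominence above 3x the robust noise SD.
    The baseline of a peak is the minimum force in the valley that follows
    it; the stiffness is the least-squares slope of the rising segment
    from the preceding valley to the peak.  The first peak is flagged
    ``desorption`` when it strictly exceeds the following peak, and the
    last ``detachment`` when it strictly exceeds the preceding one (the
    large initial/final peaks of surface and tip release); selection-rule
    flags are applied independently of each other, so the retained set
    does not depend on rule order.
    """
    rules = rules or SelectionRules()
    x = curve.extension_nm
    f = curve.force_pN
    if len(x) < 10:
        raise ValueError("degenerate curve: need >= 10 samples")
    if np.any(np.diff(x) < 0):
        raise ValueError("curve extension must be non-decreasing")

    noise = _robust_noise_sd(f)
    if noise > 1e-9 and len(f) > 20:
        # denoise over a ~0.5 nm window before peak picking; the noiseless
        # path stays untouched so synthetic round-trips are exact
        dx = float(np.median(np.diff(x)))
        win = int(np.clip(0.5 / max(dx, 1e-6), 5, min(51, len(f) // 4)))
        win += 1 - win % 2  # odd
        from scipy.signal import savgol_filter

        f = savgol_filter(f, win, 2)
    prominence = max(3.0 * noise, 1e-9)
    peaks, _ = find_peaks(f, prominence=prominence)
    if peaks.size == 0:
        return EventDetection([], False, "no force peaks detected")

    # valley minima between successive peaks (and to the curve end)
    baselines = np.empty(peaks.size)
    rise_start = np.empty(peaks.size, dtype=int)
    for k, p in enumerate(peaks):
        nxt = peaks[k + 1] if k + 1 < peaks.size else len(f)
        baselines[k] = f[p:nxt].min()
        prev = peaks[k - 1] if k > 0 else 0
        if p > prev:
            seg = f[prev:p]
            fmin = seg.min()
            # start of the rise: last sample still near the valley level
            # (a relative threshold rides out post-drop undershoot; on a
            # noiseless linear rise the fit stays exact regardless)
            thresh = fmin + max(noise, 0.15 * (f[p] - fmin), 1e-12)
            rise_start[k] = prev + int(np.flatnonzero(seg <= thresh)[-1])
        else:
            rise_start[k] = prev

    events: list[UnfoldingEvent] = []
    for k, p in enumerate(peaks):
        seg = slice(rise_start[k], p + 1)
        xs, fs = x[seg], f[seg]
        if len(xs) >= 2 and xs[-1] > xs[0]:
            stiffness = float(np.polyfit(xs, fs, 1)[0])
        else:
            stiffness = float("nan")
        p2p = float(x[p] - x[peaks[k - 1]]) if k > 0 else float("nan")
        flags = set()
        if k == 0 and peaks.size > 1 and f[p] > f[peaks[1]]:
            flags.add("desorption")
        if k == peaks.size - 1 and peaks.size > 1 and f[p] > f[peaks[-2]]:
            flags.add("detachment")
        if f[p] > rules.max_abs_force or f[p] - baselines[k] > rules.max_rel_force:
            flags.add("excluded_force")
        if np.isfinite(p2p) and p2p > rules.max_peak_to_peak:
            flags.add("excluded_distance")
        events.append(
            UnfoldingEvent(
                peak_force_abs=float(f[p]),
                baseline=float(baselines[k]),
                extension_at_peak=float(x[p]),
                peak_to_peak=p2p,
                stiffness=stiffness,
                flags=frozenset(flags),
            )
        )

    total_ext = curve.total_extension
    if total_ext < rules.min_total_extension:
        return EventDetection(
            events,
            False,
            f"total extension {total_ext:.1f} nm < {rules.min_total_extension} nm",
        )
    n_unfolding = sum(
        1 for e in events if not ({"desorption", "detachment"} & e.flags)
    )
    if n_unfolding < rules.min_unfolding_peaks:
        return EventDetection(
            events,
            False,
            f"only {n_unfolding} unfolding peaks (< {rules.min_unfolding_peaks})",
        )
    return EventDetection(events, True)


def events_frame(events: Sequence[UnfoldingEvent]) -> pd.DataFrame:
    """Tabulate events (one row each) for delimited-text output."""
    return pd.DataFrame(
        {
            "peak_force_abs_pN": [e.peak_force_abs for e in events],
            "baseline_pN": [e.baseline for e in events],
            "force_pN": [e.peak_force_rel for e in events],
            "extension_nm": [e.extension_at_peak for e in events],
            "distance_nm": [e.peak_to_peak for e in events],
            "stiffness_pN_nm": [e.stiffness for e in events],
            "flags": [",".join(sorted(e.flags)) for e in events],
            "retained": [e.retained for e in events],
        }
    )


def _five_numbers(v: np.ndarray) -> dict[str, float]:
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {k: float("nan") for k in ("median", "q25", "q75", "iqr", "mean", "sem")}
    q25, med, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "iqr": float(q75 - q25),
        "mean": float(v.mean()),
        "sem": sem,
    }


def summarize(events: Sequence[UnfoldingEvent] | pd.DataFrame) -> dict:
    """Medians, IQRs, means and SEMs of force, distance and stiffness over
    retained events; per-label blocks when events carry labels."""
    if isinstance(events, pd.DataFrame):
        df = events
        if "retained" in df.columns:
            df = df[df["retained"]]
    else:
        df = events_frame([e for e in events if e.retained])
        if any(e.label is not None for e in events):
            df = df.assign(
                label=[e.label for e in events if e.retained]
            )
    if len(df) == 0:
        raise ValueError("no retained events to summarize")
    out: dict = {"n": int(len(df))}
    for key, col in (
        ("force", "force_pN"),
        ("distance", "distance_nm"),
        ("stiffness", "stiffness_pN_nm"),
    ):
        if col in df.columns:
            out[key] = _five_numbers(df[col].to_numpy(dtype=float))
    label_col = next(
        (c for c in ("label", "true_type") if c in df.columns), None
    )
    if label_col is not None:
        per: dict[int, dict] = {}
        for lab, grp in df.groupby(label_col):
            blk = {"n": int(len(grp))}
            for key, col in (("force", "force_pN"), ("distance", "distance_nm")):
                if col in grp.columns:
                    blk[key] = _five_numbers(grp[col].to_numpy(dtype=float))
            per[int(lab)] = blk
        out["per_type"] = per
    return out


@dataclass
class Histogram:
    counts: np.ndarray
    edges: np.ndarray
    bin_width: float
    fallback: bool = False  # True when the IQR was zero


def fd_histogram(values: Sequence[float]) -> Histogram:
    """Histogram with the Freedman-Diaconis bin width 2*IQR*n^(-1/3).

    A zero IQR (e.g. all-equal data) falls back to range/sqrt(n) with the
    ``fallback`` flag set; fully degenerate data gives a single bin.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need >= 4 values for a Freedman-Diaconis histogram")
    q25, q75 = np.percentile(v, [25, 75])
    iqr = q75 - q25
    fallback = False
    if iqr <= 0:
        fallback = True
        rng = v.max() - v.min()
        width = rng / np.sqrt(v.size) if rng > 0 else 1.0
    else:
        width = 2.0 * iqr * v.size ** (-1.0 / 3.0)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        n_bins = max(int(np.ceil((hi - lo) / width)), 1)
        edges = lo + width * np.arange(n_bins + 1)
        edges[-1] = max(edges[-1], hi)  # cover the max despite rounding
    counts, edges = np.histogram(v, bins=edges)
    return Histogram(counts, edges, float(width), fallback)


def scott_bandwidth(values: np.ndarray) -> float:
    """Scott's rule h = SD * M^(-1/5) (the SD factor makes the bandwidth
    dimensionally a force; see docs/methods.md)."""
    v = np.asarray(values, dtype=float)
    return float(v.std(ddof=1) * v.size ** (-1.0 / 5.0))


def kde(values: Sequence[float], grid: Sequence[float], bandwidth: float | None = None) -> np.ndarray:
    """Gaussian kernel density estimate on ``grid``.

    The default bandwidth is Scott's rule.  Evaluation is chunked so that
    M ~ 1e5 samples stay within modest memory.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(grid, dtype=float)
    if v.size < 2:
        raise ValueError("KDE requires at least two observations")
    h = bandwidth if bandwidth is not None else scott_bandwidth(v)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    out = np.zeros(g.shape)
    chunk = max(1, int(2e6 / max(g.size, 1)))
    for start in range(0, v.size, chunk):
        block = v[start : start + chunk]
        out += norm.pdf((g[:, None] - block[None, :]) / h).sum(axis=1)
    return out / (v.size * h)
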