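"""FRAP analysis: exponential fits of nuclear import/export kinetics.

After whole-compartment bleaching, two-pool first-order exchange
between nucleus and cytoplasm makes the nuclear signal relax as a
single exponential with rate k = k_in + k_out:

    recovery (nuclear bleach):  I(t) = I_inf - A * exp(-k t)
    decay (cytoplasmic bleach): I(t) = I_inf + A * exp(-k t)

The fits here estimate (k, A, I_inf) by bounded least squares on the
post-bleach window, initialised from a log-linearised estimate with a
small multi-start on k to avoid local minima on noisy traces.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FrapTrace",
    "FrapFit",
    "FrapFitError",
    "normalize_trace",
    "fit_recovery",
    "fit_decay",
    "read_frap_trace",
]

#: fitted amplitudes below this fraction of the signal span are treated
#: as a flat trace whose rate is not interpretable
FLAT_AMPLITUDE_FRACTION = 1e-3


class FrapFitError(RuntimeError):
    """Exponential fit failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class FrapTrace:
    """Compartment-mean intensity versus time around a bleach event.

    ``bleach_index`` points at the first post-bleach sample (the frame
    acquired at the moment the bleach takes effect).
    """

    time: np.ndarray
    nuclear_intensity: np.ndarray
    cytoplasmic_intensity: np.ndarray | None
    bleach_index: int
    bleach_target: str

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(
            self, "nuclear_intensity", np.asarray(self.nuclear_intensity, dtype=float)
        )
        if self.cytoplasmic_intensity is not None:
            object.__setattr__(
                self,
                "cytoplasmic_intensity",
                np.asarray(self.cytoplasmic_intensity, dtype=float),
            )
        if time.size != self.nuclear_intensity.size:
            raise ValueError("time and nuclear_intensity lengths differ")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not 0 <= self.bleach_index < time.size:
            raise ValueError("bleach_index out of range")
        if time.size - self.bleach_index - 1 < 8:
            raise ValueError("need at least 8 post-bleach samples")
        if self.bleach_target not in ("nucleus", "cytoplasm"):
            raise ValueError("bleach_target must be 'nucleus' or 'cytoplasm'")

    @property
    def n_prebleach(self) -> int:
        return self.bleach_index


@dataclass(frozen=True)
class FrapFit:
    """Single-exponential fit result; ``flat`` flags an amplitude
    indistinguishable from zero (rate not interpretable)."""

    k: float
    amplitude: float
    plateau: float
    rss: float
    mode: str
    flat: bool = False

    def __post_init__(self) -> None:
        if self.k < 0 or self.rss < 0:
            raise ValueError("k and rss must be >= 0")


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Normalise to the mean pre-bleach nuclear intensity and shift time
    so the bleach occurs at t = 0."""
    if trace.n_prebleach < 2:
        raise ValueError("need at least 2 pre-bleach samples to normalise")
    ref = float(np.mean(trace.nuclear_intensity[: trace.bleach_index]))
    if ref <= 0:
        raise ValueError("pre-bleach nuclear mean must be positive")
    cyto = trace.cytoplasmic_intensity
    return replace(
        trace,
        time=trace.time - trace.time[trace.bleach_index],
        nuclear_intensity=trace.nuclear_intensity / ref,
        cytoplasmic_intensity=None if cyto is None else cyto / ref,
    )


def _postbleach(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Post-bleach window; the bleach frame itself is excluded."""
    sel = slice(trace.bleach_index + 1, None)
    return trace.time[sel], trace.nuclear_intensity[sel]


def _initial_rate(t: np.ndarray, resid: np.ndarray) -> float:
    """Log-linearised k estimate from |I_inf - I| ~ A exp(-k t)."""
    good = resid > 1e-3 * max(resid.max(), 1e-12)
    if good.sum() < 3:
        return 1.0 / max(t[-1] - t[0], 1e-9)
    slope = np.polyfit(t[good], np.log(resid[good]), 1)[0]
    return float(np.clip(-slope, 1e-6, None))


def _fit_exponential(t: np.ndarray, y: np.ndarray, sign: float, mode: str) -> FrapFit:
    span = float(y.max() - y.min())
    if span == 0:
        return FrapFit(k=0.0, amplitude=0.0, plateau=float(y[0]), rss=0.0, mode=mode, flat=True)
    n_tail = max(3, t.size // 10)
    plateau0 = float(np.mean(y[-n_tail:]))
    amp0 = max(abs(plateau0 - float(y[0])), 1e-6 * span)
    resid0 = np.abs(plateau0 - y)
    k0 = _initial_rate(t, resid0)

    def model(params: np.ndarray) -> np.ndarray:
        k, a, p = params
        return p - sign * a * np.exp(-k * t) - y

    best, diagnostics = None, []
    for factor in (1.0, 0.3, 3.0):
        try:
            res = least_squares(
                model,
                x0=[k0 * factor, amp0, plateau0],
                bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append(f"start x{factor}: {exc}")
            continue
        if not res.success:
            diagnostics.append(f"start x{factor}: {res.message}")
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise FrapFitError("exponential fit did not converge", diagnostics)
    rss, (k, a, p) = best
    flat = a < FLAT_AMPLITUDE_FRACTION * span
    return FrapFit(k=float(k), amplitude=float(a), plateau=float(p), rss=rss, mode=mode, flat=flat)


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Fit I(t) = I_inf - A exp(-k t) to the post-bleach nuclear signal
    (nuclear bleach; fluorescence recovers by import)."""
    t, y = _postbleach(trace)
    return _fit_exponential(t - trace.time[trace.bleach_index], y, +1.0, "recovery")


def fit_decay(trace: FrapTrace) -> FrapFit:
    """Fit I(t) = I_inf + A exp(-k t) to the post-bleach nuclear signal
    (cytoplasmic bleach; nuclear fluorescence decays by exchange)."""
    t, y = _postbleach(trace)
    return _fit_exponential(t - trace.time[trace.bleach_index], y, -1.0, "decay")


def read_frap_trace(path: str | Path, bleach_target: str | None = None) -> FrapTrace:
    """Read a trace CSV (columns time_s, nuclear_mean, cytoplasmic_mean,
    bleach_frame).  If ``bleach_target`` is omitted it is inferred from
    whether the nuclear signal drops at the bleach frame."""
    times, nuc, cyto = [], [], []
    bleach_index = 0
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            times.append(float(row["time_s"]))
            nuc.append(float(row["nuclear_mean"]))
            cyto.append(float(row["cytoplasmic_mean"]))
            bleach_index = int(row["bleach_frame"])
    nuc_arr = np.array(nuc)
    cyto_arr = np.array(cyto)
    if bleach_target is None:
        pre = float(np.mean(nuc_arr[:bleach_index])) if bleach_index else nuc_arr[0]
        bleach_target = "nucleus" if nuc_arr[bleach_index] < 0.9 * pre else "cytoplasm"
    return FrapTrace(
        time=np.array(times),
        nuclear_intensity=nuc_arr,
        cytoplasmic_intensity=None if np.all(np.isnan(cyto_arr)) else cyto_arr,
        bleach_index=bleach_index,
        bleach_target=bleach_target,
    )
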