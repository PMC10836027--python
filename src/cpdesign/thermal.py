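"""Thermal-denaturation analytics for CD melts and DSC thermograms.

Two experimental readouts of permutant stability are supported:

* **CD melts** — ellipticity vs. temperature at a fixed wavelength.  The
  half-transition temperature t_1/2 is extracted by fitting a two-state
  van't Hoff model with linear folded/unfolded baselines,

      y(T) = y_pre(T) + [y_post(T) - y_pre(T)] * f(T),
      f(T) = 1 / (1 + exp[(dH_vH / R) * (1/T - 1/T_half)]),   T in kelvin,

  where f is the fraction unfolded and dH_vH the van't Hoff enthalpy.  A
  model-free alternative (interpolating the normalized curve at f = 0.5) is
  provided for curves a two-state fit does not describe.

* **DSC thermograms** — heat capacity vs. temperature.  The excess heat
  capacity is isolated by subtracting linearly extrapolated pre- and
  post-transition baselines joined through a sigmoid progress baseline: the
  mixing fraction is the normalized running integral of the current excess,
  iterated to a fixed point.  Peaks of the excess curve give t_m per
  transition; multi-peak thermograms flag intermediate states.

A seeded synthetic generator produces CD melts and (multi-transition) DSC
thermograms from the same two-state model, for parameter-recovery testing.
Defaults mirror a typical acquisition: 20-90 degC in 1 degC steps, unit
amplitude, 2% Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.special import expit

R_GAS = 8.314  # J mol^-1 K^-1
_KELVIN = 273.15


class FitError(RuntimeError):
    """Raised when a melting-curve fit cannot be brought to convergence."""


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class MeltCurve:
    """A temperature-indexed CD trace (raw ellipticity or normalized)."""

    temperatures: np.ndarray  # degC, strictly increasing
    signal: np.ndarray
    wavelength: float | None = None  # nm
    normalized: bool = False
    noise_tolerance: float = 0.1  # slack on [0,1] bounds when normalized

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", y)
        if t.size != y.size or t.size == 0:
            raise ValueError("temperatures and signal must be non-empty, equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.normalized:
            tol = self.noise_tolerance
            if np.any(y < -tol) or np.any(y > 1 + tol):
                raise ValueError(
                    "normalized curve has values outside [0, 1] beyond the "
                    f"recorded noise tolerance {tol}"
                )

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class DSCThermogram:
    """A temperature-indexed heat-capacity trace, optionally with the
    baseline-corrected excess heat capacity."""

    temperatures: np.ndarray  # degC, strictly increasing
    cp: np.ndarray  # any consistent heat-capacity units
    excess: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "cp", c)
        if self.excess is not None:
            object.__setattr__(self, "excess", np.asarray(self.excess, dtype=float))
        if t.size != c.size or t.size == 0:
            raise ValueError("temperatures and cp must be non-empty, equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.excess is not None and len(self.excess) != t.size:
            raise ValueError("excess length mismatch")

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class TwoStateFit:
    """Result of a two-state van't Hoff fit to a melt curve."""

    t_half: float  # degC
    dH_vH: float  # kJ/mol
    pre_slope: float
    pre_intercept: float
    post_slope: float
    post_intercept: float
    rmse: float
    method: str = "fit"  # "fit" | "interp"

    def fraction_unfolded(self, temperatures: np.ndarray) -> np.ndarray:
        return _fraction_unfolded(np.asarray(temperatures, float), self.t_half, self.dH_vH)


@dataclass(frozen=True)
class SyntheticMeltParams:
    """Generating parameters for synthetic melts and thermograms.

    ``t_m``/``dH_vH`` describe the (first) transition; for DSC, ``transitions``
    holds one ``(t_m degC, dH_vH kJ/mol, weight)`` triple per transition and
    overrides the scalar pair.  Baselines are linear in temperature.
    ``noise_sd`` is the Gaussian noise s.d. in signal units (the default
    curve has unit amplitude, so 0.02 is 2% of amplitude).
    """

    t_m: float = 60.0  # degC
    dH_vH: float = 300.0  # kJ/mol
    pre_slope: float = 0.0
    pre_intercept: float = 0.0
    post_slope: float = 0.0
    post_intercept: float = 1.0
    noise_sd: float = 0.02
    n_points: int = 71
    t_min: float = 20.0
    t_max: float = 90.0
    seed: int = 0
    transitions: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")

    @property
    def all_transitions(self) -> tuple[tuple[float, float, float], ...]:
        return self.transitions or ((self.t_m, self.dH_vH, 1.0),)


# ---------------------------------------------------------------------------
# elementary transforms

def molar_ellipticity(theta_obs: float, m_res: float, c: float, l: float) -> float:
    """Molar ellipticity [theta] = theta_obs * M_res / (c * L).

    ``theta_obs`` in degrees, ``m_res`` mean residue mass (g/mol), ``c``
    protein concentration (g/L), ``l`` path length (mm).
    """
    if c <= 0 or l <= 0:
        raise ValueError("concentration and path length must be positive")
    return theta_obs * m_res / (c * l)


def _fraction_unfolded(t_c: np.ndarray, t_half_c: float, dh_kj: float) -> np.ndarray:
    """Two-state van't Hoff fraction unfolded; temperatures in degC."""
    t_k = t_c + _KELVIN
    t_half_k = t_half_c + _KELVIN
    u = (dh_kj * 1000.0 / R_GAS) * (1.0 / t_k - 1.0 / t_half_k)
    return expit(-u)


def _fit_outer_baselines(
    t: np.ndarray, y: np.ndarray, fraction: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """Linear fits ((slope, intercept) pairs) on the outer temperature windows."""
    span = t[-1] - t[0]
    pre = t <= t[0] + fraction * span
    post = t >= t[-1] - fraction * span
    if pre.sum() < 2 or post.sum() < 2:
        raise ValueError("too few points in baseline windows")
    return np.polyfit(t[pre], y[pre], 1), np.polyfit(t[post], y[post], 1)


def normalize_melt(curve: MeltCurve, mode: str = "minmax") -> MeltCurve:
    """Rescale a melt curve to the 0-1 range.

    ``minmax`` maps the observed extremes to 0 and 1 (idempotent).
    ``baseline_fraction`` converts signal to fraction unfolded using linear
    pre-/post-transition baselines fitted on the outer 15% windows:
    f(T) = (y - y_pre(T)) / (y_post(T) - y_pre(T)).
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 points to normalize")
    t, y = curve.temperatures, curve.signal
    if mode == "minmax":
        rng = y.max() - y.min()
        if rng == 0:
            raise ValueError("constant signal: zero range, cannot normalize")
        norm = (y - y.min()) / rng
    elif mode == "baseline_fraction":
        (b1, b0), (a1, a0) = _fit_outer_baselines(t, y)
        y_pre = b1 * t + b0
        y_post = a1 * t + a0
        denom = y_post - y_pre
        if np.any(np.abs(denom) < 1e-12 * max(1.0, np.abs(y).max())):
            raise ValueError("pre- and post-transition baselines coincide")
        norm = (y - y_pre) / denom
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MeltCurve(
        temperatures=t.copy(),
        signal=norm,
        wavelength=curve.wavelength,
        normalized=True,
        noise_tolerance=max(curve.noise_tolerance, 0.1),
    )


# ---------------------------------------------------------------------------
# CD melt fitting

def _initial_t_half(t: np.ndarray, y: np.ndarray) -> float:
    """Temperature of steepest signal change (Savitzky-Golay derivative)."""
    window = min(7, len(y) if len(y) % 2 else len(y) - 1)
    if window >= 5:
        dy = _signal.savgol_filter(y, window, polyorder=2, deriv=1)
    else:
        dy = np.gradient(y, t)
    interior = slice(1, -1) if len(t) > 4 else slice(None)
    idx = np.argmax(np.abs(dy[interior])) + (1 if len(t) > 4 else 0)
    return float(t[idx])


def fit_half_transition(
    curve: MeltCurve, dh_init: float = 300.0
) -> TwoStateFit:
    """Fit the two-state van't Hoff model with linear baselines.

    Initialization: t_half at the steepest point of the smoothed curve,
    baselines from the outer 15% windows, dH_vH from ``dh_init``.  Bounded
    least squares (t_half within the data range, dH_vH in [50, 2000] kJ/mol);
    several dH_vH restarts are attempted before giving up.
    """
    t, y = curve.temperatures, curve.signal
    if len(curve) < 8:
        raise FitError("too few points for a two-state fit (need >= 8)")
    (b1, b0), (a1, a0) = _fit_outer_baselines(t, y)
    t0 = _initial_t_half(t, y)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        f = _fraction_unfolded(t, params["t_half"].value, params["dh"].value)
        y_pre = params["pre_slope"] * t + params["pre_intercept"]
        y_post = params["post_slope"] * t + params["post_intercept"]
        return y_pre + (y_post - y_pre) * f - y

    best: tuple[float, lmfit.minimizer.MinimizerResult] | None = None
    for dh0 in (dh_init, 100.0, 600.0, 1200.0):
        params = lmfit.Parameters()
        params.add("t_half", value=t0, min=float(t[0]), max=float(t[-1]))
        params.add("dh", value=dh0, min=50.0, max=2000.0)
        params.add("pre_slope", value=b1)
        params.add("pre_intercept", value=b0)
        params.add("post_slope", value=a1)
        params.add("post_intercept", value=a0)
        result = lmfit.minimize(residual, params, method="leastsq")
        if not result.success:
            continue
        rmse = float(np.sqrt(np.mean(result.residual**2)))
        if best is None or rmse < best[0]:
            best = (rmse, result)
        if rmse < 0.05 * (y.max() - y.min()):
            break
    if best is None:
        raise FitError(
            "two-state fit failed to converge from all initializations "
            f"(t_half0={t0:.1f} degC, data range {t[0]:.1f}..{t[-1]:.1f})"
        )
    rmse, result = best
    p = result.params
    return TwoStateFit(
        t_half=float(p["t_half"].value),
        dH_vH=float(p["dh"].value),
        pre_slope=float(p["pre_slope"].value),
        pre_intercept=float(p["pre_intercept"].value),
        post_slope=float(p["post_slope"].value),
        post_intercept=float(p["post_intercept"].value),
        rmse=rmse,
        method="fit",
    )


def half_transition_interp(curve: MeltCurve) -> TwoStateFit:
    """Model-free t_1/2: where the baseline-normalized curve crosses 0.5.

    Smooths the fraction-unfolded curve and linearly interpolates the 0.5
    crossing nearest the steepest point.  dH_vH is reported from the local
    slope at the crossing (van't Hoff relation df/dT|_{1/2} = dH/(4RT^2)),
    so the result remains a :class:`TwoStateFit` record.
    """
    frac = normalize_melt(curve, mode="baseline_fraction")
    t, f = frac.temperatures, frac.signal
    if f[0] > f[-1]:  # unfolding decreases the signal: flip to fraction unfolded
        f = 1.0 - f
    window = min(7, len(f) if len(f) % 2 else len(f) - 1)
    if window >= 5:
        f = _signal.savgol_filter(f, window, polyorder=2)
    crossings = np.nonzero(np.diff(np.sign(f - 0.5)))[0]
    if crossings.size == 0:
        raise FitError("normalized curve never crosses 0.5 within the data range")
    steep = _initial_t_half(t, f)
    i = min(crossings, key=lambda k: abs(t[k] - steep))
    t_half = float(
        t[i] + (0.5 - f[i]) * (t[i + 1] - t[i]) / (f[i + 1] - f[i])
    )
    slope = (f[i + 1] - f[i]) / (t[i + 1] - t[i])
    dh = abs(slope) * 4.0 * R_GAS * (t_half + _KELVIN) ** 2 / 1000.0
    resid = f - _fraction_unfolded(t, t_half, max(dh, 50.0))
    return TwoStateFit(
        t_half=t_half,
        dH_vH=float(dh),
        pre_slope=0.0,
        pre_intercept=0.0,
        post_slope=0.0,
        post_intercept=1.0,
        rmse=float(np.sqrt(np.mean(resid**2))),
        method="interp",
    )


# ---------------------------------------------------------------------------
# DSC

def excess_heat_capacity(
    thermogram: DSCThermogram,
    windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
    window_fraction: float = 0.15,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> DSCThermogram:
    """Baseline-correct a thermogram to excess heat capacity.

    Linear baselines are fitted on the pre- and post-transition windows
    (explicit ``((t_lo, t_hi), (t_lo, t_hi))`` pairs, or the outer
    ``window_fraction`` of the temperature range).  They are joined by a
    sigmoid progress baseline: with transition progress a(T),

        baseline(T) = y_pre(T) * (1 - a(T)) + y_post(T) * a(T),

    where a(T) is the normalized running integral of the current excess.
    Starting from a(T) given by the min-max-normalized cp, the scheme is
    iterated to a fixed point (max |change in excess| < tol * max excess).

    The result is exactly invariant under adding any global linear function
    to cp, since both window fits absorb it.
    """
    t, cp = thermogram.temperatures, thermogram.cp
    if windows is not None:
        (p_lo, p_hi), (q_lo, q_hi) = windows
        if p_hi >= q_lo:
            raise ValueError(
                f"baseline windows overlap: pre ends at {p_hi}, post starts at {q_lo}"
            )
        pre = (t >= p_lo) & (t <= p_hi)
        post = (t >= q_lo) & (t <= q_hi)
        if pre.sum() < 2 or post.sum() < 2:
            raise ValueError("too few points in baseline windows")
        coeff_pre = np.polyfit(t[pre], cp[pre], 1)
        coeff_post = np.polyfit(t[post], cp[post], 1)
    else:
        coeff_pre, coeff_post = _fit_outer_baselines(t, cp, window_fraction)
    y_pre = np.polyval(coeff_pre, t)
    y_post = np.polyval(coeff_post, t)

    rng = cp.max() - cp.min()
    alpha = (cp - cp.min()) / rng if rng > 0 else np.zeros_like(cp)
    excess = cp - (y_pre * (1 - alpha) + y_post * alpha)
    for _ in range(max_iter):
        area = np.concatenate(
            [[0.0], np.cumsum(np.diff(t) * 0.5 * (excess[1:] + excess[:-1]))]
        )
        total = area[-1]
        scale = max(abs(total), 1e-12 * max(abs(excess).max(), 1.0))
        alpha = np.clip(area / scale if scale > 0 else alpha, 0.0, 1.0)
        new_excess = cp - (y_pre * (1 - alpha) + y_post * alpha)
        delta = np.abs(new_excess - excess).max()
        excess = new_excess
        if delta <= tol * max(abs(excess).max(), 1e-12):
            break
    else:
        raise FitError(
            f"sigmoid-baseline iteration did not converge in {max_iter} steps "
            f"(last change {delta:.3g})"
        )
    return DSCThermogram(temperatures=t.copy(), cp=cp.copy(), excess=excess)


def find_peaks(
    thermogram: DSCThermogram, min_prominence_fraction: float = 0.1
) -> list[tuple[float, float]]:
    """Transition peaks of the excess heat capacity.

    Local maxima with prominence at least ``min_prominence_fraction`` of the
    global maximum, refined by a parabola through the three points around
    each maximum; returned as ``(t_m degC, height)`` sorted by descending
    height.  An empty list means no transition above threshold.
    """
    if thermogram.excess is None:
        raise ValueError("excess heat capacity not computed; run excess_heat_capacity")
    t, ex = thermogram.temperatures, thermogram.excess
    top = ex.max()
    if top <= 0:
        return []
    idx, _ = _signal.find_peaks(ex, prominence=min_prominence_fraction * top)
    peaks = []
    for i in idx:
        if 0 < i < len(ex) - 1:
            # parabolic refinement through (i-1, i, i+1)
            y0, y1, y2 = ex[i - 1], ex[i], ex[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -1.0, 1.0))
            dt = 0.5 * (t[i + 1] - t[i - 1])
            t_m = float(t[i] + shift * dt)
            height = float(y1 - 0.25 * (y0 - y2) * shift)
        else:
            t_m, height = float(t[i]), float(ex[i])
        peaks.append((t_m, height))
    peaks.sort(key=lambda p: -p[1])
    return peaks


# ---------------------------------------------------------------------------
# synthetic generator

def _dsc_excess_model(
    t: np.ndarray, transitions: tuple[tuple[float, float, float], ...]
) -> np.ndarray:
    """Sum of weight * dH * df/dT over transitions (kJ mol^-1 K^-1)."""
    total = np.zeros_like(t)
    for t_m, dh, weight in transitions:
        f = _fraction_unfolded(t, t_m, dh)
        t_k = t + _KELVIN
        total += weight * dh * f * (1 - f) * (dh * 1000.0 / R_GAS) / t_k**2
    return total


def simulate_cd_melt(params: SyntheticMeltParams) -> MeltCurve:
    """Synthetic two-state CD melt: linear baselines mixed by the van't Hoff
    sigmoid, plus seeded Gaussian noise.  Deterministic for a fixed seed."""
    t = np.linspace(params.t_min, params.t_max, params.n_points)
    f = _fraction_unfolded(t, params.t_m, params.dH_vH)
    y_pre = params.pre_slope * t + params.pre_intercept
    y_post = params.post_slope * t + params.post_intercept
    y = y_pre + (y_post - y_pre) * f
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        y = y + rng.normal(0.0, params.noise_sd, size=t.size)
    return MeltCurve(temperatures=t, signal=y)


def simulate_dsc(params: SyntheticMeltParams) -> DSCThermogram:
    """Synthetic DSC thermogram: linear instrument baselines joined by the
    overall transition progress, plus the excess-heat-capacity peaks
    (weight * dH * df/dT per transition) and seeded Gaussian noise."""
    t = np.linspace(params.t_min, params.t_max, params.n_points)
    transitions = params.all_transitions
    weight_sum = sum(w for _, _, w in transitions)
    progress = np.zeros_like(t)
    for t_m, dh, weight in transitions:
        progress += (weight / weight_sum) * _fraction_unfolded(t, t_m, dh)
    y_pre = params.pre_slope * t + params.pre_intercept
    y_post = params.post_slope * t + params.post_intercept
    cp = y_pre + (y_post - y_pre) * progress + _dsc_excess_model(t, transitions)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        cp = cp + rng.normal(0.0, params.noise_sd, size=t.size)
    return DSCThermogram(temperatures=t, cp=cp)


# ---------------------------------------------------------------------------
# CSV I/O

def read_melt_csv(path: str | Path, kind: str = "cd") -> MeltCurve | DSCThermogram:
    """Read a curve from CSV with header ``temperature_C,signal``."""
    frame = pd.read_csv(path)
    cols = [c.strip() for c in frame.columns]
    if "temperature_C" not in cols or "signal" not in cols:
        raise ValueError(
            f"{path}: expected header 'temperature_C,signal', got {list(frame.columns)}"
        )
    frame.columns = cols
    t = frame["temperature_C"].to_numpy(float)
    y = frame["signal"].to_numpy(float)
    if kind == "cd":
        return MeltCurve(temperatures=t, signal=y)
    if kind == "dsc":
        return DSCThermogram(temperatures=t, cp=y)
    raise ValueError(f"unknown kind {kind!r} (expected 'cd' or 'dsc')")


def write_melt_csv(curve: MeltCurve | DSCThermogram, path: str | Path) -> None:
    """Write a curve as ``temperature_C,signal`` CSV."""
    y = curve.signal if isinstance(curve, MeltCurve) else curve.cp
    pd.DataFrame({"temperature_C": curve.temperatures, "signal": y}).to_csv(
        path, index=False
    )
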