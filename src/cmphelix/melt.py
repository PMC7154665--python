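"""Two-state thermal denaturation fitting of CD melt curves.

A collagen triple helix unfolds cooperatively; monitoring the ellipticity
(typically at 225 nm) against temperature yields a sigmoidal decay whose
midpoint — the temperature at which half of the material is folded — is the
transition temperature Tm.  Two model families are provided:

``boltzmann``
    An empirical sigmoid, f_folded(T) = 1 / (1 + exp((T - Tm) / k)), where k
    (deg C) sets the transition width.

``trimer_two_state``
    A van't Hoff two-state trimer <-> 3 monomer equilibrium.  With x the
    fraction of strands in trimers and total strand concentration folded into
    the equilibrium constant, x solves (1 - x)^3 / x = 0.25 *
    exp[(dH/R) * (1/Tm_K - 1/T_K)], so x(Tm) = 0.5 by construction.

Both models share linear folded/unfolded baselines,
signal(T) = x*(fa + fb*T) + (1 - x)*(ua + ub*T), and in both Tm is reported
as the folded-fraction-0.5 midpoint, so the two families agree on the
quantity of interest.  Temperatures are in deg C throughout; the van't Hoff
model converts to kelvin internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import MeltFitError

R_GAS = 8.31446261815324e-3  # kJ mol^-1 K^-1
_T0 = 273.15

MODELS = ("boltzmann", "trimer_two_state")


@dataclass
class MeltCurve:
    """A temperature (deg C) vs ellipticity series."""

    temperature: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise MeltFitError("temperature and signal must have equal length")
        if self.temperature.size < 10:
            raise MeltFitError("melt curve needs at least 10 points")
        if not np.all(np.diff(self.temperature) > 0):
            raise MeltFitError("temperature grid must be strictly increasing")


@dataclass
class MeltFitResult:
    tm: float
    slope: float  # k (deg C) for boltzmann, dH (kJ/mol) for trimer_two_state
    folded_baseline: tuple[float, float]  # (intercept, slope)
    unfolded_baseline: tuple[float, float]
    rss: float
    converged: bool
    model: str
    message: str = ""


def boltzmann_fraction(temp_c: np.ndarray, tm: float, k: float) -> np.ndarray:
    """Folded fraction of the empirical sigmoid."""
    z = np.clip((np.asarray(temp_c, dtype=float) - tm) / max(k, 1e-9), -500, 500)
    return 1.0 / (1.0 + np.exp(z))


def trimer_fraction(temp_c: np.ndarray, tm: float, dh: float) -> np.ndarray:
    """Folded strand fraction of the trimer <-> 3 monomer van't Hoff model."""
    temp_c = np.atleast_1d(np.asarray(temp_c, dtype=float))
    t_k = temp_c + _T0
    tm_k = tm + _T0
    ln_kappa = np.log(0.25) + (dh / R_GAS) * (1.0 / tm_k - 1.0 / t_k)
    ln_kappa = np.clip(ln_kappa, -500, 500)
    kappa = np.exp(ln_kappa)
    # unique root of (1-x)^3 - kappa*x on (0, 1); the function is strictly
    # decreasing in x, so vectorized bisection converges unconditionally
    lo = np.zeros_like(kappa)
    hi = np.ones_like(kappa)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        pos = (1.0 - mid) ** 3 - kappa * mid > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


def _model_signal(model: str):
    frac = boltzmann_fraction if model == "boltzmann" else trimer_fraction

    def f(temp, tm, width, fa, fb, ua, ub):
        x = frac(temp, tm, width)
        return x * (fa + fb * temp) + (1.0 - x) * (ua + ub * temp)

    return f


def _auto_init(curve: MeltCurve) -> dict:
    t, y = curve.temperature, curve.signal
    dy = np.gradient(y, t)
    tm0 = float(t[np.argmin(dy)])  # steepest decrease
    n_edge = max(3, t.size // 10)
    fa_fit = np.polyfit(t[:n_edge], y[:n_edge], 1)
    ua_fit = np.polyfit(t[-n_edge:], y[-n_edge:], 1)
    return {
        "tm": tm0,
        "folded_baseline": (float(fa_fit[1]), float(fa_fit[0])),
        "unfolded_baseline": (float(ua_fit[1]), float(ua_fit[0])),
    }


def fit_melt(curve: MeltCurve, model: str = "boltzmann", init: dict | None = None) -> MeltFitResult:
    """Fit a two-state melt model; Tm is the folded-fraction-0.5 midpoint.

    A curve without a detectable sigmoidal transition yields
    ``converged=False`` with the reason in ``message`` — never a fabricated
    Tm.
    """
    if model not in MODELS:
        raise MeltFitError(f"unknown model {model!r}; choose from {MODELS}")
    t, y = curve.temperature, curve.signal
    auto = _auto_init(curve)
    if init:
        auto.update(init)
    width0 = auto.get("slope", 2.0 if model == "boltzmann" else 300.0)
    fa0, fb0 = auto["folded_baseline"]
    ua0, ub0 = auto["unfolded_baseline"]
    p0 = [auto["tm"], width0, fa0, fb0, ua0, ub0]
    width_bounds = (0.05, 50.0) if model == "boltzmann" else (10.0, 5000.0)
    bounds = (
        [t[0], width_bounds[0], -np.inf, -np.inf, -np.inf, -np.inf],
        [t[-1], width_bounds[1], np.inf, np.inf, np.inf, np.inf],
    )
    p0[0] = float(np.clip(p0[0], t[0], t[-1]))
    p0[1] = float(np.clip(p0[1], *width_bounds))
    f = _model_signal(model)
    try:
        popt, _ = optimize.curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return MeltFitResult(np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan),
                             np.nan, False, model, f"fit failed: {exc}")
    tm, width, fa, fb, ua, ub = (float(v) for v in popt)
    resid = y - f(t, *popt)
    rss = float(np.sum(resid**2))
    result = MeltFitResult(tm, width, (fa, fb), (ua, ub), rss, True, model)
    # transition must be real: midpoint amplitude above the noise floor and
    # Tm strictly inside the scanned range
    amplitude = abs((fa + fb * tm) - (ua + ub * tm))
    noise = np.sqrt(rss / max(t.size - 6, 1))
    span = abs(float(np.ptp(y)))
    if amplitude < max(5.0 * noise, 1e-3 * max(span, 1e-12)) or span == 0.0:
        result.converged = False
        result.message = "no sigmoidal transition detected (amplitude below noise floor)"
    elif not (t[0] < tm < t[-1]):
        result.converged = False
        result.message = "fitted midpoint at the edge of the temperature range"
    return result


def fraction_folded(curve: MeltCurve, fit: MeltFitResult) -> np.ndarray:
    """Baseline-corrected normalized signal, clipped to [0, 1]; 0.5 at Tm."""
    if not fit.converged:
        raise MeltFitError("fraction_folded requires a converged fit")
    t, y = curve.temperature, curve.signal
    fa, fb = fit.folded_baseline
    ua, ub = fit.unfolded_baseline
    denom = (fa + fb * t) - (ua + ub * t)
    if np.any(np.abs(denom) < 1e-12):
        raise MeltFitError("degenerate baselines: folded and unfolded coincide")
    return np.clip((y - (ua + ub * t)) / denom, 0.0, 1.0)


def delta_tm(a: MeltFitResult, b: MeltFitResult) -> float:
    """Transition-temperature difference a - b (deg C)."""
    if not (a.converged and b.converged):
        raise MeltFitError("delta_tm requires two converged fits")
    return a.tm - b.tm


def read_melt_csv(path) -> MeltCurve:
    """Read a (temperature, signal) CSV; extra columns go to metadata."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("temperature", df.columns[0])
    scol = cols.get("signal", cols.get("ellipticity", df.columns[1]))
    return MeltCurve(df[tcol].to_numpy(float), df[scol].to_numpy(float))


def write_melt_csv(curve: MeltCurve, path) -> None:
    pd.DataFrame({"temperature": curve.temperature, "signal": curve.signal}).to_csv(
        path, index=False
    )
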