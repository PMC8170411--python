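"""Spatial-frequency tuning: curves, Difference-of-Gaussians fits, Q factor.

The tuning curve of a unit is its baseline-subtracted mean firing rate in an
early window (0.05-0.2 s) at each of the six SF band centers.  A
seven-parameter Difference-of-Gaussians model

    R(SF) = R0 + Ke * exp(-(SF-mu_e)^2 / (2 sigma_e^2))
               - Ki * exp(-(SF-mu_i)^2 / (2 sigma_i^2))

is fitted by bounded least squares; the normalized residual
``sum((y_i - f_i)^2) / sum((y_i - ybar)^2)`` is the fit error.  The
preferred SF is the argmax of the fitted curve on a dense log grid, and
tuning sharpness is the quality factor Q = SF_peak / (SF_high - SF_low)
with the half-maximum cutoffs of the baseline-subtracted fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import Condition, StimulusSequence, epoch_rates

__all__ = ["DoGFit", "dog_model", "tuning_curve", "late_response", "fit_dog",
           "q_factor", "assign_tuning_group", "EARLY_WINDOW_S",
           "LATE_WINDOW_S", "PREF_SF_GRID_CPD"]

EARLY_WINDOW_S = (0.05, 0.2)
LATE_WINDOW_S = (0.2, 0.5)
BASELINE_WINDOW_S = (-0.25, 0.05)

#: Dense log-spaced grid on which the preferred SF is located, one octave
#: beyond the stimulated 0.0075-0.24 cpd range on each side.
PREF_SF_GRID_CPD = np.logspace(np.log10(0.00375), np.log10(0.48), 512)

#: Tuned_in boundaries: preferred SF within one octave of the 0.03 cpd
#: oddball SF (exclusive).
TUNED_IN_RANGE_CPD = (0.015, 0.06)

FIT_ERROR_UNTUNED = 0.9


def dog_model(sf, r0, ke, ki, mu_e, mu_i, sigma_e, sigma_i):
    """Difference-of-Gaussians tuning model evaluated at ``sf`` (cpd)."""
    sf = np.asarray(sf, dtype=float)
    exc = ke * np.exp(-((sf - mu_e) ** 2) / (2.0 * sigma_e ** 2 + 1e-300))
    inh = ki * np.exp(-((sf - mu_i) ** 2) / (2.0 * sigma_i ** 2 + 1e-300))
    return r0 + exc - inh


@dataclass
class DoGFit:
    """Fitted DoG parameters plus derived tuning descriptors."""

    r0: float
    ke: float
    ki: float
    mu_e: float
    mu_i: float
    sigma_e: float
    sigma_i: float
    fit_error: float
    converged: bool
    pref_sf_cpd: float
    q_factor: float | None  # None when a half-max cutoff is not bracketed

    @property
    def params(self) -> tuple[float, ...]:
        return (self.r0, self.ke, self.ki, self.mu_e, self.mu_i,
                self.sigma_e, self.sigma_i)

    def predict(self, sf) -> np.ndarray:
        return dog_model(sf, *self.params)


def _mean_rates_per_band(spike_times_s, events: StimulusSequence,
                         window: tuple[float, float],
                         baseline_window: tuple[float, float]
                         ) -> tuple[np.ndarray, np.ndarray]:
    tuning = events.select(block="tuning", condition=Condition.TUNING)
    if len(tuning) == 0:
        raise ValueError("no tuning trials in the event table")
    df = tuning.to_frame()
    sfs = np.sort(df["sf_cpd"].unique())
    rates = np.empty(sfs.size)
    for i, sf in enumerate(sfs):
        onsets = df.loc[np.isclose(df["sf_cpd"], sf), "onset_s"].to_numpy()
        evoked = epoch_rates(spike_times_s, onsets, window)
        base = epoch_rates(spike_times_s, onsets, baseline_window)
        rates[i] = float(np.mean(evoked) - np.mean(base))
    return sfs, rates


def tuning_curve(spike_times_s, events: StimulusSequence,
                 window: tuple[float, float] = EARLY_WINDOW_S,
                 baseline_window: tuple[float, float] = BASELINE_WINDOW_S,
                 n_bands: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtracted mean rate per SF band in the early window.

    Returns ``(sf_cpd, rate_hz)`` with one point per band, SF ascending.
    Raises if any of the expected bands is missing from the event table.
    """
    sfs, rates = _mean_rates_per_band(spike_times_s, events, window,
                                      baseline_window)
    if sfs.size != n_bands:
        raise ValueError(f"expected {n_bands} SF bands, found {sfs.size}")
    return sfs, rates


def late_response(spike_times_s, events: StimulusSequence,
                  window: tuple[float, float] = LATE_WINDOW_S,
                  baseline_window: tuple[float, float] = BASELINE_WINDOW_S,
                  n_bands: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """As :func:`tuning_curve` but over the late (0.2-0.5 s) window."""
    return tuning_curve(spike_times_s, events, window, baseline_window,
                        n_bands)


def fit_dog(sf_cpd, rate_hz, n_restarts: int = 9, seed: int = 0) -> DoGFit:
    """Fit the seven-parameter DoG model to one tuning curve.

    Bounded nonlinear least squares starting from the canonical init (all
    parameters 0.01) plus ``n_restarts`` jittered restarts; the fit with the
    smallest error is kept.  Bounds: widths in [0, 1] cpd, all other
    parameters in [0, 2 * max(rate)].  The curve is normalized by its
    maximum before fitting (amplitudes rescaled afterwards), which makes
    the whole procedure exactly equivariant under rate scaling.  A curve
    with no positive response (max <= 0) or zero variance is degenerate:
    the fit is marked unconverged / ``fit_error = inf``.
    """
    x = np.asarray(sf_cpd, dtype=float)
    y_raw = np.asarray(rate_hz, dtype=float)
    ymax = float(np.max(y_raw))
    if ymax <= 0:
        return DoGFit(*np.full(7, np.nan), np.inf, False, np.nan, None)
    y = y_raw / ymax
    lo = np.zeros(7)
    hi = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 1.0, 1.0])
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    def residual(p):
        return dog_model(x, *p) - y

    def jacobian(p):
        r0, ke, ki, mu_e, mu_i, se, si = p
        ge = np.exp(-((x - mu_e) ** 2) / (2.0 * se ** 2 + 1e-300))
        gi = np.exp(-((x - mu_i) ** 2) / (2.0 * si ** 2 + 1e-300))
        J = np.empty((x.size, 7))
        J[:, 0] = 1.0
        J[:, 1] = ge
        J[:, 2] = -gi
        J[:, 3] = ke * ge * (x - mu_e) / (se ** 2 + 1e-300)
        J[:, 4] = -ki * gi * (x - mu_i) / (si ** 2 + 1e-300)
        J[:, 5] = ke * ge * (x - mu_e) ** 2 / (se ** 3 + 1e-300)
        J[:, 6] = -ki * gi * (x - mu_i) ** 2 / (si ** 3 + 1e-300)
        return J

    rng = np.random.default_rng(seed)
    inits = [np.full(7, 0.01)]
    for _ in range(n_restarts):
        p = rng.uniform(0.0, 1.0, size=7) * np.array([1.0, 1.5, 1.0,
                                                      0.5, 0.5, 0.3, 0.3])
        inits.append(np.clip(p, lo, hi))

    best = None
    best_ss = np.inf
    for p0 in inits:
        try:
            res = optimize.least_squares(residual, np.clip(p0, lo, hi),
                                         jac=jacobian, bounds=(lo, hi),
                                         method="trf", max_nfev=400)
        except Exception:
            continue
        ss = float(np.sum(res.fun ** 2))
        if ss < best_ss:
            best, best_ss = res, ss
        if ss_tot > 1e-12 and best_ss / ss_tot < 1e-3:
            break  # essentially perfect fit; restarts cannot improve group labels

    if best is None:
        return DoGFit(*np.full(7, np.nan), np.inf, False, np.nan, None)

    fit_error = best_ss / ss_tot if ss_tot > 1e-12 else np.inf
    # undo the normalization: amplitudes scale back, centers/widths are cpd
    p = best.x.copy()
    p[:3] *= ymax
    params = tuple(float(v) for v in p)
    curve = dog_model(PREF_SF_GRID_CPD, *params)
    pref = float(PREF_SF_GRID_CPD[int(np.argmax(curve))])
    fit = DoGFit(*params, float(fit_error), True, pref, None)
    fit.q_factor = q_factor(fit)
    return fit


def q_factor(fit: DoGFit, search_range: tuple[float, float] = (0.001, 1.0)
             ) -> float | None:
    """Quality factor Q = SF_peak / (SF_high - SF_low).

    SF_low and SF_high are the spatial frequencies flanking the preferred SF
    at which the baseline-subtracted fitted curve first drops to half its
    peak amplitude.  Returns ``None`` (undefined) when either crossing is
    not bracketed inside ``search_range`` or the peak is not positive.
    """
    if not fit.converged or not np.isfinite(fit.pref_sf_cpd):
        return None

    def g(sf):
        return fit.predict(sf) - fit.r0

    peak_sf = fit.pref_sf_cpd
    peak = float(g(peak_sf))
    if peak <= 0:
        return None
    half = peak / 2.0

    def crossing(a: float, b: float) -> float | None:
        fa, fb = g(a) - half, g(b) - half
        if fa * fb > 0:
            return None
        return float(optimize.brentq(lambda s: g(s) - half, a, b,
                                     xtol=1e-10))

    lo = crossing(search_range[0], peak_sf)
    hi = crossing(peak_sf, search_range[1])
    if lo is None or hi is None or hi <= lo:
        return None
    return peak_sf / (hi - lo)


def assign_tuning_group(fit: DoGFit) -> str:
    """Split a unit into ``tuned_in`` / ``tuned_out`` / ``untuned``.

    Untuned: the fit failed or its error exceeds 0.9.  Tuned_in: preferred
    SF strictly inside (0.015, 0.06) cpd, i.e. within one octave of the
    0.03 cpd oddball SF; everything else (boundary values included) is
    tuned_out.
    """
    if (not fit.converged or not np.isfinite(fit.fit_error)
            or fit.fit_error > FIT_ERROR_UNTUNED):
        return "untuned"
    lo, hi = TUNED_IN_RANGE_CPD
    if lo < fit.pref_sf_cpd < hi:
        return "tuned_in"
    return "tuned_out"
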