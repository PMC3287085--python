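"""Pulsatile inlet waveform as a truncated Fourier series.

The inlet boundary condition is the cross-section *mean* velocity v(t),
represented as

    v(t) = a0 + sum_k a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T)

fitted by least squares to sampled control points.  The packaged default is
a smooth two-feature coronary-like waveform with its systolic peak at
t = 0.4 s and a secondary diastolic feature near t = 0.7 s in a 1.0 s cycle;
its control-point table is a synthetic fixture (no tabulated physiological
recording is bundled), and its amplitude is a tuning constant chosen so the
spatial peak of the parabolic inlet profile at peak systole is ~17 mm/s,
which keeps model velocities in a 0–30 mm/s display range.

A user-supplied waveform can be loaded from a two-column CSV of
(time_seconds, velocity_m_per_s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Waveform",
    "fit_fourier",
    "default_waveform",
    "inlet_profile",
    "load_waveform_csv",
    "save_waveform_csv",
]

#: target spatial-peak inlet velocity at peak systole, m/s (tuning constant)
PEAK_INLET_VELOCITY = 0.017
#: peak/mean ratio of the parabolic (plane Poiseuille) inlet profile
PARABOLIC_PEAK_FACTOR = 1.5

DEFAULT_HARMONICS = 8


@dataclass(frozen=True)
class Waveform:
    """T-periodic mean-velocity waveform (m/s)."""

    period: float
    a0: float
    a: np.ndarray  # cosine coefficients, shape (K,)
    b: np.ndarray  # sine coefficients, shape (K,)
    fit_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if len(self.a) != len(self.b):
            raise ValueError("coefficient arrays must have equal length")

    @property
    def harmonics(self) -> int:
        return len(self.a)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi / self.period
        k = np.arange(1, self.harmonics + 1)
        phase = np.multiply.outer(t, k) * w
        v = self.a0 + np.cos(phase) @ self.a + np.sin(phase) @ self.b
        return float(v) if t.ndim == 0 else v

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(period=self.period, a0=self.a0 * factor,
                        a=self.a * factor, b=self.b * factor,
                        fit_rms=self.fit_rms * abs(factor))

    def peak(self, dt: float = 1e-3) -> tuple[float, float]:
        """(time, value) of the global maximum on a dt grid over one period."""
        t = np.arange(0.0, self.period, dt)
        v = self(t)
        i = int(np.argmax(v))
        return float(t[i]), float(v[i])


def fit_fourier(times, values, harmonics: int,
                period: float | None = None) -> Waveform:
    """Least-squares Fourier fit of sampled (t, v) control points.

    Requires at least ``2*harmonics + 1`` samples spanning one period.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if harmonics < 1:
        raise ValueError("need at least one harmonic")
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if len(t) < 2 * harmonics + 1:
        raise ValueError(
            f"underdetermined fit: {len(t)} samples for "
            f"{2 * harmonics + 1} coefficients")
    if period is None:
        period = float(t.max() - t.min())
        # samples on a uniform open grid [0, T) end one step short of T
        if len(t) > 2:
            period += float(np.median(np.diff(np.sort(t))))
    w = 2.0 * np.pi / period
    k = np.arange(1, harmonics + 1)
    phase = np.multiply.outer(t, k) * w
    design = np.hstack([np.ones((len(t), 1)), np.cos(phase), np.sin(phase)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = v - design @ coef
    return Waveform(period=period, a0=float(coef[0]),
                    a=coef[1:harmonics + 1].copy(),
                    b=coef[harmonics + 1:].copy(),
                    fit_rms=float(np.sqrt(np.mean(resid ** 2))))


# Control-point table for the default waveform: a synthetic two-feature
# coronary-like cycle (systolic peak at 0.40 s, diastolic feature at 0.70 s,
# period 1.0 s), in arbitrary units before amplitude scaling.
def _default_control_points(n: int = 64):
    t = np.arange(n) / n

    def bump(center, width):
        # periodized Gaussian bump
        out = np.zeros_like(t)
        for shift in (-1.0, 0.0, 1.0):
            out += np.exp(-((t - center + shift) / width) ** 2)
        return out

    v = 0.22 + 1.0 * bump(0.40, 0.075) + 0.55 * bump(0.70, 0.085)
    return t, v


def default_waveform(harmonics: int = DEFAULT_HARMONICS) -> Waveform:
    """The packaged pulsatile waveform (period 1.0 s, peak at 0.4 s)."""
    t, v = _default_control_points()
    w = fit_fourier(t, v, harmonics, period=1.0)
    _, vmax = w.peak()
    target_mean_peak = PEAK_INLET_VELOCITY / PARABOLIC_PEAK_FACTOR
    return w.scaled(target_mean_peak / vmax)


def inlet_profile(waveform: Waveform, t: float):
    """Parabolic inlet profile at time ``t``.

    Returns a function of the normalized cross-inlet coordinate xi in [0, 1]
    giving the inflow speed: a plane-Poiseuille shape ``6 v(t) xi (1 - xi)``
    whose spatial mean is v(t), peak 1.5 v(t), and value 0 at both walls.
    """
    v = waveform(t)

    def profile(xi):
        xi = np.asarray(xi, dtype=float)
        return 6.0 * v * xi * (1.0 - xi)

    return profile


def load_waveform_csv(path, harmonics: int = DEFAULT_HARMONICS,
                      period: float | None = None) -> Waveform:
    """Fit a waveform to a CSV of (time_seconds, velocity_m_per_s) rows."""
    data = np.loadtxt(path, delimiter=",", comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("waveform CSV must have two columns: t, v")
    return fit_fourier(data[:, 0], data[:, 1], harmonics, period=period)


def save_waveform_csv(waveform: Waveform, path, dt: float = 1e-3) -> None:
    t = np.arange(0.0, waveform.period, dt)
    np.savetxt(path, np.column_stack([t, waveform(t)]), delimiter=",",
               header="t_seconds,velocity_m_per_s")
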