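"""Exponential response kernels and cumulative training-load convolutions.

Daily training stimuli do not act on performance instantaneously: the acute
response (fatigue-like) decays from the session onward, while structural
adaptations grow over a few days before washing out.  Two fixed transfer
functions encode this:

* the **impulse** kernel, a single exponential decay ``exp(-t / tau_I)``
  with a short time constant (default 3 days), and
* the **serial bi-exponential** kernel, an exponential growth phase
  ``1 - exp(-t / tau_G)`` that hands over to an exponential decay
  ``exp(-(t - TD) / tau_D)`` once the lag reaches the delay ``TD``
  (default ``4 * tau_G``).

Daily series (loads, RPE, power, ...) are convolved with these kernels to
produce exponentially weighted cumulative predictors.  Time constants are
fixed from physiological knowledge, not fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["KernelConfig", "impulse_kernel", "serial_kernel", "convolve_series"]


@dataclass(frozen=True)
class KernelConfig:
    """Fixed time constants of the response kernels, in days.

    Parameters
    ----------
    tau_i : float
        Time constant of the impulse (acute response) kernel.
    tau_g : float
        Growth time constant of the serial bi-exponential kernel.
    tau_d : float
        Decay time constant of the serial bi-exponential kernel.
    td : float or None
        Delay before the decay phase begins; ``None`` means ``4 * tau_g``.
    """

    tau_i: float = 3.0
    tau_g: float = 1.0
    tau_d: float = 7.0
    td: float | None = None

    def __post_init__(self) -> None:
        for name in ("tau_i", "tau_g", "tau_d"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.td is not None and self.td < 0:
            raise ValueError(f"td must be >= 0, got {self.td}")

    @property
    def delay(self) -> float:
        """Onset of the decay branch, TD (defaults to 4*tau_g)."""
        return 4.0 * self.tau_g if self.td is None else self.td


def _check_lag(lag) -> np.ndarray:
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag must be >= 0 days")
    return lag


def impulse_kernel(lag, cfg: KernelConfig = KernelConfig()):
    """Acute-response weight ``exp(-lag / tau_i)`` at a non-negative lag.

    Strictly decreasing in lag, with values in (0, 1].
    """
    lag = _check_lag(lag)
    out = np.exp(-lag / cfg.tau_i)
    return float(out) if out.ndim == 0 else out


def serial_kernel(lag, cfg: KernelConfig = KernelConfig()):
    """Delayed-adaptation weight of the serial bi-exponential kernel.

    Growth branch ``1 - exp(-lag / tau_g)`` for ``lag < TD``; decay branch
    ``exp(-(lag - TD) / tau_d)`` from ``TD`` onward (equal to 1 exactly at
    ``lag == TD``).  Values lie in [0, 1].
    """
    lag = _check_lag(lag)
    growth = 1.0 - np.exp(-lag / cfg.tau_g)
    decay = np.exp(-(lag - cfg.delay) / cfg.tau_d)
    out = np.where(lag < cfg.delay, growth, decay)
    return float(out) if out.ndim == 0 else out


_KERNELS = {"impulse": impulse_kernel, "serial": serial_kernel}


def convolve_series(series, kernel: str = "impulse", cfg: KernelConfig = KernelConfig()):
    """Convolve a daily series with a response kernel.

    ``output(t) = sum_{l=1..t} series(l) * kernel(t - l)`` — the same-day term
    ``l = t`` is included, so the impulse kernel contributes weight 1 and the
    serial kernel weight 0 on the day itself.

    Parameters
    ----------
    series : array-like or pandas.Series
        Daily values on a contiguous day grid.  A pandas Series must carry a
        contiguous integer (day) index; a plain array is taken as days
        ``1..len(series)``.
    kernel : {"impulse", "serial"}
    cfg : KernelConfig

    Returns
    -------
    Same type as the input (Series in, Series out), same length.
    """
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; expected 'impulse' or 'serial'")
    index = None
    if isinstance(series, pd.Series):
        index = series.index
        steps = np.diff(np.asarray(index))
        if len(steps) and not np.all(steps == 1):
            raise ValueError("series index must be a contiguous day grid")
        values = series.to_numpy(dtype=float)
    else:
        values = np.asarray(series, dtype=float)
    if values.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(values)):
        raise ValueError("series contains non-finite values")
    n = len(values)
    if n == 0:
        out = values
    else:
        weights = _KERNELS[kernel](np.arange(n, dtype=float), cfg)
        out = np.convolve(values, weights)[:n]
    if index is not None:
        return pd.Series(out, index=index, name=series.name)
    return out
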