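"""Hill (Naka-Rushton) intensity-response fitting.

The amplitude of the scotopic ERG a- and b-waves grows with flash strength
as a saturating sigmoid,

    V(I) = Vmax * I**n / (k**n + I**n),

where ``Vmax`` is the saturated amplitude (uV), ``k`` the intensity that
evokes half of ``Vmax`` (the semi-saturation constant) and ``n`` the slope
(cooperativity).  Intensities are handled on a log10 scale throughout the
package (log photons um^-2 s^-1) while the fit itself is performed on the
model expressed in linear intensity; ``k`` is reported as ``log10(k)`` to
match the convention used for flash-intensity ladders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np

__all__ = ["HillFit", "OPIntensitySummary", "hill_value", "hill_amplitude_log", "fit_hill", "summarize_op"]


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill fit to one amplitude-vs-intensity series."""

    Vmax_uV: float
    k_log: float
    n_slope: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""

    def predict(self, intensities_log: Sequence[float]) -> np.ndarray:
        """Evaluate the fitted curve at log10 intensities."""
        return hill_amplitude_log(np.asarray(intensities_log, float), self.Vmax_uV, self.k_log, self.n_slope)


@dataclass(frozen=True)
class OPIntensitySummary:
    """OP areas at the two designated comparison intensities.

    The OP area-intensity relation is biphasic, so no sigmoid is fitted;
    instead the area at an intermediate, rod-driven step and at the final,
    mixed rod/cone step are carried forward for group comparison.
    """

    area_at_idx8_uVms: float
    area_at_idx13_uVms: float

    def __post_init__(self) -> None:
        if self.area_at_idx8_uVms < 0 or self.area_at_idx13_uVms < 0:
            raise ValueError("OP areas must be non-negative")


def hill_value(I_linear, Vmax: float, k_linear: float, n: float):
    """Hill function in linear intensity: ``Vmax * I^n / (k^n + I^n)``."""
    I_linear = np.asarray(I_linear, dtype=float)
    if np.any(I_linear < 0):
        raise ValueError("intensity must be >= 0")
    if Vmax <= 0 or k_linear <= 0 or n <= 0:
        raise ValueError("Vmax, k and n must be > 0")
    out = Vmax * I_linear**n / (k_linear**n + I_linear**n)
    return out if out.ndim else float(out)


def hill_amplitude_log(intensity_log, Vmax: float, k_log: float, n: float):
    """Hill function evaluated at log10 intensity, numerically stable.

    Identical to ``hill_value(10**intensity_log, Vmax, 10**k_log, n)`` but
    avoids overflow for large ``n * intensity``.
    """
    intensity_log = np.asarray(intensity_log, dtype=float)
    # V = Vmax / (1 + 10^(n*(k_log - I_log)))
    out = Vmax / (1.0 + 10.0 ** (n * (k_log - intensity_log)))
    return out if out.ndim else float(out)


def _initial_k_log(intensities_log: np.ndarray, amplitudes: np.ndarray) -> float:
    """Half-max crossing of the empirical curve, by linear interpolation."""
    order = np.argsort(intensities_log)
    x, y = intensities_log[order], amplitudes[order]
    half = 0.5 * float(np.max(y))
    above = np.nonzero(y >= half)[0]
    if above.size == 0:
        return float(np.median(x))
    i = int(above[0])
    if i == 0 or y[i] == y[i - 1]:
        return float(x[i])
    frac = (half - y[i - 1]) / (y[i] - y[i - 1])
    return float(x[i - 1] + frac * (x[i] - x[i - 1]))


def fit_hill(intensities_log: Sequence[float], amplitudes_uV: Sequence[float]) -> HillFit:
    """Least-squares Hill fit of an amplitude-vs-intensity series.

    The model is fitted in linear intensity with ``k`` parameterized as
    ``log10(k)``.  Initialization is deterministic: ``Vmax0`` is the largest
    amplitude, ``k0`` the interpolated half-max crossing and ``n0 = 1``; the
    same data always yield the same fit.  Requires >= 4 points with >= 2
    distinct intensities spanning >= 1 log unit.
    """
    x = np.asarray(intensities_log, dtype=float)
    y = np.asarray(amplitudes_uV, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("intensities and amplitudes must be 1-D and equal length")
    if x.size < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter Hill curve")
    if np.unique(x).size < 2 or (x.max() - x.min()) < 1.0:
        raise ValueError("intensities must span at least 1 log unit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite data")

    ymax = float(np.max(y))
    if ymax <= 0:
        return HillFit(np.nan, np.nan, np.nan, float(np.sum(y**2)), False, x.size, "no positive amplitudes")

    # Fit on sorted data so the result is invariant to input order.
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    params = lmfit.Parameters()
    params.add("Vmax", value=ymax, min=1e-12, max=10.0 * ymax)
    params.add("k_log", value=_initial_k_log(xs, ys), min=float(x.min()) - 2.0, max=float(x.max()) + 2.0)
    params.add("n", value=1.0, min=0.1, max=5.0)

    def residual(p):
        return hill_amplitude_log(xs, p["Vmax"].value, p["k_log"].value, p["n"].value) - ys

    result = lmfit.minimize(residual, params, method="leastsq")
    ok = bool(result.success)
    p = result.params
    return HillFit(
        Vmax_uV=float(p["Vmax"].value),
        k_log=float(p["k_log"].value),
        n_slope=float(p["n"].value),
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        converged=ok,
        n_points=x.size,
        message=str(result.message),
    )


def summarize_op(areas_uVms: Sequence[float], idx_intermediate: int = 8, idx_final: int = 13) -> OPIntensitySummary:
    """Pick the OP areas at the two designated 1-based intensity indices."""
    areas = np.asarray(areas_uVms, dtype=float)
    for idx in (idx_intermediate, idx_final):
        if not (1 <= idx <= areas.size):
            raise ValueError(f"intensity index {idx} outside the available 1..{areas.size} range")
    return OPIntensitySummary(
        area_at_idx8_uVms=float(areas[idx_intermediate - 1]),
        area_at_idx13_uVms=float(areas[idx_final - 1]),
    )
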