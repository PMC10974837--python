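"""Sensor noise model: true readings -> noisy measured sets per variant.

Each measured quantity receives an independent zero-mean Gaussian error
whose standard deviation depends on the sensor class:

* ``u_t`` — absolute (unpaired) temperature reading, degC.  Default
  0.053, from the accuracy figure of a precision analog sensor
  (LMT70-class part).
* ``u_dt`` — differential temperature from a *paired* (bias-calibrated)
  sensor pair, degC.  Default 2*0.0003: after an oil-bath pairing the
  residual error is two sensors' worth of intrinsic output noise.
* ``u_q`` — heat-flux reading, W/m^2.  Default 1.3 (thin-film flux
  sensor plus its ADC chain).
* ``u_h`` — channel heat-transfer coefficient, W/(m^2*K).  Default 0.12
  (0.1 mm thickness tolerance, 1% conductivity tolerance).

The mapping from variant to noisy quantities encodes which readings are
physically independent measurements: e.g. HTp measures T_ss1 absolutely
and dT_ss differentially (fresh draws for each), and the averaging
variants share their differential/flux/k draws across the averaged
equations while each absolute base temperature gets its own draw —
that sharing pattern is what lets averaging reduce variance.

For the TT family the characteristic parameter k = h_s2/h_s1 is treated
as measured: h_s1 and h_s2 are perturbed separately with ``u_h`` and the
ratio of the noisy values is used, so the two coefficients appear as
separate components of the uncertainty budget.  Set
``h_noise_for_tt=False`` for the strict reading in which TT-family
variants carry temperature noise only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .estimators import MeasuredSet, Variant
from .forward import DerivedCoefficients, TrueReadings

__all__ = ["NoiseSpec", "sample_measured_set", "sample_measured_arrays"]

logger = logging.getLogger(__name__)

_SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Standard deviations of the four sensor error classes plus options.

    ``ut_interpretation`` selects how the four values are read:
    ``"gaussian_sd"`` (default) uses them directly as Gaussian SDs;
    ``"uniform_bound"`` treats them as half-widths of uniform error
    bounds and draws with the equivalent SD (value / sqrt(3)).

    ``share_flux_in_htpm`` controls whether HTpm's two averaged
    equations see the same flux draw (default) or independent ones.
    """

    u_t: float = 0.053
    u_dt: float = 2 * 0.0003
    u_q: float = 1.3
    u_h: float = 0.12
    ut_interpretation: str = "gaussian_sd"
    h_noise_for_tt: bool = True
    share_flux_in_htpm: bool = True

    def __post_init__(self) -> None:
        for name in ("u_t", "u_dt", "u_q", "u_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise SD {name!r} must be >= 0")
        if self.ut_interpretation not in ("gaussian_sd", "uniform_bound"):
            raise ValueError(
                "ut_interpretation must be 'gaussian_sd' or 'uniform_bound', "
                f"got {self.ut_interpretation!r}"
            )

    def effective_sds(self) -> tuple[float, float, float, float]:
        """(u_t, u_dt, u_q, u_h) as Gaussian SDs after interpretation."""
        s = 1.0 if self.ut_interpretation == "gaussian_sd" else 1.0 / _SQRT3
        return (self.u_t * s, self.u_dt * s, self.u_q * s, self.u_h * s)

    def zeroed(self) -> "NoiseSpec":
        return replace(self, u_t=0.0, u_dt=0.0, u_q=0.0, u_h=0.0)


def _noisy_k(
    coeffs: DerivedCoefficients,
    u_h: float,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """k = h_s2/h_s1 from separately perturbed coefficients.

    A perturbed h_s1 <= 0 would flip the ratio's sign unphysically; such
    draws (essentially impossible at realistic u_h) are redrawn and
    counted in the log.
    """
    h1 = coeffs.h_s1 + rng.normal(0.0, u_h, n) if u_h > 0 else np.full(n, coeffs.h_s1)
    redraws = 0
    while True:
        bad = h1 <= 0.0
        nbad = int(bad.sum())
        if nbad == 0:
            break
        redraws += nbad
        h1[bad] = coeffs.h_s1 + rng.normal(0.0, u_h, nbad)
    if redraws:
        logger.warning("redrew %d non-positive h_s1 perturbations", redraws)
    h2 = coeffs.h_s2 + rng.normal(0.0, u_h, n) if u_h > 0 else np.full(n, coeffs.h_s2)
    return h2 / h1


def sample_measured_arrays(
    variant: Variant,
    truth: TrueReadings,
    coeffs: DerivedCoefficients,
    noise: NoiseSpec,
    rng: np.random.Generator,
    n: int,
) -> dict[str, np.ndarray]:
    """``n`` independent noisy realizations of a variant's measured set.

    Returns a dict of length-``n`` arrays keyed like
    :data:`~dhfsim.estimators.REQUIRED_QUANTITIES`; the draw order is
    fixed, so a given (seed, variant, n) always yields the same arrays.
    """
    u_t, u_dt, u_q, u_h = noise.effective_sds()
    if not noise.h_noise_for_tt:
        u_h = 0.0

    def temp(x: float) -> np.ndarray:
        return x + rng.normal(0.0, u_t, n) if u_t > 0 else np.full(n, x)

    def diff(x: float) -> np.ndarray:
        return x + rng.normal(0.0, u_dt, n) if u_dt > 0 else np.full(n, x)

    def flux(x: float) -> np.ndarray:
        return x + rng.normal(0.0, u_q, n) if u_q > 0 else np.full(n, x)

    if variant is Variant.HT:
        return {
            "T_ss1": temp(truth.T_ss1),
            "T_ss2": temp(truth.T_ss2),
            "q_1": flux(truth.q_1),
            "q_2": flux(truth.q_2),
        }
    if variant is Variant.HTP:
        return {
            "T_ss1": temp(truth.T_ss1),
            "dT_ss": diff(truth.dT_ss),
            "q_1": flux(truth.q_1),
            "q_2": flux(truth.q_2),
        }
    if variant is Variant.HTPM:
        out = {
            "T_ss1": temp(truth.T_ss1),
            "T_ss2": temp(truth.T_ss2),
            "dT_ss": diff(truth.dT_ss),
            "q_1": flux(truth.q_1),
            "q_2": flux(truth.q_2),
        }
        if not noise.share_flux_in_htpm:
            out["q_1b"] = flux(truth.q_1)
            out["q_2b"] = flux(truth.q_2)
        return out
    if variant is Variant.TT:
        return {
            "T_ss1": temp(truth.T_ss1),
            "T_ss2": temp(truth.T_ss2),
            "T_sa1": temp(truth.T_sa1),
            "T_sa2": temp(truth.T_sa2),
            "k_meas": _noisy_k(coeffs, u_h, rng, n),
        }
    if variant is Variant.TTP:
        return {
            "T_ss1": temp(truth.T_ss1),
            "dT_ss": diff(truth.dT_ss),
            "dT_s1": diff(truth.dT_s1),
            "dT_s2": diff(truth.dT_s2),
            "k_meas": _noisy_k(coeffs, u_h, rng, n),
        }
    if variant is Variant.TTPM:
        return {
            "T_ss1": temp(truth.T_ss1),
            "T_ss2": temp(truth.T_ss2),
            "T_sa1": temp(truth.T_sa1),
            "T_sa2": temp(truth.T_sa2),
            "dT_ss": diff(truth.dT_ss),
            "dT_s1": diff(truth.dT_s1),
            "dT_s2": diff(truth.dT_s2),
            "k_meas": _noisy_k(coeffs, u_h, rng, n),
        }
    raise ValueError(f"unknown variant {variant!r}")


def sample_measured_set(
    variant: Variant,
    truth: TrueReadings,
    coeffs: DerivedCoefficients,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> MeasuredSet:
    """One noisy realization, as a validated :class:`MeasuredSet`."""
    arrays = sample_measured_arrays(variant, truth, coeffs, noise, rng, 1)
    return MeasuredSet(variant=variant, **{k: float(v[0]) for k, v in arrays.items()})
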