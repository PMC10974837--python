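"""First-order (GUM-style) uncertainty budget for each estimator variant.

At a stable operating point the combined standard uncertainty of a CBT
estimate is obtained from a first-order Taylor expansion,

    u_c^2 = sum_x (dCBT_e/dx)^2 * u_x^2 ,

summing over the variant's independent measured components x (absolute
temperatures, differentials, fluxes, channel coefficients), with each
sensitivity coefficient evaluated at the error-free readings.  The
fractional share of component x in the budget is

    ru(x) = (dCBT_e/dx)^2 * u_x^2 / u_c^2 ,

which sums to one and identifies the sensor class that limits the
design.

Sensitivities are provided in closed form (:func:`analytic_partials`)
and, independently, by central finite differences
(:func:`numeric_partials`), which serves as the oracle for the closed
forms.  The channel coefficients h_s1, h_s2 act on the TT-family
estimators only through k = h_s2/h_s1 and are propagated by the chain
rule dk/dh_s1 = -k/h_s1, dk/dh_s2 = 1/h_s1, so they appear as two
separate budget components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .estimators import TAYLOR_COMPONENTS, Variant, evaluate_variant
from .forward import (
    DerivedCoefficients,
    EnvState,
    ProbeConfig,
    TrueReadings,
    derive_channel_coefficients,
    simulate_true_readings,
)
from .noise import NoiseSpec

__all__ = [
    "SingularPointError",
    "UncertaintyBudget",
    "analytic_partials",
    "numeric_partials",
    "combined_uncertainty",
    "compat_share_noise",
]


class SingularPointError(ValueError):
    """The linearization point sits on a vanishing estimator denominator."""


@dataclass(frozen=True)
class UncertaintyBudget:
    """Combined uncertainty (degC) and per-component fractional shares.

    ``ru`` is None when every component uncertainty is zero (the budget
    degenerates and shares are undefined).
    """

    variant: Variant
    u_combined: float
    sensitivities: dict[str, float]
    component_u: dict[str, float]
    ru: Optional[dict[str, float]]


def _denominators(variant: Variant, truth: TrueReadings, k: float) -> None:
    if variant.uses_flux:
        if truth.q_2 - truth.q_1 == 0.0:
            raise SingularPointError("q_2 - q_1 vanishes at the linearization point")
    else:
        if k * truth.dT_s2 - truth.dT_s1 == 0.0:
            raise SingularPointError(
                "k*dT_s2 - dT_s1 vanishes at the linearization point"
            )


def analytic_partials(
    variant: Variant, truth: TrueReadings, coeffs: DerivedCoefficients
) -> dict[str, float]:
    """Closed-form sensitivity coefficients at the error-free point.

    Keys are exactly the variant's independent components
    (:data:`~dhfsim.estimators.TAYLOR_COMPONENTS`); units degC per unit
    of the component.
    """
    k = coeffs.k
    _denominators(variant, truth, k)
    q1, q2 = truth.q_1, truth.q_2
    dss, d1, d2 = truth.dT_ss, truth.dT_s1, truth.dT_s2

    if variant is Variant.HT:
        d = q2 - q1
        return {
            "T_ss1": 1.0 + q1 / d,
            "T_ss2": -q1 / d,
            "q_1": dss * q2 / d**2,
            "q_2": -q1 * dss / d**2,
        }
    if variant is Variant.HTP:
        d = q2 - q1
        return {
            "T_ss1": 1.0,
            "q_1": dss * q2 / d**2,
            "q_2": -q1 * dss / d**2,
            "dT_ss": q1 / d,
        }
    if variant is Variant.HTPM:
        d = q2 - q1
        return {
            "T_ss1": 0.5,
            "T_ss2": 0.5,
            "q_1": dss * q2 / d**2,
            "q_2": -q1 * dss / d**2,
            "dT_ss": (q1 + q2) / (2.0 * d),
        }

    # TT family: f = d1*dss/g with g = k*d2 - d1
    g = k * d2 - d1
    df_dd1 = k * d2 * dss / g**2
    df_dd2 = -k * d1 * dss / g**2
    df_ddss = d1 / g
    df_dk = -d1 * d2 * dss / g**2
    dk_dh1 = -k / coeffs.h_s1
    dk_dh2 = 1.0 / coeffs.h_s1

    if variant is Variant.TT:
        # absolutes enter through d1 = T_ss1-T_sa1, d2 = T_ss2-T_sa2, dss
        return {
            "T_ss1": 1.0 + df_dd1 + df_ddss,
            "T_ss2": df_dd2 - df_ddss,
            "T_sa1": -df_dd1,
            "T_sa2": -df_dd2,
            "h_s1": df_dk * dk_dh1,
            "h_s2": df_dk * dk_dh2,
        }
    if variant is Variant.TTP:
        return {
            "T_ss1": 1.0,
            "dT_ss": df_ddss,
            "dT_s1": df_dd1,
            "dT_s2": df_dd2,
            "h_s1": df_dk * dk_dh1,
            "h_s2": df_dk * dk_dh2,
        }
    if variant is Variant.TTPM:
        return {
            "T_ss1": 0.25,
            "T_ss2": 0.25,
            "T_sa1": 0.25,
            "T_sa2": 0.25,
            "dT_ss": 0.5 + df_ddss,
            "dT_s1": 0.25 + df_dd1,
            "dT_s2": 0.25 + df_dd2,
            "h_s1": df_dk * dk_dh1,
            "h_s2": df_dk * dk_dh2,
        }
    raise ValueError(f"unknown variant {variant!r}")


def _errorfree_inputs(
    variant: Variant, truth: TrueReadings, h_s1: float, h_s2: float
) -> dict[str, float]:
    vals = {
        "T_ss1": truth.T_ss1, "T_ss2": truth.T_ss2,
        "T_sa1": truth.T_sa1, "T_sa2": truth.T_sa2,
        "dT_ss": truth.dT_ss, "dT_s1": truth.dT_s1, "dT_s2": truth.dT_s2,
        "q_1": truth.q_1, "q_2": truth.q_2, "k_meas": h_s2 / h_s1,
    }
    from .estimators import REQUIRED_QUANTITIES

    return {n: vals[n] for n in REQUIRED_QUANTITIES[variant]}


def numeric_partials(
    variant: Variant,
    truth: TrueReadings,
    coeffs: DerivedCoefficients,
    step: float = 1e-6,
) -> dict[str, float]:
    """Central-difference sensitivities; oracle for :func:`analytic_partials`.

    Each component is perturbed by ``step`` times a characteristic scale
    (max of |value| and 1 in the component's unit).  h_s1/h_s2 are
    perturbed physically, re-forming k from the perturbed coefficients.
    """
    _denominators(variant, truth, coeffs.k)
    base = _errorfree_inputs(variant, truth, coeffs.h_s1, coeffs.h_s2)

    def eval_at(h_s1: float, h_s2: float, **overrides: float) -> float:
        vals = _errorfree_inputs(variant, truth, h_s1, h_s2)
        vals.update(overrides)
        return float(evaluate_variant(variant, vals))

    out: dict[str, float] = {}
    for comp in TAYLOR_COMPONENTS[variant]:
        if comp in ("h_s1", "h_s2"):
            x0 = getattr(coeffs, comp)
            h = step * max(abs(x0), 1.0)
            kw1 = {comp: x0 + h}
            kw2 = {comp: x0 - h}
            hi = eval_at(
                kw1.get("h_s1", coeffs.h_s1), kw1.get("h_s2", coeffs.h_s2)
            )
            lo = eval_at(
                kw2.get("h_s1", coeffs.h_s1), kw2.get("h_s2", coeffs.h_s2)
            )
        else:
            x0 = base[comp]
            h = step * max(abs(x0), 1.0)
            hi = eval_at(coeffs.h_s1, coeffs.h_s2, **{comp: x0 + h})
            lo = eval_at(coeffs.h_s1, coeffs.h_s2, **{comp: x0 - h})
        out[comp] = (hi - lo) / (2.0 * h)
    return out


_COMPONENT_CLASS = {
    "T_ss1": "u_t", "T_ss2": "u_t", "T_sa1": "u_t", "T_sa2": "u_t",
    "dT_ss": "u_dt", "dT_s1": "u_dt", "dT_s2": "u_dt",
    "q_1": "u_q", "q_2": "u_q",
    "h_s1": "u_h", "h_s2": "u_h",
}


def combined_uncertainty(
    variant: Variant,
    probe: ProbeConfig,
    env: EnvState,
    noise: NoiseSpec,
) -> UncertaintyBudget:
    """First-order combined uncertainty and component shares at a setpoint.

    Raises :class:`SingularPointError` at T_amb = CBT (or an identical-
    channel probe), where the linearization does not exist.
    """
    coeffs = derive_channel_coefficients(probe)
    truth = simulate_true_readings(coeffs, env)
    sens = analytic_partials(variant, truth, coeffs)

    u_t, u_dt, u_q, u_h = noise.effective_sds()
    if not noise.h_noise_for_tt:
        u_h = 0.0
    u_by_class = {"u_t": u_t, "u_dt": u_dt, "u_q": u_q, "u_h": u_h}
    comp_u = {c: u_by_class[_COMPONENT_CLASS[c]] for c in sens}

    terms = {c: (sens[c] * comp_u[c]) ** 2 for c in sens}
    total = float(np.sqrt(sum(terms.values())))
    ru = {c: t / total**2 for c, t in terms.items()} if total > 0 else None
    return UncertaintyBudget(
        variant=variant,
        u_combined=total,
        sensitivities=sens,
        component_u=comp_u,
        ru=ru,
    )


def compat_share_noise(variant: Variant, base: NoiseSpec = NoiseSpec()) -> NoiseSpec:
    """Effective noise levels reproducing a published share breakdown.

    The uncertainty-share tables published for this probe class are not
    mutually consistent with the datasheet-derived default SDs: back-
    solving the printed HT/HTp shares implies an effective flux SD of
    about 2.39 W/m^2 (vs the 1.3 datasheet value), and the printed TT
    shares imply an effective channel-coefficient SD of about 0.220
    W/(m^2*K) (vs 0.12).  The scaling behind the printed TTp row is not
    recoverable.  These presets exist purely for side-by-side
    comparison of budget *shares*; they are not better estimates of the
    sensors.
    """
    if variant in (Variant.HT, Variant.HTP, Variant.HTPM):
        return replace(base, u_q=2.39)
    if variant is Variant.TT:
        return replace(base, u_h=0.220)
    return base
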