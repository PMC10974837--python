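"""Steady-state lumped thermal model of the blood-skin-probe-air stack.

A dual-heat-flux (DHF) probe presses two adjacent measurement channels
against the skin.  Each channel is a slab of thermally resistive material
(e.g. PDMS) of known conductivity and thickness, instrumented with
temperature sensors on both faces and, in the heat-flux configurations,
a flux sensor at the skin interface.  Because the two channels have
different thermal resistances they carry different fluxes, and the pair
of readings eliminates the unknown skin heat-transfer coefficient from
the core-body-temperature (CBT) estimate.

The model is one-dimensional and algebraic: blood at CBT, a passive skin
layer, the channel slab, and a convective film to ambient air form a
series thermal-resistance chain.  Each layer is summarised by a
heat-transfer coefficient h = k/d (conductivity over thickness,
W/(m^2*K)); the overall coefficient of channel i is the series
combination

    1/h_i = 1/h_t + 1/h_si + 1/h_sa

and the steady-state flux is q_i = h_i * (CBT - T_amb).  All readings
are affine in the driving gradient (CBT - T_amb), so temperatures may be
kept in degrees Celsius throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = [
    "ConfigurationError",
    "ProbeConfig",
    "DerivedCoefficients",
    "EnvState",
    "TrueReadings",
    "derive_channel_coefficients",
    "simulate_true_readings",
    "single_flux_estimate",
]


class ConfigurationError(ValueError):
    """A probe/environment parameter is physically inadmissible."""


@dataclass(frozen=True)
class ProbeConfig:
    """Geometry and material description of the two-channel probe.

    Lengths are in metres; use :meth:`from_mm` for the millimetre
    convention used on sensor datasheets.  Defaults describe a PDMS
    probe with 15 mm / 30 mm channels on 2.5 mm of skin under natural
    convection.

    Attributes
    ----------
    k_s1, k_s2 : float
        Thermal conductivity of the channel material, W/(m*K).
    d_s1, d_s2 : float
        Channel slab thickness, m.
    k_t : float
        Skin thermal conductivity, W/(m*K).
    d_t : float
        Skin thickness, m.
    h_sa : float
        Sensor-air convection coefficient, W/(m^2*K); applied
        identically to both channels.
    """

    k_s1: float = 0.15
    k_s2: float = 0.15
    d_s1: float = 0.015
    d_s2: float = 0.030
    k_t: float = 0.37
    d_t: float = 0.0025
    h_sa: float = 6.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ConfigurationError(
                    f"probe parameter {f.name!r} must be strictly positive, got {v!r}"
                )

    @classmethod
    def from_mm(
        cls,
        *,
        k_s1: float = 0.15,
        k_s2: float = 0.15,
        d_s1_mm: float = 15.0,
        d_s2_mm: float = 30.0,
        k_t: float = 0.37,
        d_t_mm: float = 2.5,
        h_sa: float = 6.1,
    ) -> "ProbeConfig":
        """Build a config from thicknesses given in millimetres."""
        return cls(
            k_s1=k_s1,
            k_s2=k_s2,
            d_s1=d_s1_mm * 1e-3,
            d_s2=d_s2_mm * 1e-3,
            k_t=k_t,
            d_t=d_t_mm * 1e-3,
            h_sa=h_sa,
        )


@dataclass(frozen=True)
class DerivedCoefficients:
    """Per-layer and overall heat-transfer coefficients, W/(m^2*K).

    ``k`` is the dimensionless characteristic probe parameter
    h_s2/h_s1 — the only probe property entering the temperature-only
    estimators.  ``k != 1`` is what makes the probe a usable DHF pair.
    """

    h_t: float
    h_s1: float
    h_s2: float
    h_sa: float
    h_1: float
    h_2: float
    k: float


@dataclass(frozen=True)
class EnvState:
    """Thermal environment: core body temperature and ambient air, degC."""

    cbt: float = 37.0
    t_amb: float = 25.0


@dataclass(frozen=True)
class TrueReadings:
    """Error-free steady-state sensor values for one probe/environment.

    ``q_i`` in W/m^2; temperatures in degC.  ``dT_ss = T_ss1 - T_ss2``
    (skin-side inter-channel differential), ``dT_si = T_ssi - T_sai``
    (across-slab differential of channel i).
    """

    q_1: float
    q_2: float
    T_ss1: float
    T_ss2: float
    T_sa1: float
    T_sa2: float
    dT_ss: float
    dT_s1: float
    dT_s2: float


def derive_channel_coefficients(probe: ProbeConfig) -> DerivedCoefficients:
    """Reduce a probe geometry to layer and overall coefficients.

    Each layer's coefficient is conductivity/thickness; the overall
    channel coefficient is the series combination with the skin and the
    convective film.
    """
    h_t = probe.k_t / probe.d_t
    h_s1 = probe.k_s1 / probe.d_s1
    h_s2 = probe.k_s2 / probe.d_s2
    h_1 = 1.0 / (1.0 / h_t + 1.0 / h_s1 + 1.0 / probe.h_sa)
    h_2 = 1.0 / (1.0 / h_t + 1.0 / h_s2 + 1.0 / probe.h_sa)
    return DerivedCoefficients(
        h_t=h_t, h_s1=h_s1, h_s2=h_s2, h_sa=probe.h_sa, h_1=h_1, h_2=h_2,
        k=h_s2 / h_s1,
    )


def simulate_true_readings(coeffs: DerivedCoefficients, env: EnvState) -> TrueReadings:
    """Error-free readings for a probe in a given thermal environment.

    Per channel i: ``q_i = h_i*(CBT - T_amb)``, skin-side surface
    ``T_ssi = CBT - q_i/h_t``, air-side surface
    ``T_sai = T_ssi - q_i/h_si``.  When T_amb equals CBT every flux is
    zero and all surfaces sit at CBT — the singular operating point of
    every DHF estimator.
    """
    grad = env.cbt - env.t_amb
    q_1 = coeffs.h_1 * grad
    q_2 = coeffs.h_2 * grad
    t_ss1 = env.cbt - q_1 / coeffs.h_t
    t_ss2 = env.cbt - q_2 / coeffs.h_t
    t_sa1 = t_ss1 - q_1 / coeffs.h_s1
    t_sa2 = t_ss2 - q_2 / coeffs.h_s2
    return TrueReadings(
        q_1=q_1, q_2=q_2,
        T_ss1=t_ss1, T_ss2=t_ss2, T_sa1=t_sa1, T_sa2=t_sa2,
        dT_ss=t_ss1 - t_ss2, dT_s1=t_ss1 - t_sa1, dT_s2=t_ss2 - t_sa2,
    )


def single_flux_estimate(t_ss: float, q: float, h_t: float) -> float:
    """Single-channel CBT estimate ``T_ss + q/h_t``.

    Requires the (in practice unknown) skin coefficient ``h_t``; the
    DHF estimators exist to remove this dependence.
    """
    if not (h_t > 0):
        raise ConfigurationError(f"h_t must be strictly positive, got {h_t!r}")
    return t_ss + q / h_t
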