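"""The six dual-heat-flux CBT estimator variants.

Two sensor families exist.  HT-family probes measure heat flux directly
(flux sensor + skin-side temperature sensor per channel); TT-family
probes infer flux from the temperature drop across the channel slab and
need only four temperature sensors plus the characteristic probe
parameter k = h_s2/h_s1.

Within each family:

* the base variant (``HT``, ``TT``) uses unpaired absolute temperature
  readings;
* the "p" variant (``HTp``, ``TTp``) measures inter-sensor temperature
  *differences* with a calibrated (paired) sensor pair, whose
  differential uncertainty is orders of magnitude below the absolute
  one;
* the "pm" variant additionally averages the algebraically equivalent
  re-expressions of the estimate anchored on each available absolute
  sensor (two forms for HTpm, four for TTpm), which decorrelates the
  absolute-sensor noise and reduces variance.

All variants share the same singular denominator structure: they divide
by q_2 - q_1 (HT family) or k*dT_s2 - dT_s1 (TT family), both of which
vanish when T_amb = CBT or when the two channels are identical.  A zero
denominator yields a non-finite estimate (flagged, never raised): the
blow-up near the singular point is physically meaningful behaviour.

Estimator kernels accept numpy arrays so that Monte Carlo repetitions
evaluate vectorized; the public scalar API wraps the same kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Union

import numpy as np

__all__ = [
    "Variant",
    "MeasuredSet",
    "CBTEstimate",
    "UndefinedEstimateError",
    "REQUIRED_QUANTITIES",
    "TAYLOR_COMPONENTS",
    "skin_coefficient_estimate",
    "estimate_cbt",
    "evaluate_variant",
]

ArrayLike = Union[float, np.ndarray]


class Variant(str, Enum):
    """Estimator variant identifier (sensor family x pairing x averaging)."""

    HT = "HT"
    HTP = "HTp"
    HTPM = "HTpm"
    TT = "TT"
    TTP = "TTp"
    TTPM = "TTpm"

    @classmethod
    def parse(cls, label: str) -> "Variant":
        for v in cls:
            if v.value.lower() == label.lower():
                return v
        raise ValueError(
            f"unknown variant {label!r}; expected one of "
            f"{[v.value for v in cls]}"
        )

    @property
    def uses_flux(self) -> bool:
        return self in (Variant.HT, Variant.HTP, Variant.HTPM)


#: Measured quantities each variant's equations consume.
REQUIRED_QUANTITIES: dict[Variant, frozenset[str]] = {
    Variant.HT: frozenset({"T_ss1", "T_ss2", "q_1", "q_2"}),
    Variant.HTP: frozenset({"T_ss1", "dT_ss", "q_1", "q_2"}),
    Variant.HTPM: frozenset({"T_ss1", "T_ss2", "dT_ss", "q_1", "q_2"}),
    Variant.TT: frozenset({"T_ss1", "T_ss2", "T_sa1", "T_sa2", "k_meas"}),
    Variant.TTP: frozenset({"T_ss1", "dT_ss", "dT_s1", "dT_s2", "k_meas"}),
    Variant.TTPM: frozenset(
        {"T_ss1", "T_ss2", "T_sa1", "T_sa2", "dT_ss", "dT_s1", "dT_s2", "k_meas"}
    ),
}

#: Independent uncertainty components entering the first-order budget,
#: in reporting order.  h_s1/h_s2 act through k for the TT family.
TAYLOR_COMPONENTS: dict[Variant, tuple[str, ...]] = {
    Variant.HT: ("T_ss1", "T_ss2", "q_1", "q_2"),
    Variant.HTP: ("T_ss1", "q_1", "q_2", "dT_ss"),
    Variant.HTPM: ("T_ss1", "T_ss2", "q_1", "q_2", "dT_ss"),
    Variant.TT: ("T_ss1", "T_ss2", "T_sa1", "T_sa2", "h_s1", "h_s2"),
    Variant.TTP: ("T_ss1", "dT_ss", "dT_s1", "dT_s2", "h_s1", "h_s2"),
    Variant.TTPM: (
        "T_ss1", "T_ss2", "T_sa1", "T_sa2",
        "dT_ss", "dT_s1", "dT_s2", "h_s1", "h_s2",
    ),
}


class UndefinedEstimateError(ValueError):
    """An estimator denominator is exactly zero where an exception is due."""


@dataclass(frozen=True)
class MeasuredSet:
    """One realization of the variant-specific measured quantities.

    Exactly the quantities required by ``variant`` must be set (see
    :data:`REQUIRED_QUANTITIES`).  ``q_1b``/``q_2b`` are an optional
    second, independent flux draw consumed only by HTpm when flux noise
    is not shared between its two averaged equations.
    """

    variant: Variant
    T_ss1: Optional[float] = None
    T_ss2: Optional[float] = None
    T_sa1: Optional[float] = None
    T_sa2: Optional[float] = None
    dT_ss: Optional[float] = None
    dT_s1: Optional[float] = None
    dT_s2: Optional[float] = None
    q_1: Optional[float] = None
    q_2: Optional[float] = None
    k_meas: Optional[float] = None
    q_1b: Optional[float] = None
    q_2b: Optional[float] = None

    def __post_init__(self) -> None:
        required = REQUIRED_QUANTITIES[self.variant]
        quantities = {
            "T_ss1", "T_ss2", "T_sa1", "T_sa2",
            "dT_ss", "dT_s1", "dT_s2", "q_1", "q_2", "k_meas",
        }
        present = {n for n in quantities if getattr(self, n) is not None}
        if present != required:
            missing = sorted(required - present)
            extra = sorted(present - required)
            raise UndefinedEstimateError(
                f"measured set does not match variant {self.variant.value}: "
                f"missing {missing}, unexpected {extra}"
            )
        if (self.q_1b is None) != (self.q_2b is None):
            raise UndefinedEstimateError("q_1b and q_2b must be set together")
        if self.q_1b is not None and self.variant is not Variant.HTPM:
            raise UndefinedEstimateError(
                "second flux draw (q_1b/q_2b) is only meaningful for HTpm"
            )

    def values(self) -> dict[str, float]:
        """The present quantities as a plain dict (kernel input)."""
        out = {n: getattr(self, n) for n in REQUIRED_QUANTITIES[self.variant]}
        if self.q_1b is not None:
            out["q_1b"] = self.q_1b
            out["q_2b"] = self.q_2b
        return out


@dataclass(frozen=True)
class CBTEstimate:
    """A CBT estimate in degC; ``finite`` is False iff a denominator vanished."""

    value: float
    variant: Variant
    finite: bool


def skin_coefficient_estimate(
    q_1: float, q_2: float, t_ss1: float, t_ss2: float
) -> float:
    """Skin heat-transfer coefficient from the two channels' readings.

    Eliminating h_t between the two single-channel balance equations
    CBT = T_ssi + q_i/h_t gives ``h_t = (q_1 - q_2)/(T_ss2 - T_ss1)``
    (the hotter channel carries more flux and leaves a cooler skin
    surface, so the ratio is positive).  This elimination is the
    algebraic heart of the DHF method; the estimate equals the true h_t
    exactly on error-free readings.
    """
    dt = t_ss2 - t_ss1
    if dt == 0.0:
        raise UndefinedEstimateError(
            "skin coefficient undefined: T_ss1 == T_ss2 (zero denominator)"
        )
    return (q_1 - q_2) / dt


def _safe_div(num: ArrayLike, den: ArrayLike) -> np.ndarray:
    """Elementwise num/den with exact-zero denominators mapped to NaN.

    No epsilon clipping: near-singular amplification must be preserved,
    since the blow-up magnitudes near T_amb = CBT are part of the
    physics under study.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0.0, np.nan, num) / np.where(den == 0.0, 1.0, den)
    return out


def evaluate_variant(variant: Variant, v: Mapping[str, ArrayLike]) -> np.ndarray:
    """Vectorized estimator kernel over a mapping of measured quantities.

    ``v`` holds scalars or equally-shaped arrays for the quantities in
    :data:`REQUIRED_QUANTITIES` (plus optionally ``q_1b``/``q_2b`` for
    HTpm).  Returns the estimate array; singular draws come back NaN.
    """
    if variant is Variant.HT:
        d = np.asarray(v["q_2"], float) - np.asarray(v["q_1"], float)
        return v["T_ss1"] + _safe_div(
            np.asarray(v["q_1"], float) * (np.asarray(v["T_ss1"], float) - v["T_ss2"]),
            d,
        )
    if variant is Variant.HTP:
        d = np.asarray(v["q_2"], float) - np.asarray(v["q_1"], float)
        return v["T_ss1"] + _safe_div(np.asarray(v["q_1"], float) * v["dT_ss"], d)
    if variant is Variant.HTPM:
        q1a, q2a = v["q_1"], v["q_2"]
        q1b, q2b = v.get("q_1b", q1a), v.get("q_2b", q2a)
        da = np.asarray(q2a, float) - np.asarray(q1a, float)
        db = np.asarray(q2b, float) - np.asarray(q1b, float)
        e1 = v["T_ss1"] + _safe_div(np.asarray(q1a, float) * v["dT_ss"], da)
        e2 = v["T_ss2"] + _safe_div(np.asarray(q2b, float) * v["dT_ss"], db)
        return 0.5 * (e1 + e2)
    if variant is Variant.TT:
        d1 = np.asarray(v["T_ss1"], float) - v["T_sa1"]
        d2 = np.asarray(v["T_ss2"], float) - v["T_sa2"]
        dss = np.asarray(v["T_ss1"], float) - v["T_ss2"]
        g = np.asarray(v["k_meas"], float) * d2 - d1
        return v["T_ss1"] + _safe_div(d1 * dss, g)
    if variant is Variant.TTP:
        g = np.asarray(v["k_meas"], float) * v["dT_s2"] - np.asarray(v["dT_s1"], float)
        return v["T_ss1"] + _safe_div(
            np.asarray(v["dT_s1"], float) * v["dT_ss"], g
        )
    if variant is Variant.TTPM:
        dss = np.asarray(v["dT_ss"], float)
        d1 = np.asarray(v["dT_s1"], float)
        d2 = np.asarray(v["dT_s2"], float)
        g = np.asarray(v["k_meas"], float) * d2 - d1
        f = _safe_div(d1 * dss, g)  # shared correction term, computed once
        e1 = v["T_ss1"] + f
        e2 = v["T_ss2"] + dss + f
        e3 = v["T_sa1"] + d1 + f
        e4 = v["T_sa2"] + dss + d2 + f
        return 0.25 * (e1 + e2 + e3 + e4)
    raise ValueError(f"unknown variant {variant!r}")


def estimate_cbt(variant: Variant, m: MeasuredSet) -> CBTEstimate:
    """Apply one estimator variant to one measured realization.

    A vanishing denominator produces a non-finite estimate with
    ``finite=False`` rather than an exception; a measured set whose
    quantities do not match the variant raises
    :class:`UndefinedEstimateError` at construction.
    """
    if m.variant is not variant:
        raise UndefinedEstimateError(
            f"measured set built for {m.variant.value}, requested {variant.value}"
        )
    value = float(evaluate_variant(variant, m.values()))
    return CBTEstimate(value=value, variant=variant, finite=math.isfinite(value))
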