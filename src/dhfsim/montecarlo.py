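"""Monte Carlo uncertainty estimation and the parameter-sweep experiments.

One MC *trial* fixes the probe and environment, simulates the
error-free readings once, draws ``n_reps`` noisy measured sets, applies
the estimator, and reports the sample standard deviation of the
estimation errors (estimate minus true CBT).  Repeating the trial
``n_trials`` times on independent substreams yields

* ``mu_cbt`` — the mean of the per-trial SDs: the MC prediction of the
  standard uncertainty of the CBT estimate;
* ``su_cbt`` — the SD of the per-trial SDs: the repeatability of the MC
  prediction itself, usable as a confidence measure on ``mu_cbt``.

Non-finite estimates (singular denominators) are never dropped: they
propagate into the trial SD and are counted, because the blow-up near
T_amb = CBT and near identical channels is a finding, not an artifact.

Five sweep experiments vary one setup parameter at a time: ambient
temperature, CBT, the channel-coefficient pair at fixed ratio, the
channel-coefficient ratio at fixed h_s1, and the convective film
coefficient h_sa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .estimators import Variant, evaluate_variant
from .forward import (
    EnvState,
    ProbeConfig,
    derive_channel_coefficients,
    simulate_true_readings,
)
from .noise import NoiseSpec, sample_measured_arrays

__all__ = [
    "MCResult",
    "SweepSpec",
    "RESULT_COLUMNS",
    "run_mc_trial",
    "estimate_uncertainty",
    "build_sweep_grid",
    "run_sweep",
    "experiment_spec",
    "EXPERIMENTS",
]

SeedLike = Union[int, np.random.SeedSequence]

#: Column order of the tidy result table produced by :func:`run_sweep`.
RESULT_COLUMNS = (
    "variant", "parameter", "value",
    "mu_cbt", "su_cbt", "n_reps", "n_trials", "seed", "nonfinite_count",
)


@dataclass(frozen=True)
class MCResult:
    """Monte Carlo uncertainty estimate for one variant at one setpoint."""

    variant: Variant
    mu_cbt: float
    su_cbt: float
    n_reps: int
    n_trials: int
    seed: int
    nonfinite_count: int


def run_mc_trial(
    variant: Variant,
    probe: ProbeConfig,
    env: EnvState,
    noise: NoiseSpec,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """One MC trial: sample SD (ddof=1) of ``n_reps`` estimation errors.

    Returns ``(sd, nonfinite_count)``.  Non-finite estimates make the
    SD non-finite rather than being excluded.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a sample standard deviation")
    coeffs = derive_channel_coefficients(probe)
    truth = simulate_true_readings(coeffs, env)
    vals = sample_measured_arrays(variant, truth, coeffs, noise, rng, n_reps)
    est = evaluate_variant(variant, vals)
    errors = est - env.cbt
    nonfinite = int(np.count_nonzero(~np.isfinite(est)))
    return float(np.std(errors, ddof=1)), nonfinite


def estimate_uncertainty(
    variant: Variant,
    probe: ProbeConfig,
    env: EnvState,
    noise: NoiseSpec,
    n_reps: int = 10_000,
    n_trials: int = 100,
    seed: SeedLike = 0,
) -> MCResult:
    """Full MC procedure: ``n_trials`` independent trials of ``n_reps`` reps.

    Per-trial random streams are spawned deterministically from the
    master seed, so results are bit-for-bit reproducible and trials are
    statistically independent.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sds = np.empty(n_trials)
    nonfinite = 0
    for i, child in enumerate(ss.spawn(n_trials)):
        sd, nf = run_mc_trial(variant, probe, env, noise, n_reps, np.random.default_rng(child))
        sds[i] = sd
        nonfinite += nf
    with np.errstate(invalid="ignore"):
        mu = float(np.mean(sds))
        su = float(np.std(sds, ddof=1))
    seed_repr = ss.entropy if isinstance(ss.entropy, int) else -1
    return MCResult(
        variant=variant, mu_cbt=mu, su_cbt=su,
        n_reps=n_reps, n_trials=n_trials, seed=int(seed_repr),
        nonfinite_count=nonfinite,
    )


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep definition.

    ``parameter`` is one of ``tamb``, ``cbt``, ``hs_pair``, ``hs_ratio``,
    ``hsa``; ``grid`` is the strictly monotone sequence of values it
    takes.  Grid values are interpreted per parameter:

    * ``tamb``/``cbt`` — degC, written into the environment;
    * ``hs_pair`` — channel conductivity k_s1 = k_s2 in W/(m*K) at the
      default thicknesses (so h_s1/h_s2 stays 2);
    * ``hs_ratio`` — target ratio r = h_s1/h_s2, achieved by thickening
      channel 2 while channel 1 stays at its default;
    * ``hsa`` — convective coefficient in W/(m^2*K).
    """

    parameter: str
    grid: tuple[float, ...]

    _PARAMS = ("tamb", "cbt", "hs_pair", "hs_ratio", "hsa")

    def __post_init__(self) -> None:
        if self.parameter not in self._PARAMS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"expected one of {self._PARAMS}"
            )
        g = np.asarray(self.grid, float)
        if g.size < 2 or not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0)):
            raise ValueError("sweep grid must be strictly monotone with >= 2 points")


def build_sweep_grid(
    spec: SweepSpec, base_probe: ProbeConfig, base_env: EnvState
) -> list[tuple[ProbeConfig, EnvState]]:
    """Materialize a sweep as concrete (probe, env) pairs, one per grid value."""
    out: list[tuple[ProbeConfig, EnvState]] = []
    for v in spec.grid:
        if spec.parameter == "tamb":
            out.append((base_probe, replace(base_env, t_amb=float(v))))
        elif spec.parameter == "cbt":
            out.append((base_probe, replace(base_env, cbt=float(v))))
        elif spec.parameter == "hs_pair":
            out.append((replace(base_probe, k_s1=float(v), k_s2=float(v)), base_env))
        elif spec.parameter == "hs_ratio":
            # h_s1 fixed at its base value; h_s2 = h_s1/r via channel-2 thickness
            h_s1 = base_probe.k_s1 / base_probe.d_s1
            d_s2 = base_probe.k_s2 * float(v) / h_s1
            out.append((replace(base_probe, d_s2=d_s2), base_env))
        elif spec.parameter == "hsa":
            out.append((replace(base_probe, h_sa=float(v)), base_env))
    return out


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(np.linspace(start, stop, n))


def experiment_spec(name: str) -> SweepSpec:
    """Named sweep experiments.

    ``e1`` ambient -15..45 degC (0.5 steps); ``e1n`` the narrow
    36.95..37.05 sub-sweep (1 mdegC steps) resolving the paired-variant
    instability; ``e2`` CBT 35..45 (0.25); ``e3`` channel conductivity
    0.01..100 W/(m*K), 60 log-spaced points (h_s1 about 0.67..6667 at
    ratio 2); ``e4`` coefficient ratio 1.25..10000, 60 log-spaced
    points; ``e5`` h_sa 6..104 (steps of 2).
    """
    key = name.lower()
    if key not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; expected one of {sorted(EXPERIMENTS)}")
    return EXPERIMENTS[key]


EXPERIMENTS: dict[str, SweepSpec] = {
    "e1": SweepSpec("tamb", _grid(-15.0, 45.0, 0.5)),
    "e1n": SweepSpec("tamb", _grid(36.95, 37.05, 0.001)),
    "e2": SweepSpec("cbt", _grid(35.0, 45.0, 0.25)),
    "e3": SweepSpec("hs_pair", tuple(np.logspace(math.log10(0.01), math.log10(100.0), 60))),
    "e4": SweepSpec("hs_ratio", tuple(np.logspace(math.log10(1.25), math.log10(10_000.0), 60))),
    "e5": SweepSpec("hsa", _grid(6.0, 104.0, 2.0)),
}

#: Variants the narrow ambient sub-sweep is meaningful for.
NARROW_SWEEP_VARIANTS = (Variant.TTP, Variant.TTPM)


def run_sweep(
    spec: SweepSpec,
    variants: Iterable[Variant],
    probe: ProbeConfig,
    env: EnvState,
    noise: NoiseSpec,
    n_reps: int = 10_000,
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """MC uncertainty for every variant at every grid point.

    Returns a tidy :data:`RESULT_COLUMNS` table, one row per
    (variant, grid point), deterministic under the master seed: each
    cell gets its own spawned substream, so adding variants or points
    does not perturb the others' draws.
    """
    variants = list(variants)
    points = build_sweep_grid(spec, probe, env)
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(variants) * len(points))
    rows = []
    i = 0
    for variant in variants:
        for value, (p, e) in zip(spec.grid, points):
            res = estimate_uncertainty(
                variant, p, e, noise,
                n_reps=n_reps, n_trials=n_trials, seed=children[i],
            )
            i += 1
            rows.append({
                "variant": variant.value,
                "parameter": spec.parameter,
                "value": float(value),
                "mu_cbt": res.mu_cbt,
                "su_cbt": res.su_cbt,
                "n_reps": n_reps,
                "n_trials": n_trials,
                "seed": seed,
                "nonfinite_count": res.nonfinite_count,
            })
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
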