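"""YAML run configuration with strict validation and full defaults.

A run config is a small human-editable YAML file with up to five
blocks — ``probe``, ``env``, ``noise``, ``mc``, ``sweep`` — every key of
which has a physically motivated default, so an empty file is a valid
config describing the default probe.  Unknown keys are rejected rather
than ignored: silent typos in uncertainty studies are expensive.

Probe thicknesses are given in millimetres (the convention of sensor
datasheets) and converted to SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .estimators import Variant
from .forward import ConfigurationError, EnvState, ProbeConfig
from .noise import NoiseSpec

__all__ = ["ConfigError", "MCSettings", "SweepSettings", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Malformed or physically invalid run configuration."""


@dataclass(frozen=True)
class MCSettings:
    n_reps: int = 10_000
    n_trials: int = 100
    seed: int = 0


@dataclass(frozen=True)
class SweepSettings:
    experiment: str = "e1"
    variants: tuple[str, ...] = ("HT", "HTp", "HTpm", "TT", "TTp", "TTpm")


@dataclass(frozen=True)
class RunConfig:
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    env: EnvState = field(default_factory=EnvState)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    mc: MCSettings = field(default_factory=MCSettings)
    sweep: SweepSettings = field(default_factory=SweepSettings)

    def variant_list(self) -> list[Variant]:
        return [Variant.parse(v) for v in self.sweep.variants]

    def echo(self) -> dict[str, Any]:
        """Effective configuration as a plain dict (for logs/manifests)."""
        return {
            "probe": {
                "k_s1": self.probe.k_s1, "k_s2": self.probe.k_s2,
                "d_s1_mm": self.probe.d_s1 * 1e3, "d_s2_mm": self.probe.d_s2 * 1e3,
                "k_t": self.probe.k_t, "d_t_mm": self.probe.d_t * 1e3,
                "h_sa": self.probe.h_sa,
            },
            "env": {"cbt_c": self.env.cbt, "tamb_c": self.env.t_amb},
            "noise": {
                "u_t_c": self.noise.u_t, "u_dt_c": self.noise.u_dt,
                "u_q_wm2": self.noise.u_q, "u_h_wm2k": self.noise.u_h,
                "ut_interpretation": self.noise.ut_interpretation,
                "h_noise_for_tt": self.noise.h_noise_for_tt,
                "share_flux_in_htpm": self.noise.share_flux_in_htpm,
            },
            "mc": {
                "n_reps": self.mc.n_reps, "n_trials": self.mc.n_trials,
                "seed": self.mc.seed,
            },
            "sweep": {
                "experiment": self.sweep.experiment,
                "variants": list(self.sweep.variants),
            },
        }


_PROBE_KEYS = {"k_s1", "k_s2", "d_s1_mm", "d_s2_mm", "k_t", "d_t_mm", "h_sa"}
_ENV_KEYS = {"cbt_c", "tamb_c"}
_NOISE_KEYS = {
    "u_t_c", "u_dt_c", "u_q_wm2", "u_h_wm2k",
    "ut_interpretation", "h_noise_for_tt", "share_flux_in_htpm",
}
_MC_KEYS = {"n_reps", "n_trials", "seed"}
_SWEEP_KEYS = {"experiment", "variants"}


def _check_keys(block: Mapping[str, Any], allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {name!r} block: {sorted(unknown)}")


def _build(data: Mapping[str, Any]) -> RunConfig:
    _check_keys(data, {"probe", "env", "noise", "mc", "sweep"}, "top-level")

    probe_raw = dict(data.get("probe") or {})
    _check_keys(probe_raw, _PROBE_KEYS, "probe")
    try:
        probe = ProbeConfig.from_mm(**probe_raw)
    except (ConfigurationError, TypeError) as exc:
        raise ConfigError(f"invalid probe block: {exc}") from exc

    env_raw = dict(data.get("env") or {})
    _check_keys(env_raw, _ENV_KEYS, "env")
    env = EnvState(
        cbt=float(env_raw.get("cbt_c", 37.0)),
        t_amb=float(env_raw.get("tamb_c", 25.0)),
    )

    noise_raw = dict(data.get("noise") or {})
    _check_keys(noise_raw, _NOISE_KEYS, "noise")
    try:
        noise = NoiseSpec(
            u_t=float(noise_raw.get("u_t_c", 0.053)),
            u_dt=float(noise_raw.get("u_dt_c", 2 * 0.0003)),
            u_q=float(noise_raw.get("u_q_wm2", 1.3)),
            u_h=float(noise_raw.get("u_h_wm2k", 0.12)),
            ut_interpretation=str(noise_raw.get("ut_interpretation", "gaussian_sd")),
            h_noise_for_tt=bool(noise_raw.get("h_noise_for_tt", True)),
            share_flux_in_htpm=bool(noise_raw.get("share_flux_in_htpm", True)),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid noise block: {exc}") from exc

    mc_raw = dict(data.get("mc") or {})
    _check_keys(mc_raw, _MC_KEYS, "mc")
    mc = MCSettings(
        n_reps=int(mc_raw.get("n_reps", 10_000)),
        n_trials=int(mc_raw.get("n_trials", 100)),
        seed=int(mc_raw.get("seed", 0)),
    )
    if mc.n_reps < 2 or mc.n_trials < 2:
        raise ConfigError("mc.n_reps and mc.n_trials must both be >= 2")

    sweep_raw = dict(data.get("sweep") or {})
    _check_keys(sweep_raw, _SWEEP_KEYS, "sweep")
    variants = sweep_raw.get("variants", list(SweepSettings().variants))
    if isinstance(variants, str):
        variants = [v.strip() for v in variants.split(",")]
    for v in variants:
        Variant.parse(v)  # fail early with a clear message
    sweep = SweepSettings(
        experiment=str(sweep_raw.get("experiment", "e1")),
        variants=tuple(variants),
    )
    return RunConfig(probe=probe, env=env, noise=noise, mc=mc, sweep=sweep)


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load and validate a YAML run config; ``None`` means all defaults.

    An empty file yields the default configuration.  Schema violations,
    unknown keys, and non-positive physical parameters raise
    :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text()) or {}
    if not isinstance(data, Mapping):
        raise ConfigError("config root must be a mapping of blocks")
    return _build(data)
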