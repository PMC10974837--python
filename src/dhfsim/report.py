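"""Result serialization and sweep figures.

Sweep results are written as plain CSV (6 significant digits) with a
sibling ``<name>.manifest.json`` capturing the effective configuration
and master seed, so any results file can be regenerated exactly.
Figures are two-panel (mu_cbt / su_cbt vs the swept parameter), one
line per variant, matching how this class of sensitivity study is
usually presented.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .montecarlo import RESULT_COLUMNS

__all__ = ["write_results", "read_results", "render_sweep_figure"]

_AXIS_LABELS = {
    "tamb": "ambient temperature [degC]",
    "cbt": "core body temperature [degC]",
    "hs_pair": "channel conductivity k_s [W/(m K)]",
    "hs_ratio": "coefficient ratio h_s1/h_s2 [-]",
    "hsa": "convective coefficient h_sa [W/(m2 K)]",
}


def write_results(
    table: pd.DataFrame,
    path: Union[str, Path],
    config_echo: Optional[Mapping[str, Any]] = None,
) -> Path:
    """Write a sweep table as CSV plus a JSON provenance manifest."""
    if table.empty:
        raise ValueError("refusing to write an empty result table")
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"result table missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[list(RESULT_COLUMNS)].to_csv(path, index=False, float_format="%.6g")
    manifest = {
        "rows": int(len(table)),
        "seed": int(table["seed"].iloc[0]),
        "parameter": str(table["parameter"].iloc[0]),
        "variants": sorted(table["variant"].unique().tolist()),
        "config": dict(config_echo) if config_echo is not None else None,
    }
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def render_sweep_figure(
    table: pd.DataFrame,
    out: Union[str, Path],
    log_y: bool = True,
    log_x: bool = False,
) -> Path:
    """Two-panel (mu_cbt, su_cbt) figure, one line per variant."""
    if table.empty:
        raise ValueError("cannot render an empty result table")
    parameter = str(table["parameter"].iloc[0])
    xlabel = _AXIS_LABELS.get(parameter, parameter)
    fig, (ax_mu, ax_su) = plt.subplots(1, 2, figsize=(11, 4.2), sharex=True)
    for variant, grp in table.groupby("variant", sort=False):
        grp = grp.sort_values("value")
        ax_mu.plot(grp["value"], grp["mu_cbt"], label=variant, lw=1.2)
        ax_su.plot(grp["value"], grp["su_cbt"], label=variant, lw=1.2)
    for ax, ylab in ((ax_mu, "mu_cbt [degC]"), (ax_su, "su_cbt [degC]")):
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylab)
        if log_y:
            ax.set_yscale("log")
        if log_x:
            ax.set_xscale("log")
        ax.grid(True, which="both", alpha=0.3)
    ax_mu.legend(fontsize=8)
    fig.tight_layout()
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
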