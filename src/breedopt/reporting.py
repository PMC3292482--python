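"""Summaries of sweep outputs: strategy-frequency tables, OSI/DSI gain
ratios and unit conversions.

All functions are pure transformations of the sweep result tables, so the
reports can be regenerated offline from saved CSVs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .index_engine import Trait

__all__ = [
    "STRATEGY_LABELS",
    "classify_strategy",
    "strategy_table",
    "method_ratio",
    "kg_to_genetic_sd",
]

#: display labels for stage combinations (Pd = pedigree-only preselection)
STRATEGY_LABELS = {
    ("PED",): "Pd",
    ("PED", "PPT"): "Pd+PT",
    ("PED", "GS"): "Pd+GS",
    ("PED", "GS", "PPT"): "Pd+GS+PT",
    ("GS",): "GS",
    ("PPT",): "PT",
    ("GS", "PPT"): "GS+PT",
}


def classify_strategy(stages: str | tuple[str, ...]) -> str:
    """Map a path's used stages (tuple or '+'-joined string) to its label."""
    if isinstance(stages, str):
        stages = tuple(s for s in stages.split("+") if s)
    try:
        return STRATEGY_LABELS[tuple(stages)]
    except KeyError:
        raise ValueError(f"unknown stage combination {stages!r}") from None


def strategy_table(
    sweep_df: pd.DataFrame,
    r_bands: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Count, per path and r_GEBV band, how often each stage combination is
    the optimum across the sweep points.

    Within each (path, band, method) the counts sum to the number of sweep
    points in the band.
    """
    if r_bands is None:
        r_bands = [(sweep_df["r_gebv"].min(), sweep_df["r_gebv"].max())]
    rows = []
    for method, mdf in sweep_df.groupby("method"):
        for lo, hi in r_bands:
            band = mdf[(mdf["r_gebv"] >= lo - 1e-9) & (mdf["r_gebv"] <= hi + 1e-9)]
            for path, col in (("SS", "ss_stages"), ("SD", "sd_stages"), ("DS", "ds_stages")):
                counts = band[col].map(classify_strategy).value_counts()
                for strategy, n in counts.items():
                    rows.append({
                        "path_id": path, "r_low": lo, "r_high": hi,
                        "method": method, "strategy": strategy,
                        "count": int(n), "band_points": len(band),
                    })
    return pd.DataFrame(rows).sort_values(
        ["method", "path_id", "r_low", "strategy"]
    ).reset_index(drop=True)


def method_ratio(osi_df: pd.DataFrame, dsi_df: pd.DataFrame) -> pd.DataFrame:
    """Per-point ΔG_a(DSI)/ΔG_a(OSI); sweep grids must match exactly."""
    keys = ["r_gebv", "c_gebv"]
    o = osi_df.sort_values(keys).reset_index(drop=True)
    d = dsi_df.sort_values(keys).reset_index(drop=True)
    if len(o) != len(d) or not np.allclose(o[keys].values, d[keys].values):
        raise ValueError("OSI and DSI sweeps cover different (r, C) points")
    out = o[keys].copy()
    out["delta_g_a_osi"] = o["delta_g_a"].values
    out["delta_g_a_dsi"] = d["delta_g_a"].values
    out["ratio"] = out["delta_g_a_dsi"] / out["delta_g_a_osi"]
    return out


def kg_to_genetic_sd(value_kg: float, trait: Trait) -> float:
    """Express a gain in units of the additive-genetic standard deviation."""
    return value_kg / trait.sigma_a
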