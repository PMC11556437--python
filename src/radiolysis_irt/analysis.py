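"""Yield analysis: G-values, uncertainties, material balance, condition sweeps.

The radiation chemical yield (G-value) of a species is the number of its
molecules present per 100 eV of deposited energy.  The material-balance
diagnostic checks the redox bookkeeping of the whole scheme at a given time:

    G_red = G(e_aq) + 2 G(H2) + G(H)
    G_ox  = G(OH)   + 2 G(H2O2) + 3 G(HO2)

which must agree whenever every reaction and the initial condition conserve
reducing/oxidizing equivalents.  The discrepancy is reported as
|G_red - G_ox| as a percentage of their mean (symmetric and scale invariant).
"""

from __future__ import annotations

import math
from dataclasses import replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .irt import run_ensemble
from .parameters import build_chemical_table
from .results import GValueSeries, MaterialBalanceReport
from .spur import SpurModel

__all__ = [
    "gvalue",
    "material_balance",
    "uncertainty",
    "run_condition",
    "temperature_sweep",
    "ph_sweep",
    "series_to_frame",
    "load_reference",
]

RED_WEIGHTS = {"e_aq": 1.0, "H2": 2.0, "H": 1.0}
OX_WEIGHTS = {"OH": 1.0, "H2O2": 2.0, "HO2": 3.0}


def gvalue(count: float, energy_ev: float) -> float:
    """G = 100 x count / energy(eV): molecules per 100 eV."""
    if energy_ev <= 0:
        raise ValueError("deposited energy must be positive")
    return 100.0 * count / energy_ev


def material_balance(g: dict[str, float]) -> MaterialBalanceReport:
    """Redox balance report from a per-species G map (missing species count as 0)."""
    red_terms = {sp: w * g.get(sp, 0.0) for sp, w in RED_WEIGHTS.items()}
    ox_terms = {sp: w * g.get(sp, 0.0) for sp, w in OX_WEIGHTS.items()}
    g_red = sum(red_terms.values())
    g_ox = sum(ox_terms.values())
    mean = 0.5 * (g_red + g_ox)
    pct = 0.0 if mean == 0 else abs(g_red - g_ox) / mean * 100.0
    return MaterialBalanceReport(
        g_red=g_red, g_ox=g_ox, difference_pct=pct,
        red_terms=red_terms, ox_terms=ox_terms,
    )


def uncertainty(per_run_g: np.ndarray) -> np.ndarray:
    """Between-run standard error of the mean; needs >= 2 runs.

    ``per_run_g`` has the runs on axis 0.
    """
    per_run_g = np.asarray(per_run_g, dtype=float)
    n_runs = per_run_g.shape[0]
    if n_runs < 2:
        raise ValueError("uncertainty estimation needs at least 2 runs")
    return per_run_g.std(axis=0, ddof=1) / math.sqrt(n_runs)


def run_condition(config: RunConfig, model: SpurModel | None = None) -> GValueSeries:
    """Build the chemical table for the config's condition and run the ensemble."""
    model = model or (
        SpurModel.from_yaml(config.spur_model_path)
        if config.spur_model_path
        else SpurModel.default()
    )
    table = build_chemical_table(
        config.temperature_c, config.ph, overrides=config.overrides_path
    )
    return run_ensemble(model, table, config)


def _sweep(
    config: RunConfig,
    conditions: list[tuple[float, float]],
    model: SpurModel | None,
    at_time_us: float,
) -> pd.DataFrame:
    model = model or (
        SpurModel.from_yaml(config.spur_model_path)
        if config.spur_model_path
        else SpurModel.default()
    )
    kind = "temperature" if len({ph for _, ph in conditions}) == 1 else "ph"
    try:
        ref = load_reference()
        ref = ref[(ref.kind == kind) & (ref.quantity == "g_e_aq")]
        ref_map = dict(zip(ref.condition.astype(float), ref.value.astype(float)))
    except OSError:
        ref_map = {}
    rows = []
    for temp, ph in conditions:
        cfg = replace(config, temperature_c=temp, ph=ph)
        series = run_condition(cfg, model)
        g_at = series.at_time(at_time_us)
        se_at = series.stderr_at_time(at_time_us)
        balance = material_balance(g_at)
        cond_key = temp if kind == "temperature" else ph
        for sp in series.species:
            reference = ref_map.get(cond_key) if sp == "e_aq" else None
            rows.append(
                {
                    "temperature_c": temp,
                    "ph": ph,
                    "species": sp,
                    "g_value": g_at[sp],
                    "std_error": se_at[sp],
                    "reference": reference,
                    "pct_diff": (
                        abs(g_at[sp] - reference) / reference * 100.0
                        if reference
                        else None
                    ),
                    "g_red": balance.g_red,
                    "g_ox": balance.g_ox,
                    "balance_pct": balance.difference_pct,
                }
            )
    return pd.DataFrame(rows)


def temperature_sweep(
    config: RunConfig,
    temperatures: list[float],
    model: SpurModel | None = None,
    at_time_us: float = 1.0,
) -> pd.DataFrame:
    """G at ``at_time_us`` per species per temperature (fixed pH from config)."""
    return _sweep(
        config, [(t, config.ph) for t in temperatures], model, at_time_us
    )


def ph_sweep(
    config: RunConfig,
    ph_values: list[float],
    model: SpurModel | None = None,
    at_time_us: float = 1.0,
) -> pd.DataFrame:
    """G at ``at_time_us`` per species per pH (fixed temperature from config)."""
    return _sweep(
        config, [(config.temperature_c, ph) for ph in ph_values], model, at_time_us
    )


def series_to_frame(series: GValueSeries) -> pd.DataFrame:
    """Long-format (time_us, species, g_value, std_error) table of one run."""
    rows = []
    for j, sp in enumerate(series.species):
        for i, t in enumerate(series.times_us):
            rows.append(
                {
                    "time_us": t,
                    "species": sp,
                    "g_value": series.g[j, i],
                    "std_error": series.stderr[j, i],
                }
            )
    return pd.DataFrame(rows)


def load_reference(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged literature reference values (G(e_aq) at 1 us, balance percentages)."""
    if path is None:
        path = str(resources.files("radiolysis_irt").joinpath("data", "reference_gvalues.csv"))
    return pd.read_csv(path, comment="#")
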