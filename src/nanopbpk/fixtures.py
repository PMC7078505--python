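"""Synthetic biodistribution observations and correlation-based validation.

Real whole-body validation data for this model are imaging-derived organ
concentration time courses (%ID·g⁻¹, mean ± SD over a small animal group).
The generator here produces SYNTHETIC observations with the same structure —
tumor-free model predictions converted to per-gram concentrations and
corrupted with multiplicative lognormal noise — so the correlation
workflow can be exercised end-to-end without bundling third-party data.
Users can supply their own observations in the same tabular schema
(columns: organ, time_h, mean_percent_id_per_g, sd, n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SimulationConfig, SimulationResult, simulate
from .physiology import BodySpec, default_body
from .transport import NanoparticleSpec

__all__ = [
    "BiodistributionObservations",
    "DEFAULT_TIMEPOINTS_H",
    "generate_fixture",
    "predicted_concentrations",
    "correlate_predictions",
]

#: default imaging schedule (h) out to 24 h post-injection
DEFAULT_TIMEPOINTS_H = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0)


@dataclass(frozen=True)
class BiodistributionObservations:
    """Mean ± SD organ concentrations (%ID·g⁻¹) with replicate count."""

    table: pd.DataFrame  # organ, time_h, mean_percent_id_per_g, sd, n

    def __post_init__(self) -> None:
        required = {"organ", "time_h", "mean_percent_id_per_g", "sd", "n"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"observations table missing columns {sorted(missing)}")
        if (self.table["n"] < 1).any() or (self.table["sd"] < 0).any():
            raise ValueError("need n >= 1 and sd >= 0")


def _organ_masses_g(body: BodySpec) -> dict:
    masses = {o.name: o.f_wt * body.body_weight_g for o in body.organs}
    masses["plasma"] = body.plasma_weight_fraction * body.body_weight_g
    return masses


def predicted_concentrations(
    result: SimulationResult,
    body: BodySpec,
    timepoints_h: Sequence[float],
    organs: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Model organ totals interpolated to the schedule, as %ID·g⁻¹.

    All sub-compartments of an organ are summed: an imaging readout cannot
    distinguish vascular, interstitial and phagocytized particles.
    """
    masses = _organ_masses_g(body)
    organs = list(organs) if organs is not None else sorted(masses)
    rows = []
    for organ in organs:
        total = result.compartment_total(organ)
        conc = np.interp(timepoints_h, result.time_h, total) / masses[organ]
        for t, c in zip(timepoints_h, conc):
            rows.append((organ, float(t), float(c)))
    return pd.DataFrame(rows, columns=["organ", "time_h", "predicted_percent_id_per_g"])


def generate_fixture(
    np_spec: NanoparticleSpec,
    body: Optional[BodySpec] = None,
    noise_cv: float = 0.2,
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H,
    n_reps: int = 4,
    seed: int = 0,
) -> BiodistributionObservations:
    """Simulate the tumor-free model and emit noisy synthetic observations.

    Multiplicative lognormal noise with coefficient of variation ``noise_cv``
    is applied per animal replicate (mean-preserving in expectation);
    ``noise_cv = 0`` returns the model predictions exactly with zero SD.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    body = body if body is not None else default_body()
    config = SimulationConfig(t_end_h=max(timepoints_h) * 1.5,
                              time_grid_h=None)
    result = simulate(np_spec, body=body, config=config)
    pred = predicted_concentrations(result, body, timepoints_h)
    rng = np.random.default_rng(seed)
    rows = []
    sigma = np.sqrt(np.log1p(noise_cv**2))
    for _, row in pred.iterrows():
        mu = row["predicted_percent_id_per_g"]
        if noise_cv == 0:
            reps = np.full(n_reps, mu)
        else:
            reps = mu * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n_reps)
        rows.append((row["organ"], row["time_h"], float(reps.mean()),
                     float(reps.std(ddof=1)) if n_reps > 1 else 0.0, n_reps))
    table = pd.DataFrame(
        rows, columns=["organ", "time_h", "mean_percent_id_per_g", "sd", "n"]
    )
    return BiodistributionObservations(table)


def correlate_predictions(
    result: SimulationResult,
    obs: BiodistributionObservations,
    body: Optional[BodySpec] = None,
) -> float:
    """Pearson correlation between predicted and observed mean concentrations.

    Pairs are matched on (organ, time); at least three matched pairs and
    non-degenerate variance on both sides are required.
    """
    body = body if body is not None else result.params.body
    organs = sorted(obs.table["organ"].unique())
    times = sorted(obs.table["time_h"].unique())
    pred = predicted_concentrations(result, body, times, organs)
    merged = obs.table.merge(pred, on=["organ", "time_h"], how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched (organ, time) pairs")
    x = merged["predicted_percent_id_per_g"].to_numpy()
    y = merged["mean_percent_id_per_g"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in predictions or observations")
    return float(stats.pearsonr(x, y).statistic)
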