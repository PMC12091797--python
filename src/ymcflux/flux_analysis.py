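"""Post-processing of fluxome time series.

Column (per-time-point) normalization divides every net flux by the sum of
flux magnitudes at that time point, so normalized magnitudes sum to one and
values are comparable across time points; row normalization (display only)
scales each reaction's series by its own maximum magnitude.  Absolute
pathway fluxes are recovered by rescaling each normalized fluxome so the
oxygen exchange magnitude matches the measured |vO2|.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model_io import PtmAugmentation
from .oxygen_flux import OxygenFluxSeries

__all__ = [
    "FluxomeSeries",
    "CosubstrateFluxes",
    "normalize_fluxome",
    "row_normalize",
    "pathway_fraction",
    "net_pathway_flux",
    "sugar_consumption",
    "extract_cosubstrate_fluxes",
]

PHASES = ("OX", "RB", "RC")


@dataclass
class FluxomeSeries:
    """Net fluxes (reactions x timepoints) with phase labels per time point.

    ``values`` holds net fluxes (signed); ``normalized`` is set by
    :func:`normalize_fluxome` and declares itself via ``normalization``.
    """

    values: pd.DataFrame  # index: reaction ids, columns: time labels
    phases: List[str]
    subsystems: Dict[str, str] = field(default_factory=dict)
    normalization: str = "none"  # "none" | "column" | "row"

    def __post_init__(self) -> None:
        if len(self.phases) != self.values.shape[1]:
            raise ValueError("one phase label per time point required")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels {unknown}; expected {PHASES}")

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.values.index)

    def phase_columns(self, phase: str) -> List[str]:
        return [c for c, p in zip(self.values.columns, self.phases) if p == phase]


@dataclass
class CosubstrateFluxes:
    """Normalized production fluxes of the histone-PTM cosubstrates."""

    times: List[str]
    acetyl_coa: np.ndarray
    sam: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.acetyl_coa) == len(self.sam)):
            raise ValueError("cosubstrate series lengths must match the time grid")


def normalize_fluxome(series: FluxomeSeries) -> FluxomeSeries:
    """Divide each column by its sum of flux magnitudes (signs preserved)."""
    totals = series.values.abs().sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero flux column(s) {list(zero.index)}; cannot normalize")
    return replace(
        series, values=series.values / totals, normalization="column"
    )


def row_normalize(series: FluxomeSeries) -> FluxomeSeries:
    """Scale each reaction's series by its own maximum magnitude (display)."""
    peak = series.values.abs().max(axis=1).replace(0, 1.0)
    return replace(series, values=series.values.div(peak, axis=0), normalization="row")


def pathway_fraction(
    series: FluxomeSeries, pathways: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Fraction of total metabolic flux transiting each pathway.

    Entry (p, t) = mean |flux| over the pathway's reactions at time t,
    divided by the sum of all network flux magnitudes at t.
    """
    totals = series.values.abs().sum(axis=0)
    rows = {}
    for name, ids in pathways.items():
        ids = list(ids)
        if not ids:
            raise ValueError(f"pathway {name!r} is empty")
        missing = [r for r in ids if r not in series.values.index]
        if missing:
            raise KeyError(f"pathway {name!r} references unknown reactions {missing}")
        rows[name] = series.values.loc[ids].abs().mean(axis=0) / totals
    return pd.DataFrame(rows).T


def net_pathway_flux(
    series: FluxomeSeries,
    pathway: Sequence[str],
    oxygen: OxygenFluxSeries,
    oxygen_reaction_id: str,
) -> Dict[str, float]:
    """Per-phase mean absolute pathway flux in mmol/gDW/h.

    Each time point's fluxome is rescaled so the oxygen exchange magnitude
    equals the measured |vO2| at that time, pinning absolute units; the
    pathway value is the mean rescaled |flux| over its reactions, averaged
    (unweighted) over each phase's time points.
    """
    if len(oxygen.times) != series.values.shape[1]:
        raise ValueError("oxygen series must align with the flux time points")
    if oxygen_reaction_id not in series.values.index:
        raise KeyError(f"oxygen exchange {oxygen_reaction_id!r} not in fluxome")
    ox_flux = series.values.loc[oxygen_reaction_id].abs().to_numpy()
    if np.any(ox_flux == 0):
        raise ValueError("zero oxygen exchange flux at some time point; scale undefined")
    factors = np.abs(oxygen.vo2) / ox_flux
    sub = series.values.loc[list(pathway)].abs().to_numpy() * factors[np.newaxis, :]
    per_time = sub.mean(axis=0)
    out: Dict[str, float] = {}
    for phase in PHASES:
        idx = [i for i, p in enumerate(series.phases) if p == phase]
        if idx:
            out[phase] = float(np.mean(per_time[idx]))
    return out


def sugar_consumption(
    series: FluxomeSeries,
    sugar_ids: Mapping[str, str],
) -> pd.DataFrame:
    """Consumption rates (positive magnitudes) per sugar and time point.

    ``sugar_ids`` maps sugar name -> reaction id, with a direction suffix
    chosen per convention: exchange reactions consume in the negative (net
    uptake) direction, degradation reactions in the positive direction.
    Pass ids as ``{"glucose": "EX_glc"}`` for exchanges (consumption =
    max(0, -net)) or ``{"glycogen": "+GLYCDEG"}`` with a leading ``+`` for
    forward-consuming degradation reactions (consumption = max(0, net)).
    """
    rows = {}
    for sugar, rid in sugar_ids.items():
        forward = rid.startswith("+")
        rid = rid.lstrip("+")
        if rid not in series.values.index:
            raise KeyError(f"unknown sugar reaction id {rid!r}")
        net = series.values.loc[rid]
        rows[sugar] = np.maximum(0.0, net if forward else -net)
    return pd.DataFrame(rows).T


def extract_cosubstrate_fluxes(
    series: FluxomeSeries,
    aug: Optional[PtmAugmentation] = None,
    acetylation_id: Optional[str] = None,
    methylation_id: Optional[str] = None,
) -> CosubstrateFluxes:
    """Read the normalized fluxes of the designated histone-PTM sinks.

    Sink ids come from ``aug`` (the augmentation's designated reactions) or
    can be given directly.
    """
    if aug is not None:
        acetylation_id = acetylation_id or aug.histone_acetylation_id
        methylation_id = methylation_id or aug.histone_methylation_id
    if acetylation_id is None or methylation_id is None:
        raise ValueError("acetylation and methylation sink ids are required")
    for rid, label in ((acetylation_id, "acetylation"), (methylation_id, "methylation")):
        if rid not in series.values.index:
            raise KeyError(f"{label} sink {rid!r} not present in the fluxome series")
    return CosubstrateFluxes(
        times=list(series.values.columns),
        acetyl_coa=series.values.loc[acetylation_id].to_numpy(dtype=float),
        sam=series.values.loc[methylation_id].to_numpy(dtype=float),
    )
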