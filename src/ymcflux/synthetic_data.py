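"""Synthetic study-condition generator.

Everything the pipeline consumes can be generated here without downloads:
toy stoichiometric networks with known maximum-entropy optima (chain,
diamond, and a ~22-reaction "mini-cell" with glucose/oxygen exchanges,
storage sugars, biomass, and histone acetylation/methylation sinks), a
dissolved-oxygen trace forward-integrated from a planted uptake-rate
function, smooth positive expression profiles keyed to the toy GPR genes,
and gene x timepoint enrichment matrices with planted per-gene correlation
to a cosubstrate flux series.

Default conditions mirror the study design: 15 time points over one
metabolic cycle (2.5 h), phases OX (short, high oxygen uptake), RB and RC,
chemostat parameters kLa = 225 1/h, growth rate 0.1 1/h, and a planted
oscillatory qO2 between about 2 and 8 mmol/gDW/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_io import MetabolicNetwork, Metabolite, Reaction
from .oxygen_flux import CultureParams, DissolvedOxygenSeries
from .epigenome import EnrichmentMatrix, GeneAnnotation

__all__ = [
    "SyntheticScenario",
    "make_toy_network",
    "simulate_do_trace",
    "simulate_epigenome",
    "simulate_expression",
    "default_qo2",
    "default_phases",
    "toy_annotation",
]

CYCLE_HOURS = 2.5
N_TIMEPOINTS = 15


def default_phases(n: int = N_TIMEPOINTS) -> List[str]:
    """OX/RB/RC phase labels over one cycle (OX short, RC longest)."""
    n_ox = max(1, round(n * 0.25))
    n_rb = max(1, round(n * 0.33))
    return ["OX"] * n_ox + ["RB"] * n_rb + ["RC"] * (n - n_ox - n_rb)


def default_qo2(t: np.ndarray) -> np.ndarray:
    """Planted oscillatory specific O2 uptake (mmol/gDW/h), peak in OX."""
    t = np.asarray(t, dtype=float)
    return 5.0 + 3.0 * np.cos(2.0 * np.pi * t / CYCLE_HOURS)


@dataclass
class SyntheticScenario:
    """Seeded description of one synthetic study.

    ``rho_planted`` is the population correlation of the first
    ``n_correlated`` genes' enrichment series to the cosubstrate flux
    series; remaining genes are pure noise (rho = 0).
    """

    seed: int = 0
    topology: str = "mini-cell"
    n_timepoints: int = N_TIMEPOINTS
    cycle_hours: float = CYCLE_HOURS
    n_genes: int = 300
    n_correlated: int = 60
    rho_planted: float = 0.8
    noise_sd: float = 1.0
    culture: CultureParams = field(default_factory=CultureParams)

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho_planted <= 1.0):
            raise ValueError("planted correlation must lie in [-1, 1]")

    @property
    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.cycle_hours, self.n_timepoints)

    @property
    def phases(self) -> List[str]:
        return default_phases(self.n_timepoints)


# ---------------------------------------------------------------------------
# Toy networks
# ---------------------------------------------------------------------------

def _rxn(rid, eq, lb, ub, subsystem="", gpr="", name=""):
    from .model_io import parse_reaction_equation

    return Reaction(
        id=rid,
        stoichiometry=parse_reaction_equation(eq),
        lower_bound=lb,
        upper_bound=ub,
        subsystem=subsystem,
        gpr=gpr,
        name=name,
    )


def make_toy_network(topology: str, chain_length: int = 3) -> MetabolicNetwork:
    """Small stoichiometric fixtures with known structure.

    - ``chain``: linear source -> ... -> sink path of ``chain_length``
      reactions.
    - ``diamond``: one source flux splitting into two stoichiometrically
      identical parallel branches that rejoin.
    - ``mini-cell``: glucose/oxygen/methionine exchanges, lumped glycolysis,
      fermentation and respiration, storage sugars (glycogen, trehalose),
      biomass, and designated histone acetylation (HISTAT) and methylation
      (HISTMT) sinks; <= 25 reactions with subsystem labels and GPRs.
    """
    if topology == "chain":
        k = chain_length
        if k < 2:
            raise ValueError("chain needs length >= 2")
        mets = [Metabolite(f"m{i}", compartment="c") for i in range(k - 1)]
        rxns = []
        for i in range(k):
            lhs = f"m{i-1}" if i > 0 else ""
            rhs = f"m{i}" if i < k - 1 else ""
            eq = f"{lhs} --> {rhs}"
            rxns.append(_rxn(f"R{i}", eq, 0, 10, subsystem="chain"))
        return MetabolicNetwork(mets, rxns)

    if topology == "diamond":
        mets = [Metabolite("A", compartment="c"), Metabolite("B", compartment="c")]
        rxns = [
            _rxn("SRC", " --> A", 0, 10, subsystem="boundary"),
            _rxn("BR1", "A --> B", 0, 10, subsystem="branch"),
            _rxn("BR2", "A --> B", 0, 10, subsystem="branch"),
            _rxn("SNK", "B --> ", 0, 10, subsystem="boundary"),
        ]
        return MetabolicNetwork(mets, rxns)

    if topology == "mini-cell":
        comp = {"e": "e", "c": "c"}
        met_ids = [
            "glc_e", "glc_c", "o2_e", "o2_c", "pyr_c", "etoh_c", "etoh_e",
            "co2_c", "co2_e", "glycogen_c", "tre_c", "accoa_c", "met_e",
            "met_c", "sam_c",
        ]
        mets = [Metabolite(m, compartment=comp[m.rsplit("_", 1)[-1]]) for m in met_ids]
        rxns = [
            _rxn("EX_glc", "glc_e <=> ", -10, 0, "Exchange"),
            _rxn("GLCt", "glc_e --> glc_c", 0, 10, "Transport", "HXT1"),
            _rxn("EX_o2", "o2_e <=> ", -30, 0, "Exchange"),
            _rxn("O2t", "o2_e --> o2_c", 0, 30, "Transport"),
            _rxn("EX_met", "met_e <=> ", -5, 0, "Exchange"),
            _rxn("METt", "met_e --> met_c", 0, 5, "Transport", "MUP1"),
            _rxn("GLYC", "glc_c --> 2 pyr_c", 0, 20, "Glycolysis", "GLK1 and PFK1"),
            _rxn("FERM", "pyr_c --> etoh_c + co2_c", 0, 20, "Fermentation", "PDC1 or PDC5"),
            _rxn("ETOHt", "etoh_c --> etoh_e", 0, 20, "Transport"),
            _rxn("EX_etoh", "etoh_e --> ", 0, 20, "Exchange"),
            _rxn("RESP", "pyr_c + 3 o2_c --> 3 co2_c", 0, 10, "Oxidative phosphorylation", "COX1 and QCR2"),
            _rxn("CO2t", "co2_c --> co2_e", 0, 100, "Transport"),
            _rxn("EX_co2", "co2_e --> ", 0, 100, "Exchange"),
            _rxn("GLYCSYN", "glc_c --> glycogen_c", 0, 5, "Storage carbohydrate", "GSY1"),
            _rxn("GLYCDEG", "glycogen_c --> glc_c", 0, 5, "Storage carbohydrate", "GPH1"),
            _rxn("TRESYN", "2 glc_c --> tre_c", 0, 5, "Storage carbohydrate", "TPS1"),
            _rxn("TREDEG", "tre_c --> 2 glc_c", 0, 5, "Storage carbohydrate", "NTH1"),
            _rxn("PDH", "pyr_c --> accoa_c + co2_c", 0, 10, "Pyruvate metabolism", "PDA1 and PDB1"),
            _rxn("HISTAT", "accoa_c --> ", 0, 10, "Histone acetylation", "HAT1"),
            _rxn("MAT", "met_c --> sam_c", 0, 5, "Methionine cycle", "SAM1 or SAM2"),
            _rxn("HISTMT", "sam_c --> ", 0, 5, "Histone methylation", "SET1"),
            _rxn(
                "BIOMASS",
                "0.5 glc_c + 0.2 pyr_c + 0.05 accoa_c + 0.02 sam_c + o2_c --> ",
                0, 10, "Growth", "",
            ),
        ]
        return MetabolicNetwork(
            mets, rxns, biomass_reaction_id="BIOMASS", oxygen_exchange_id="EX_o2"
        )

    raise ValueError(f"unknown topology {topology!r}")


MINI_CELL_GENES = [
    "HXT1", "MUP1", "GLK1", "PFK1", "PDC1", "PDC5", "COX1", "QCR2", "GSY1",
    "GPH1", "TPS1", "NTH1", "PDA1", "PDB1", "HAT1", "SAM1", "SAM2", "SET1",
]


# ---------------------------------------------------------------------------
# Dissolved-oxygen trace
# ---------------------------------------------------------------------------

def simulate_do_trace(
    qo2_fn: Callable[[np.ndarray], np.ndarray],
    params: CultureParams,
    grid: np.ndarray,
    do0: Optional[float] = None,
) -> DissolvedOxygenSeries:
    """Forward-integrate the DO mass balance for a planted qO2(t).

    dDO/dt = kLa (1 - DO) - qO2(t) X / c*, integrated at high resolution
    (RK45) and sampled onto ``grid``; DO clipped to [0, 1].
    """
    from scipy.integrate import solve_ivp

    grid = np.asarray(grid, dtype=float)
    if np.any(np.asarray(qo2_fn(grid)) < 0):
        raise ValueError("planted qO2 must be nonnegative on the grid")
    if do0 is None:
        # start at the quasi-steady DO for the initial uptake
        do0 = 1.0 - float(qo2_fn(grid[:1])[0]) * params.biomass / (
            params.kla * params.c_star
        )
        do0 = min(max(do0, 0.0), 1.0)

    def rhs(t, y):
        q = float(np.asarray(qo2_fn(np.asarray([t])))[0])
        return [params.kla * (1.0 - y[0]) - q * params.biomass / params.c_star]

    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        [do0],
        t_eval=grid,
        method="RK45",
        rtol=1e-9,
        atol=1e-11,
        max_step=(grid[-1] - grid[0]) / 200.0,
    )
    if not sol.success:
        raise RuntimeError(f"DO integration failed: {sol.message}")
    return DissolvedOxygenSeries(grid, np.clip(sol.y[0], 0.0, 1.0))


# ---------------------------------------------------------------------------
# Expression and epigenome matrices
# ---------------------------------------------------------------------------

def simulate_expression(
    scenario: SyntheticScenario,
    genes: Optional[Sequence[str]] = None,
    time_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Smooth positive FPKM profiles (log-normal around phase-dependent
    means) for the toy network's GPR genes; genes x timepoints."""
    genes = list(genes) if genes is not None else list(MINI_CELL_GENES)
    rng = np.random.default_rng(scenario.seed + 1)
    t = scenario.time_grid
    n_t = len(t)
    labels = list(time_labels) if time_labels is not None else [
        f"t{i+1}" for i in range(n_t)
    ]
    data = np.empty((len(genes), n_t))
    for i, gene in enumerate(genes):
        base = rng.lognormal(mean=3.0, sigma=0.5)
        phase_shift = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.2, 0.8)
        profile = base * np.exp(
            amp * np.sin(2 * np.pi * t / scenario.cycle_hours + phase_shift)
        )
        noise = rng.lognormal(mean=0.0, sigma=0.05, size=n_t)
        data[i] = profile * noise
    return pd.DataFrame(data, index=genes, columns=labels)


def simulate_epigenome(
    scenario: SyntheticScenario,
    flux_series: np.ndarray,
    assay: str = "H3K9Ac",
    n_genes: Optional[int] = None,
    rho: Optional[np.ndarray] = None,
) -> Tuple[EnrichmentMatrix, np.ndarray]:
    """Enrichment matrix with planted per-gene correlation to a flux series.

    Each gene's series is rho * z(flux) + sqrt(1-rho^2) * noise on the
    standardized scale, then affinely mapped to nonnegative enrichment
    units.  Returns the matrix and the ground-truth rho vector.
    """
    flux = np.asarray(flux_series, dtype=float)
    n_t = len(flux)
    if n_t != scenario.n_timepoints:
        raise ValueError("flux series length must equal the scenario grid")
    n_genes = n_genes if n_genes is not None else scenario.n_genes
    if rho is None:
        rho = np.zeros(n_genes)
        rho[: min(scenario.n_correlated, n_genes)] = scenario.rho_planted
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1):
        raise ValueError("|rho| > 1 for some gene")
    if len(rho) != n_genes:
        raise ValueError("rho vector length must equal n_genes")

    z = (flux - flux.mean()) / flux.std() if flux.std() > 0 else np.zeros(n_t)
    rng = np.random.default_rng(scenario.seed + {"H3K9Ac": 2, "H3K4me3": 3, "ATAC": 4, "RNA": 5}.get(assay, 6))
    noise = rng.standard_normal((n_genes, n_t)) * scenario.noise_sd
    noise_z = (noise - noise.mean(axis=1, keepdims=True)) / np.where(
        noise.std(axis=1, keepdims=True) == 0, 1, noise.std(axis=1, keepdims=True)
    )
    series = rho[:, None] * z[None, :] + np.sqrt(1 - rho[:, None] ** 2) * noise_z
    # affine map to nonnegative enrichment units
    values = 10.0 + 3.0 * series
    values = np.clip(values, 0.0, None)
    index = [f"gene{i:04d}" for i in range(n_genes)]
    labels = [f"t{i+1}" for i in range(n_t)]
    mat = EnrichmentMatrix(
        values=pd.DataFrame(values, index=index, columns=labels), assay=assay
    )
    return mat, rho


# ---------------------------------------------------------------------------
# Toy genome annotation (for the epigenome file path)
# ---------------------------------------------------------------------------

def toy_annotation(
    n_genes: int, spacing: int = 3000, window: int = 500
) -> Tuple[List[GeneAnnotation], Dict[str, int]]:
    """Two-chromosome toy annotation with evenly spaced alternating-strand
    genes; returns (genes, chromosome lengths)."""
    genes = []
    half = (n_genes + 1) // 2
    for i in range(n_genes):
        chrom = "chrI" if i < half else "chrII"
        j = i if i < half else i - half
        start = 2 * window + j * spacing
        end = start + 1500
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneAnnotation(f"gene{i:04d}", chrom, start, end, strand))
    lengths = {
        "chrI": 2 * window + half * spacing + 4000,
        "chrII": 2 * window + (n_genes - half) * spacing + 4000,
    }
    return genes, lengths
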