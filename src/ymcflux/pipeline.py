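"""End-to-end orchestration.

Runs the stages simulate -> oxygen -> fluxes -> analysis -> enrich ->
dominance from one structured configuration, with deterministic seeding
(one root seed, split per stage), a JSON manifest recording config hash,
seed, versions, per-stage status and output-file hashes, and stage
idempotence (a completed stage is skipped unless forced).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .model_io import (
    GprPolicy,
    expression_to_reaction_weights,
    read_fpkm_table,
    read_sbml,
    split_reversible,
    write_sbml,
)
from .oxygen_flux import (
    CultureParams,
    DissolvedOxygenSeries,
    OxygenFluxSeries,
    oxygen_uptake_rate,
    read_do_table,
    savgol_derivative,
    write_oxygen_table,
)
from .maxent_cbm import FluxProblem, PhysiologyConstraint, solve_series
from .flux_analysis import (
    CosubstrateFluxes,
    FluxomeSeries,
    extract_cosubstrate_fluxes,
    net_pathway_flux,
    normalize_fluxome,
    pathway_fraction,
    sugar_consumption,
)
from .epigenome import (
    EnrichmentMatrix,
    align_timepoints,
    promoter_enrichment,
    read_bed6,
    read_bedgraph,
)
from .dominance_stats import atac_association, dominance_analysis, select_correlated_genes
from .synthetic_data import (
    SyntheticScenario,
    default_phases,
    default_qo2,
    make_toy_network,
    simulate_do_trace,
    simulate_epigenome,
    simulate_expression,
    toy_annotation,
)

logger = logging.getLogger("ymcflux")

STAGES = ("simulate", "oxygen", "fluxes", "analysis", "enrich", "dominance")

ATAC_LABELS = ["OX_I", "OX_II", "RB_I", "RB_II", "RC_I", "RC_II"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Structured configuration for a pipeline run."""

    outdir: Path
    seed: int = 0
    # input paths; None means "use the simulate stage's outputs"
    model_path: Optional[Path] = None
    expression_path: Optional[Path] = None
    do_path: Optional[Path] = None
    annotation_path: Optional[Path] = None
    signal_dir: Optional[Path] = None
    culture: CultureParams = field(default_factory=CultureParams)
    # alignment rules: (assay, [labels to average])
    merge_rules: List[Tuple[str, List[str]]] = field(
        default_factory=lambda: [
            ("RNA", ["t10", "t11"]),
            ("H3K9Ac", ["t13", "t14"]),
            ("H3K4me3", ["t13", "t14"]),
        ]
    )
    phases: Optional[List[str]] = None  # per matched time point
    half_width: int = 500
    correlation_cutoff: float = 0.7
    max_random_fraction: float = 0.10
    savgol_window: int = 5
    savgol_order: int = 2
    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)
    force: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not (0 < self.max_random_fraction < 1):
            raise ConfigError("max_random_fraction must lie in (0, 1)")
        if not (-1 <= self.correlation_cutoff <= 1):
            raise ConfigError("correlation_cutoff must lie in [-1, 1]")
        if self.half_width <= 0:
            raise ConfigError("half_width must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "culture" in raw and isinstance(raw["culture"], dict):
            raw["culture"] = CultureParams(**raw["culture"])
        if "scenario" in raw and isinstance(raw["scenario"], dict):
            raw["scenario"] = SyntheticScenario(**raw["scenario"])
        if "merge_rules" in raw:
            raw["merge_rules"] = [(a, list(ls)) for a, ls in raw["merge_rules"]]
        for key in ("outdir", "model_path", "expression_path", "do_path",
                    "annotation_path", "signal_dir"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "outdir" not in raw:
            raise ConfigError("missing required config field: outdir")
        return cls(**raw)

    # resolved paths -------------------------------------------------------
    def path(self, stage: str, name: str) -> Path:
        return self.outdir / stage / name

    def resolved_model(self) -> Path:
        return self.model_path or self.path("simulate", "model.xml")

    def resolved_expression(self) -> Path:
        return self.expression_path or self.path("simulate", "expression.tsv")

    def resolved_do(self) -> Path:
        return self.do_path or self.path("simulate", "do_trace.tsv")

    def resolved_annotation(self) -> Path:
        return self.annotation_path or self.path("simulate", "annotation.bed")

    def resolved_signal_dir(self) -> Path:
        return self.signal_dir or (self.outdir / "simulate")

    def validate_for(self, stages: Sequence[str]) -> None:
        """Schema check: the requested stages must have resolvable inputs."""
        missing: List[str] = []
        # a path counts as resolvable if set explicitly, if the simulate
        # stage will produce it in this run, or if a previous simulate run
        # already left it in the run directory
        simulated = "simulate" in stages
        if "fluxes" in stages and not simulated:
            if self.model_path is None and not self.resolved_model().exists():
                missing.append("model_path")
            if self.expression_path is None and not self.resolved_expression().exists():
                missing.append("expression_path")
        if "oxygen" in stages and not simulated:
            if self.do_path is None and not self.resolved_do().exists():
                missing.append("do_path")
        if "enrich" in stages and not simulated:
            if self.annotation_path is None and not self.resolved_annotation().exists():
                missing.append("annotation_path")
            if self.signal_dir is None and not self.resolved_annotation().exists():
                missing.append("signal_dir")
        if missing:
            raise ConfigError(
                f"config is missing required field(s) for the requested stages: {missing}"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    blob = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _chip_labels16() -> List[str]:
    return [f"t{i+1}" for i in range(16)]


def _expand_15_to_16(df15: pd.DataFrame, insert_after_col: int) -> pd.DataFrame:
    """Spread a 15-column matched-grid matrix onto a 16-point sampling grid
    by duplicating one matched column into the two raw labels that will be
    averaged back together."""
    cols = df15.to_numpy()
    out = np.empty((df15.shape[0], 16))
    out[:, :insert_after_col + 1] = cols[:, :insert_after_col + 1]
    out[:, insert_after_col + 1] = cols[:, insert_after_col]
    out[:, insert_after_col + 2:] = cols[:, insert_after_col + 1:]
    return pd.DataFrame(out, index=df15.index, columns=_chip_labels16())


def _cosubstrate_series_for_planting(config: RunConfig, net, do_series):
    """Run oxygen + flux inference on the simulated inputs to obtain the
    realized cosubstrate flux series the epigenome matrices are planted
    against (the generator's ground truth)."""
    expr15 = simulate_expression(config.scenario)
    qo2 = _recover_qo2(config, do_series)
    solutions = _solve_timepoints(net, expr15, qo2, config)
    series = _fluxome_series(net, solutions, list(expr15.columns), config)
    norm = normalize_fluxome(series)
    return extract_cosubstrate_fluxes(
        norm, acetylation_id="HISTAT", methylation_id="HISTMT"
    )


def stage_simulate(config: RunConfig) -> List[Path]:
    out = config.outdir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    scen = config.scenario
    net = make_toy_network(scen.topology)
    write_sbml(net, out / "model.xml")

    do_series = simulate_do_trace(default_qo2, config.culture, scen.time_grid)
    pd.DataFrame({"time_h": do_series.times, "DO_fraction": do_series.do}).to_csv(
        out / "do_trace.tsv", sep="\t", index=False
    )

    # expression: 15 matched profiles spread onto the 16-point RNA grid
    expr15 = simulate_expression(scen)
    expr16 = _expand_15_to_16(expr15, insert_after_col=9)
    expr16.index.name = "gene"
    expr16.to_csv(out / "expression.tsv", sep="\t")

    # epigenome planted against the realized cosubstrate fluxes
    cosub = _cosubstrate_series_for_planting(config, net, do_series)
    genes, chrom_lengths = toy_annotation(scen.n_genes, window=config.half_width)
    with open(out / "annotation.bed", "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    with open(out / "chrom.sizes", "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")

    gene_ids = [g.gene_id for g in genes]
    files = [out / "model.xml", out / "do_trace.tsv", out / "expression.tsv",
             out / "annotation.bed", out / "chrom.sizes"]

    def write_tracks(mat: pd.DataFrame, prefix: str) -> None:
        from .epigenome import promoter_window

        for label in mat.columns:
            path = out / f"{prefix}_{label}.bedGraph"
            with open(path, "w") as fh:
                for g in genes:
                    s, e = promoter_window(g, config.half_width, chrom_lengths)
                    fh.write(f"{g.chromosome}\t{s}\t{e}\t{mat.loc[g.gene_id, label]:.6f}\n")
            files.append(path)

    k9_15, _ = simulate_epigenome(
        scen, cosub.acetyl_coa, assay="H3K9Ac", n_genes=scen.n_genes
    )
    k4_15, _ = simulate_epigenome(
        scen, cosub.sam, assay="H3K4me3", n_genes=scen.n_genes
    )
    for mat15, name in ((k9_15, "H3K9Ac"), (k4_15, "H3K4me3")):
        df15 = pd.DataFrame(
            mat15.values.to_numpy(), index=gene_ids, columns=mat15.values.columns
        )
        df16 = _expand_15_to_16(df15, insert_after_col=12)
        write_tracks(df16, name)

    # ATAC: 6 samples (two per phase), planted against acetyl-CoA flux
    # subsampled at the matching matched-grid time points
    atac_idx = _atac_timepoint_indices(config)
    atac_scen = SyntheticScenario(
        seed=scen.seed, n_timepoints=scen.n_timepoints, n_genes=scen.n_genes,
        n_correlated=scen.n_correlated, rho_planted=scen.rho_planted,
    )
    atac15, _ = simulate_epigenome(
        atac_scen, cosub.acetyl_coa, assay="ATAC", n_genes=scen.n_genes
    )
    atac6 = pd.DataFrame(
        atac15.values.to_numpy()[:, atac_idx], index=gene_ids, columns=ATAC_LABELS
    )
    write_tracks(atac6, "ATAC")
    return files


def _atac_timepoint_indices(config: RunConfig) -> List[int]:
    """Two roughly mid-half sample indices per phase on the matched grid."""
    phases = config.phases or default_phases(config.scenario.n_timepoints)
    idx = []
    for phase in ("OX", "RB", "RC"):
        where = [i for i, p in enumerate(phases) if p == phase]
        idx.append(where[len(where) // 4])
        idx.append(where[(3 * len(where)) // 4])
    return idx


def _recover_qo2(config: RunConfig, series: DissolvedOxygenSeries) -> OxygenFluxSeries:
    ddo = savgol_derivative(series, order=config.savgol_order, window=config.savgol_window)
    return oxygen_uptake_rate(series, config.culture, ddo)


def stage_oxygen(config: RunConfig) -> List[Path]:
    do_path = config.resolved_do()
    if not do_path.exists():
        raise ConfigError(
            f"oxygen stage requires the DO trace {do_path} (run 'simulate' or set do_path)"
        )
    out = config.outdir / "oxygen"
    out.mkdir(parents=True, exist_ok=True)
    series = read_do_table(do_path)
    flux = _recover_qo2(config, series)
    write_oxygen_table(flux, out / "oxygen_flux.tsv")
    return [out / "oxygen_flux.tsv"]


def _solve_timepoints(net, expression: pd.DataFrame, oxygen: OxygenFluxSeries,
                      config: RunConfig):
    irr = split_reversible(net)
    problems = []
    for j, col in enumerate(expression.columns):
        weights = expression_to_reaction_weights(irr, expression[col].to_dict(), GprPolicy())
        phys = PhysiologyConstraint(
            w_mu=config.culture.dilution_rate,
            w_o2=float(oxygen.qo2[j]),
            fix_growth=True,
        )
        problems.append(FluxProblem(irr=irr, weights=weights, physiology=phys))
    return solve_series(problems)


def _fluxome_series(net, solutions, time_labels, config: RunConfig) -> FluxomeSeries:
    net_mat = pd.DataFrame(
        {lbl: pd.Series(sol.net_fluxes) for lbl, sol in zip(time_labels, solutions)}
    ).loc[[r.id for r in net.reactions]]
    phases = config.phases or default_phases(len(time_labels))
    subsystems = {r.id: r.subsystem for r in net.reactions}
    return FluxomeSeries(values=net_mat, phases=list(phases), subsystems=subsystems)


def stage_fluxes(config: RunConfig) -> List[Path]:
    model_path = config.resolved_model()
    expr_path = config.resolved_expression()
    oxy_path = config.path("oxygen", "oxygen_flux.tsv")
    for p, stage in ((model_path, "simulate"), (expr_path, "simulate"), (oxy_path, "oxygen")):
        if not Path(p).exists():
            raise ConfigError(f"fluxes stage requires {p} (run stage '{stage}' first)")
    out = config.outdir / "fluxes"
    out.mkdir(parents=True, exist_ok=True)

    net = read_sbml(model_path)
    expr = read_fpkm_table(expr_path)
    rna = EnrichmentMatrix(values=expr, assay="RNA")
    rna = align_timepoints(rna, config.merge_rules)
    expr = rna.values
    oxy_df = pd.read_csv(oxy_path, sep="\t")
    if len(oxy_df) != expr.shape[1]:
        raise ConfigError(
            f"oxygen series has {len(oxy_df)} points but the aligned expression "
            f"table has {expr.shape[1]} time points"
        )
    oxygen = OxygenFluxSeries(oxy_df["time_h"].to_numpy(), oxy_df["qO2"].to_numpy())

    solutions = _solve_timepoints(net, expr, oxygen, config)
    irr = split_reversible(net)
    files = []
    for lbl, sol in zip(expr.columns, solutions):
        fwd = {cid: 0.0 for cid in net.reaction_index}
        rev = {cid: 0.0 for cid in net.reaction_index}
        for cid, pid, d, v in zip(
            sol.component_ids, irr.parent_reaction_ids, irr.directions, sol.v
        ):
            (fwd if d > 0 else rev)[pid] = float(v)
        df = pd.DataFrame(
            {
                "reaction_id": [r.id for r in net.reactions],
                "net_flux": [sol.net_fluxes[r.id] for r in net.reactions],
                "forward": [fwd[r.id] for r in net.reactions],
                "reverse": [rev[r.id] for r in net.reactions],
                "subsystem": [r.subsystem for r in net.reactions],
            }
        )
        path = out / f"fluxes_{lbl.replace('+', '_')}.tsv"
        df.to_csv(path, sep="\t", index=False)
        files.append(path)

    series = _fluxome_series(net, solutions, list(expr.columns), config)
    series.values.index.name = "reaction_id"
    series.values.to_csv(out / "fluxome_net.tsv", sep="\t")
    files.append(out / "fluxome_net.tsv")
    solver_manifest = {
        "time_points": list(map(str, expr.columns)),
        "anchors": {"w_mu": config.culture.dilution_rate, "w_o2": oxygen.qo2.tolist()},
        "tolerances": {"optimality": 1e-8, "feasibility": 1e-9},
        "status": [s.status for s in solutions],
        "objective_values": [s.objective_value for s in solutions],
        "max_sv_residuals": [s.max_sv_residual for s in solutions],
    }
    (out / "solver_manifest.json").write_text(json.dumps(solver_manifest, indent=1))
    files.append(out / "solver_manifest.json")
    return files


def stage_analysis(config: RunConfig) -> List[Path]:
    flux_path = config.path("fluxes", "fluxome_net.tsv")
    oxy_path = config.path("oxygen", "oxygen_flux.tsv")
    for p, stage in ((flux_path, "fluxes"), (oxy_path, "oxygen")):
        if not p.exists():
            raise ConfigError(f"analysis stage requires {p} (run stage '{stage}' first)")
    out = config.outdir / "analysis"
    out.mkdir(parents=True, exist_ok=True)

    net = read_sbml(config.resolved_model())
    net_mat = pd.read_csv(flux_path, sep="\t", index_col=0)
    phases = config.phases or default_phases(net_mat.shape[1])
    subsystems = {r.id: r.subsystem for r in net.reactions}
    series = FluxomeSeries(values=net_mat, phases=list(phases), subsystems=subsystems)
    norm = normalize_fluxome(series)
    norm.values.index.name = "reaction_id"
    norm.values.to_csv(out / "fluxome_normalized.tsv", sep="\t")

    cosub = extract_cosubstrate_fluxes(
        norm, acetylation_id="HISTAT", methylation_id="HISTMT"
    )
    pd.DataFrame(
        {"time": cosub.times, "acetyl_coa": cosub.acetyl_coa, "sam": cosub.sam}
    ).to_csv(out / "cosubstrate_fluxes.tsv", sep="\t", index=False)

    pathways: Dict[str, List[str]] = {}
    for rid, sub in subsystems.items():
        if sub and rid in norm.values.index:
            pathways.setdefault(sub, []).append(rid)
    frac = pathway_fraction(norm, pathways)
    frac.index.name = "pathway"
    frac.to_csv(out / "pathway_fractions.tsv", sep="\t")

    oxy_df = pd.read_csv(oxy_path, sep="\t")
    oxygen = OxygenFluxSeries(oxy_df["time_h"].to_numpy(), oxy_df["qO2"].to_numpy())
    results: Dict[str, Dict[str, float]] = {}
    oxp = pathways.get("Oxidative phosphorylation")
    if oxp and net.oxygen_exchange_id in norm.values.index:
        results["oxidative_phosphorylation"] = net_pathway_flux(
            norm, oxp, oxygen, net.oxygen_exchange_id
        )
    (out / "net_pathway_flux.json").write_text(json.dumps(results, indent=1))

    sugar_ids = {}
    if "EX_glc" in norm.values.index:
        sugar_ids["glucose"] = "EX_glc"
    for sugar, rid in (("glycogen", "GLYCDEG"), ("trehalose", "TREDEG")):
        if rid in norm.values.index:
            sugar_ids[sugar] = "+" + rid
    files = [out / "fluxome_normalized.tsv", out / "cosubstrate_fluxes.tsv",
             out / "pathway_fractions.tsv", out / "net_pathway_flux.json"]
    if sugar_ids:
        cons = sugar_consumption(norm, sugar_ids)
        cons.index.name = "sugar"
        cons.to_csv(out / "sugar_consumption.tsv", sep="\t")
        files.append(out / "sugar_consumption.tsv")
    return files


def stage_enrich(config: RunConfig) -> List[Path]:
    ann_path = config.resolved_annotation()
    sig_dir = config.resolved_signal_dir()
    if not Path(ann_path).exists():
        raise ConfigError(f"enrich stage requires the annotation {ann_path}")
    out = config.outdir / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    genes = read_bed6(ann_path)
    chrom_lengths = None
    sizes = Path(sig_dir) / "chrom.sizes"
    if sizes.exists():
        chrom_lengths = {
            line.split("\t")[0]: int(line.split("\t")[1])
            for line in sizes.read_text().splitlines() if line.strip()
        }

    files = []
    for assay in ("H3K9Ac", "H3K4me3", "ATAC"):
        tracks = sorted(Path(sig_dir).glob(f"{assay}_*.bedGraph"))
        if not tracks:
            continue
        cols = {}
        for path in tracks:
            label = path.stem[len(assay) + 1:]
            track = read_bedgraph(path)
            cols[label] = promoter_enrichment(
                track, genes, config.half_width, chrom_lengths
            )
        df = pd.DataFrame(cols)
        if assay != "ATAC":
            df = df[sorted(df.columns, key=lambda l: int(l.lstrip("t")))]
        else:
            df = df[[l for l in ATAC_LABELS if l in df.columns]]
        mat = align_timepoints(EnrichmentMatrix(values=df, assay=assay), config.merge_rules)
        mat.values.index.name = "gene"
        path = out / f"enrichment_{assay}.tsv"
        mat.values.to_csv(path, sep="\t")
        files.append(path)
    if not files:
        raise ConfigError(f"no signal tracks found under {sig_dir}")
    return files


def stage_dominance(config: RunConfig) -> List[Path]:
    cosub_path = config.path("analysis", "cosubstrate_fluxes.tsv")
    if not cosub_path.exists():
        raise ConfigError(f"dominance stage requires {cosub_path} (run stage 'analysis')")
    out = config.outdir / "dominance"
    out.mkdir(parents=True, exist_ok=True)
    cosub = pd.read_csv(cosub_path, sep="\t")
    seed = _stage_seed(config.seed, "dominance")

    files = []
    dominances: Dict[str, pd.Series] = {}
    for assay, flux_col in (("H3K9Ac", "acetyl_coa"), ("H3K4me3", "sam")):
        enr_path = config.path("enrich", f"enrichment_{assay}.tsv")
        if not enr_path.exists():
            raise ConfigError(f"dominance stage requires {enr_path} (run stage 'enrich')")
        marks = EnrichmentMatrix(
            values=pd.read_csv(enr_path, sep="\t", index_col=0), assay=assay
        )
        flux = cosub[flux_col].to_numpy()
        result = dominance_analysis(
            marks, flux, config.max_random_fraction, reps_per_gene=1, seed=seed
        )
        dominances[assay] = result.r
        per_gene = pd.DataFrame(
            {"gene": result.r.index, "r": result.r.to_numpy(),
             "defined": result.defined.to_numpy()}
        )
        per_gene.to_csv(out / f"dominance_{assay}.tsv", sep="\t", index=False)
        pd.DataFrame({"null_r": result.null}).to_csv(
            out / f"null_{assay}.tsv", sep="\t", index=False
        )
        thresholds = {
            tail: {
                "threshold": cv.threshold,
                "null_count": cv.null_count,
                "observed_count": cv.observed_count,
                "attained": cv.attained,
            }
            for tail, cv in (("positive", result.positive), ("negative", result.negative))
        }
        (out / f"thresholds_{assay}.json").write_text(
            json.dumps({"seed": seed, "max_random_fraction": config.max_random_fraction,
                        **thresholds}, indent=1)
        )
        selected = select_correlated_genes(result.r.dropna(), config.correlation_cutoff)
        (out / f"selected_genes_{assay}.txt").write_text("\n".join(selected) + "\n")
        files += [out / f"dominance_{assay}.tsv", out / f"null_{assay}.tsv",
                  out / f"thresholds_{assay}.json", out / f"selected_genes_{assay}.txt"]

    atac_path = config.path("enrich", "enrichment_ATAC.tsv")
    if atac_path.exists():
        atac = EnrichmentMatrix(
            values=pd.read_csv(atac_path, sep="\t", index_col=0), assay="ATAC"
        )
        for assay, dom in dominances.items():
            assoc = atac_association(dom, atac)
            assoc.index.name = "atac_timepoint"
            path = out / f"atac_association_{assay}.tsv"
            assoc.to_csv(path, sep="\t")
            files.append(path)
    return files


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "oxygen": stage_oxygen,
    "fluxes": stage_fluxes,
    "analysis": stage_analysis,
    "enrich": stage_enrich,
    "dominance": stage_dominance,
}


def run(config: RunConfig, stages: Optional[Sequence[str]] = None) -> Path:
    """Run the requested stages in pipeline order; returns the run directory.

    A stage whose manifest entry is complete and whose outputs exist is
    skipped unless ``config.force``.  The manifest records the config hash,
    seed, package version, per-stage status and output hashes.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s) {sorted(unknown)}")
    config.validate_for(stages)
    config.outdir.mkdir(parents=True, exist_ok=True)

    manifest_path = config.outdir / "run_manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.update(
        {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
        }
    )
    manifest.setdefault("stages", {})

    for stage in STAGES:
        if stage not in stages:
            continue
        prior = manifest["stages"].get(stage, {})
        outputs_exist = prior.get("status") == "complete" and all(
            Path(p).exists() for p in prior.get("outputs", {})
        )
        if outputs_exist and not config.force:
            logger.info("stage %s: up to date, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        files = _STAGE_FUNCS[stage](config)
        manifest["stages"][stage] = {
            "status": "complete",
            "seed": _stage_seed(config.seed, stage),
            "outputs": {str(p): _sha256(Path(p)) for p in files},
        }
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return config.outdir
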