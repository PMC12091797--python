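"""Metabolic network I/O and preparation for flux inference.

Reads SBML genome-scale models (via cobrapy), augments them with the
histone-PTM reaction sets (acetylation via the ATP-citrate-lyase route,
methylation via the methionine cycle) and the glycogen storage reaction,
splits reversible reactions into nonnegative forward/reverse flux
components, and maps gene-expression tables onto per-component weights
through gene-protein-reaction (GPR) rules.
"""

from __future__ import annotations

import ast
import importlib.resources
import io
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "IrreversibleNetwork",
    "ExpressionWeights",
    "GprPolicy",
    "PtmAugmentation",
    "ModelFormatError",
    "read_sbml",
    "write_sbml",
    "load_ptm_augmentation",
    "augment_with_ptm_reactions",
    "split_reversible",
    "expression_to_reaction_weights",
    "parse_reaction_equation",
]


class ModelFormatError(ValueError):
    """Raised when a model file or network definition is malformed."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float
    upper_bound: float
    name: str = ""
    subsystem: str = ""
    gpr: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicNetwork:
    """A stoichiometric network with bounds, subsystems and GPR rules.

    Reaction order is the document order of the source and defines the
    column order of the stoichiometric matrix ``S`` (M metabolites x N
    reactions).
    """

    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_reaction_id: Optional[str] = None
    oxygen_exchange_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ModelFormatError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelFormatError("duplicate reaction ids")
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in met_ids:
                    raise ModelFormatError(
                        f"reaction {r.id!r} references undeclared metabolite {m!r}"
                    )
            if not (r.lower_bound <= r.upper_bound):
                raise ModelFormatError(
                    f"reaction {r.id!r} has lower_bound > upper_bound"
                )
        for attr in ("biomass_reaction_id", "oxygen_exchange_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in set(rxn_ids):
                raise ModelFormatError(f"{attr}={rid!r} is not a reaction in the network")

    @property
    def metabolite_index(self) -> Dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    @property
    def S(self) -> np.ndarray:
        """Stoichiometric matrix, metabolites x reactions, document order."""
        midx = self.metabolite_index
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[midx[m], j] = c
        return S

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index[rid]]
        except KeyError:
            raise KeyError(f"unknown reaction id {rid!r}") from None


# ---------------------------------------------------------------------------
# SBML I/O (cobrapy-backed)
# ---------------------------------------------------------------------------

def read_sbml(
    path,
    biomass_reaction_id: Optional[str] = None,
    oxygen_exchange_id: Optional[str] = None,
) -> MetabolicNetwork:
    """Read an SBML model into a :class:`MetabolicNetwork`.

    Reactions keep document order, bounds, subsystem labels and GPR strings.
    ``biomass_reaction_id`` defaults to the model's objective reaction and
    ``oxygen_exchange_id`` to an exchange named ``EX_o2*`` when present.
    """
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelFormatError(f"could not parse SBML file {path}: {exc}") from exc

    metabolites = [
        Metabolite(m.id, m.name or "", m.compartment or "") for m in model.metabolites
    ]
    # subsystem labels: cobra keeps them on reactions for some encodings and
    # in SBML groups for others (e.g. BiGG models); merge both sources
    group_subsystem: Dict[str, str] = {}
    for grp in getattr(model, "groups", []):
        for member in grp.members:
            group_subsystem.setdefault(getattr(member, "id", ""), grp.name or grp.id)
    reactions = []
    for r in model.reactions:
        if r.lower_bound is None or r.upper_bound is None:
            raise ModelFormatError(f"reaction {r.id!r} is missing flux bounds")
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                name=r.name or "",
                subsystem=r.subsystem or group_subsystem.get(r.id, ""),
                gpr=r.gene_reaction_rule or "",
            )
        )

    if biomass_reaction_id is None:
        obj = [r.id for r in model.reactions if r.objective_coefficient]
        if len(obj) == 1:
            biomass_reaction_id = obj[0]
    if oxygen_exchange_id is None:
        o2 = [r.id for r in model.reactions if r.id.lower().startswith("ex_o2")]
        # prefer the bare o2 exchange over e.g. EX_o2s (superoxide)
        for cand in o2:
            if re.fullmatch(r"ex_o2(_\w+)?", cand.lower()):
                oxygen_exchange_id = cand
                break

    return MetabolicNetwork(metabolites, reactions, biomass_reaction_id, oxygen_exchange_id)


def write_sbml(net: MetabolicNetwork, path) -> None:
    """Write a network as SBML level 3 + fbc (round-trips with read_sbml)."""
    import cobra
    import cobra.io

    model = cobra.Model("ymcflux_model")
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in net.metabolites
    }
    for r in net.reactions:
        rxn = cobra.Reaction(r.id, name=r.name, subsystem=r.subsystem)
        rxn.lower_bound = r.lower_bound
        rxn.upper_bound = r.upper_bound
        model.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr:
            rxn.gene_reaction_rule = r.gpr
    if net.biomass_reaction_id:
        model.objective = net.biomass_reaction_id
    by_subsystem: Dict[str, list] = {}
    for r in net.reactions:
        if r.subsystem:
            by_subsystem.setdefault(r.subsystem, []).append(model.reactions.get_by_id(r.id))
    if by_subsystem:
        from cobra.core import Group

        model.add_groups(
            [Group(re.sub(r"\W+", "_", name), name=name, members=members,
                   kind="partonomy")
             for name, members in by_subsystem.items()]
        )
    cobra.io.write_sbml_model(model, str(path))


# ---------------------------------------------------------------------------
# PTM augmentation
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "-->", "<->")


def parse_reaction_equation(equation: str) -> Dict[str, float]:
    """Parse ``'2 a_c + b_c --> c_c'`` into a stoichiometry mapping.

    Either side may be empty (exchange/demand reactions).
    """
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelFormatError(f"no reaction arrow in equation {equation!r}")
    lhs, rhs = equation.split(arrow, 1)
    stoich: Dict[str, float] = {}

    def _side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.split()
            if not parts:
                continue
            if len(parts) == 2:
                coef, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise ModelFormatError(f"cannot parse term {term!r} in {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    _side(lhs, -1.0)
    _side(rhs, +1.0)
    return stoich


@dataclass
class PtmAugmentation:
    """Reaction sets added on top of the genome-scale model.

    Six acetylation reactions (ATP-citrate-lyase route), ten methylation
    reactions (methionine cycle incl. its exchanges) and the glycogen
    consumption reaction, with designated sink reactions whose fluxes stand
    for histone acetylation (acetyl-CoA use) and methylation (SAM use).
    """

    acetylation: List[Reaction]
    methylation: List[Reaction]
    storage: List[Reaction]
    histone_acetylation_id: str = "HISTAT"
    histone_methylation_id: str = "HISTMT"

    def __post_init__(self) -> None:
        ac_ids = {r.id for r in self.acetylation}
        me_ids = {r.id for r in self.methylation}
        if self.histone_acetylation_id not in ac_ids:
            raise ModelFormatError(
                f"designated acetylation sink {self.histone_acetylation_id!r} "
                "is not among the acetylation reactions"
            )
        if self.histone_methylation_id not in me_ids:
            raise ModelFormatError(
                f"designated methylation sink {self.histone_methylation_id!r} "
                "is not among the methylation reactions"
            )

    @property
    def all_reactions(self) -> List[Reaction]:
        return list(self.acetylation) + list(self.methylation) + list(self.storage)


def load_ptm_augmentation() -> PtmAugmentation:
    """Load the packaged PTM reaction fixture (synthetic reconstruction)."""
    text = (
        importlib.resources.files("ymcflux").joinpath("data/ptm_reactions.tsv").read_text()
    )
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", keep_default_na=False)
    groups: Dict[str, List[Reaction]] = {"acetylation": [], "methylation": [], "storage": []}
    for row in df.itertuples(index=False):
        rxn = Reaction(
            id=row.id,
            stoichiometry=parse_reaction_equation(row.equation),
            lower_bound=float(row.lower_bound),
            upper_bound=float(row.upper_bound),
            name=row.name,
            subsystem=row.subsystem,
            gpr=row.gpr,
        )
        groups[row.tag].append(rxn)
    return PtmAugmentation(groups["acetylation"], groups["methylation"], groups["storage"])


def augment_with_ptm_reactions(
    net: MetabolicNetwork, aug: PtmAugmentation
) -> MetabolicNetwork:
    """Return a new network with the augmentation reactions appended.

    New metabolites referenced by the added reactions are declared with the
    compartment inferred from their id suffix. Raises on any id collision.
    """
    existing = set(net.reaction_index)
    new_rxns = aug.all_reactions
    collisions = [r.id for r in new_rxns if r.id in existing]
    if collisions:
        raise ModelFormatError(
            f"augmentation reaction ids already present in network: {collisions}"
        )
    met_ids = {m.id for m in net.metabolites}
    new_mets: List[Metabolite] = []
    for r in new_rxns:
        for mid in r.stoichiometry:
            if mid not in met_ids:
                comp = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
                new_mets.append(Metabolite(mid, compartment=comp))
                met_ids.add(mid)
    return MetabolicNetwork(
        metabolites=list(net.metabolites) + new_mets,
        reactions=list(net.reactions) + [Reaction(**vars(r)) for r in new_rxns],
        biomass_reaction_id=net.biomass_reaction_id,
        oxygen_exchange_id=net.oxygen_exchange_id,
    )


# ---------------------------------------------------------------------------
# Reversible-reaction splitting
# ---------------------------------------------------------------------------

@dataclass
class IrreversibleNetwork:
    """Nonnegative flux components: one per irreversible reaction, a
    forward/reverse pair per reversible one.  Net parent flux = forward
    - reverse."""

    parent: MetabolicNetwork
    component_ids: List[str]
    parent_reaction_ids: List[str]
    directions: np.ndarray  # +1 forward, -1 reverse
    lb: np.ndarray
    ub: np.ndarray
    reverse_of: Dict[str, str]  # reverse component id -> forward component id

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    @property
    def component_index(self) -> Dict[str, int]:
        return {c: i for i, c in enumerate(self.component_ids)}

    @property
    def S(self) -> np.ndarray:
        """Metabolites x components stoichiometric matrix."""
        Sp = self.parent.S
        ridx = self.parent.reaction_index
        cols = [ridx[p] for p in self.parent_reaction_ids]
        return Sp[:, cols] * self.directions[np.newaxis, :]

    def components_of(self, reaction_id: str) -> List[int]:
        return [
            i for i, p in enumerate(self.parent_reaction_ids) if p == reaction_id
        ]

    def net_fluxes(self, v: np.ndarray) -> Dict[str, float]:
        """Recombine component fluxes into net per-parent-reaction fluxes."""
        net = {r.id: 0.0 for r in self.parent.reactions}
        for i, p in enumerate(self.parent_reaction_ids):
            net[p] += self.directions[i] * v[i]
        return net


def split_reversible(net: MetabolicNetwork) -> IrreversibleNetwork:
    """Split each reversible reaction into nonnegative forward and reverse
    components; reverse stoichiometry is the negation of the parent's."""
    comp_ids: List[str] = []
    parents: List[str] = []
    directions: List[float] = []
    lbs: List[float] = []
    ubs: List[float] = []
    reverse_of: Dict[str, str] = {}
    for r in net.reactions:
        fwd_id = r.id
        comp_ids.append(fwd_id)
        parents.append(r.id)
        directions.append(+1.0)
        lbs.append(max(0.0, r.lower_bound))
        ubs.append(max(0.0, r.upper_bound))
        if r.lower_bound < 0:
            rev_id = r.id + "__rev"
            comp_ids.append(rev_id)
            parents.append(r.id)
            directions.append(-1.0)
            lbs.append(max(0.0, -r.upper_bound))
            ubs.append(-r.lower_bound)
            reverse_of[rev_id] = fwd_id
    return IrreversibleNetwork(
        parent=net,
        component_ids=comp_ids,
        parent_reaction_ids=parents,
        directions=np.asarray(directions),
        lb=np.asarray(lbs),
        ub=np.asarray(ubs),
        reverse_of=reverse_of,
    )


# ---------------------------------------------------------------------------
# Expression weights through GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprPolicy:
    """How GPR boolean rules combine gene expression values.

    AND (subunits of one complex) takes the minimum member value; OR
    (isoenzymes) sums the alternatives.  Reactions with no rule, or none of
    whose genes are measured, receive the mean of all mapped weights; all
    weights are floored at a pseudocount ``pseudocount_scale`` x (mean
    positive expression value).
    """

    pseudocount_scale: float = 1e-6


@dataclass
class ExpressionWeights:
    """Per-flux-component nonnegative weights g with their GPR provenance."""

    g: np.ndarray
    component_ids: List[str]
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.g <= 0):
            raise ValueError("expression weights must be strictly positive")


def _eval_gpr_node(node: ast.AST, values: Mapping[str, float]) -> Optional[float]:
    """Evaluate a GPR AST: AND -> min, OR -> sum; unmeasured genes are
    skipped within a rule, a fully-unmeasured rule evaluates to None."""
    if isinstance(node, ast.Expression):
        return _eval_gpr_node(node.body, values)
    if isinstance(node, ast.Name):
        return values.get(node.id)
    if isinstance(node, ast.BoolOp):
        parts = [_eval_gpr_node(c, values) for c in node.values]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        if isinstance(node.op, ast.And):
            return min(parts)
        return sum(parts)
    raise ModelFormatError(f"unsupported GPR syntax node {type(node).__name__}")


def evaluate_gpr(rule: str, values: Mapping[str, float]) -> Optional[float]:
    """Evaluate one GPR rule string against a gene->expression mapping."""
    if not rule or not rule.strip():
        return None
    from cobra.core.gene import GPR

    gpr = GPR.from_string(rule)
    if gpr.body is None:
        return None
    return _eval_gpr_node(gpr.body, values)


def expression_to_reaction_weights(
    irr: IrreversibleNetwork,
    fpkm: Mapping[str, float],
    policy: GprPolicy = GprPolicy(),
) -> ExpressionWeights:
    """Map a gene->FPKM table to one strictly positive weight per component.

    Forward and reverse components of a reaction carry the same weight.
    """
    fpkm = dict(fpkm)
    if not fpkm:
        raise ValueError("empty expression table")
    if any(v < 0 for v in fpkm.values()):
        raise ValueError("FPKM values must be nonnegative")

    per_reaction: Dict[str, Optional[float]] = {}
    for r in irr.parent.reactions:
        per_reaction[r.id] = evaluate_gpr(r.gpr, fpkm)

    mapped = [v for v in per_reaction.values() if v is not None]
    fill = float(np.mean(mapped)) if mapped else float(np.mean(list(fpkm.values())))
    positive = [v for v in fpkm.values() if v > 0]
    eps = policy.pseudocount_scale * (float(np.mean(positive)) if positive else 1.0)
    if eps <= 0:
        eps = policy.pseudocount_scale

    g = np.empty(irr.n_components)
    provenance: Dict[str, str] = {}
    for i, (cid, pid) in enumerate(zip(irr.component_ids, irr.parent_reaction_ids)):
        val = per_reaction[pid]
        if val is None:
            g[i] = max(fill, eps)
            provenance[cid] = "fill:mean-of-mapped"
        else:
            g[i] = max(val, eps)
            provenance[cid] = "gpr"
    return ExpressionWeights(g=g, component_ids=list(irr.component_ids), provenance=provenance)


def read_fpkm_table(path) -> pd.DataFrame:
    """Read a ``gene<TAB>t1...tK`` FPKM table into genes x timepoints."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty expression table {path}")
    return df
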