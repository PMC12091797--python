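# Methods

`ymcflux` links metabolic flux dynamics to histone-modification dynamics in
the yeast metabolic cycle (YMC), the robust respiratory oscillation of
*S. cerevisiae* in glucose-limited chemostat culture. The pipeline has four
quantitative layers: (1) oxygen uptake rates from a dissolved-oxygen trace,
(2) transcriptome-conditioned maximum-entropy inference of the genome-scale
fluxome at each time point, (3) extraction of the production fluxes of the
histone-PTM cosubstrates acetyl-CoA and SAM, and (4) per-gene "metabolic
dominance" statistics correlating those fluxes with promoter enrichment of
H3K9Ac, H3K4me3 and ATAC accessibility.

## Oxygen uptake from dissolved oxygen

A gas–liquid mass balance on the dissolved-oxygen fraction DO = c/c* in a
chemostat gives

    dDO/dt = kLa (1 − DO) − qO2 X / c*
    qO2    = (c*/X) [ kLa (1 − DO) − dDO/dt ]

with kLa the volumetric transfer coefficient (h⁻¹), c* the O₂ saturation
concentration (mmol L⁻¹), X the biomass concentration (g L⁻¹) and qO2 the
specific uptake rate (mmol gDW⁻¹ h⁻¹). The exchange flux is vO2 = −qO2
(negative = consumption).

dDO/dt is estimated with a Savitzky–Golay derivative of order 2. Because
YMC sampling grids are irregular, the filter is implemented as local
polynomial least squares in real time coordinates (window recentred at each
sample; one-sided windows at the ends) rather than the uniform-spacing
convolution form. The window defaults to 5 points — the smallest odd window
exceeding the polynomial order that still smooths a 15–16-point series
without flattening phase transitions — and is configurable.

Defaults: kLa = 225 h⁻¹ (a comparable reactor configuration) and dilution
rate 0.1 h⁻¹ (the chemostat growth rate). c* = 0.236 mmol L⁻¹ (O₂
saturation in water at 30 °C) and X = 5 g L⁻¹ are assumptions, not
measurements; both only rescale qO2 linearly. DO values outside [0, 1]
are clipped with a warning (instrument noise), not rejected.

## Maximum-entropy fluxome inference

The flux polytope is 𝒫 = {v ≥ 0 | Sv = 0, LB ≤ v ≤ UB} on the split
network: every reversible reaction contributes a forward and a reverse
nonnegative component (bounds [max(0, LB), max(0, UB)] and
[max(0, −UB), −min(0, LB)]); net flux = forward − reverse. Given expression
weights g > 0, the inferred fluxome maximizes

    Hg(v) = − Σᵢ (vᵢ/V) log[ (vᵢ/V) / (gᵢ/G) ],   V = Σⱼ vⱼ, G = Σⱼ gⱼ,

i.e. it minimizes the Kullback–Leibler divergence of the flux-fraction
distribution from the expression distribution; Hg(v) ≤ 0 with equality iff
v ∝ g. Weights come from gene–protein–reaction rules: AND (complex
subunits) takes the minimum member FPKM, OR (isoenzymes) sums; forward and
reverse components share their reaction's weight. Reactions without a rule
or without any measured gene receive the mean of the mapped weights — a
neutral prior that lets stoichiometric feasibility govern them. All weights
are floored at 10⁻⁶ × (mean positive FPKM) so the objective stays finite
while rankings are preserved.

The objective depends only on flux fractions, so the absolute scale is
pinned physiologically: the biomass flux v_μ is fixed to the observed
growth rate w_μ, and the ratio constraint

    v_μ − (w_μ / w_o2) v_o2 = 0

ties it to the measured oxygen uptake magnitude w_o2, where v_o2 is the
uptake-direction (reverse) component of the oxygen exchange reaction.
Together these make v_o2 equal the measured uptake, giving absolute
mmol gDW⁻¹ h⁻¹ units.

Numerics: the program is solved with scipy's interior trust-region method
(`trust-constr`) with the analytic gradient
∂KL/∂vₖ = (1/V)[log(pₖ/qₖ) − KL]; flux components are floored at
δ = 10⁻¹⁰ inside the logarithm and reported fluxes below δ truncate to 0.
Optimality tolerance 10⁻⁸, step tolerance 10⁻¹²; after convergence the
point is polished by a minimum-norm least-squares projection onto the
equality constraints (the correction is within solver tolerance, so bounds
stay intact), leaving |Sv| residuals at the 10⁻¹⁵ level. The initial point
is the expression vector scaled into the bounds — deterministic, so
repeated solves are bit-identical; multi-start agreement (tested to 10⁻⁶
relative) reflects the strict convexity of the objective on the
scale-pinned constraint set. Infeasibility is diagnosed in stages —
stoichiometry + bounds first, then the physiology constraints — so error
messages name the violated constraint class.

No additional uptake bounds (e.g. glucose) are imposed beyond the model's
own; the physiology constraint is the only data-driven restriction.

## Fluxome post-processing

Two normalizations are kept strictly separate and each output declares
which was applied. Column normalization (analysis scale) divides every net
flux by the sum of flux magnitudes at that time point, so magnitudes sum
to 1. Row normalization (display only) scales each reaction by its own peak
magnitude. Pathway fractions are mean |flux| over the pathway's reactions
divided by the total network |flux| at that time point — the fraction of
metabolic flux transiting the pathway. Absolute pathway fluxes (e.g.
oxidative phosphorylation) are recovered by rescaling each time point's
fluxome so the oxygen exchange magnitude equals the measured |vO2|, then
averaging (unweighted) over each phase's time points. Pathway magnitudes
use net fluxes (|forward − reverse|), not summed directional fluxes. Sugar
consumption is the positive part of the consuming direction: max(0, −net)
for exchanges, max(0, net) for degradation reactions.

Cosubstrate production fluxes are read off the designated sink reactions of
the augmented model — the histone-acetylation sink (acetyl-CoA use) and the
histone-methylation sink (SAM use) — on the column-normalized scale.

## Model augmentation

The genome-scale model is augmented with 6 acetylation reactions (the
ATP-citrate-lyase route: citrate cleavage, nuclear diffusion of
acetyl-CoA/CoA, a histone acetyltransferase step and demands), 10
methylation reactions (the methionine cycle: methionine
adenosyltransferase, histone methyltransferase, SAH hydrolysis, methionine
regeneration, plus exchanges for its metabolites) and a lumped glycogen
consumption reaction (trehalose is already present in iMM904-class models;
glycogen is not). The shipped stoichiometries are a plausible synthetic
reconstruction, clearly flagged as such in `data/ptm_reactions.tsv`; users
with a curated inventory can substitute their own table in the same format.
Augmentation validates id uniqueness (a second application raises a
collision error) and declares any new metabolites.

## Promoter enrichment and time-grid alignment

Promoters are ±500 bp (configurable) around the strand-aware TSS (gene
start on +, gene end on −), in 0-based half-open coordinates, clipped at
chromosome boundaries; GFF3 input (1-based closed) is converted on read.
Enrichment is length-normalized mean coverage: Σ(value × overlap)/window
width, so boundary-clipped promoters remain comparable. Overlapping
promoters of neighbouring genes are scored independently and no input/IgG
correction is applied. A `scale_per_million` flag depth-normalizes the
track first (off by default).

Assays sampled on different grids are aligned by averaging designated
column sets — in the study conditions, RNA-seq time points 10 and 11 and
ChIP-seq time points 13 and 14 — yielding 15 matched time points.

## Dominance statistics

Metabolic dominance of a gene is the Pearson correlation (n = 15) between
its mark-enrichment series and the cosubstrate flux series. Zero-variance
genes are flagged undefined (NaN) and excluded from counts. The null
shuffles both series independently per gene (one rep per gene by default,
matching the null to the observed set size; configurable upward) with a
seeded generator, making runs bit-reproducible.

Critical values scan the observed values in each tail (one-tailed: above
for positive, below for negative) for the least extreme threshold at which
(#null at-or-beyond)/(#observed at-or-beyond) < the declared random
fraction (default 10%, strict inequality). Because that ratio is a
false-discovery estimate, a candidate only qualifies when at least
`min_observed` (default 10) observed genes lie beyond it; without this
guard the single most extreme gene always produces a vacuous 0/1 ratio and
pure-noise inputs would "attain" thresholds. Study-scale tails (hundreds to
thousands of genes) are far above the floor. Gene selection for functional
analysis uses dominance ≥ 0.7, inclusive.

ATAC association regresses per-time-point promoter accessibility on
dominance over shared genes (exact-id join; an alias map can be supplied),
reporting Pearson r, −log₁₀ of the two-sided t-approximation p-value, and
the least-squares slope. Constant columns are reported missing with a
warning.

## Synthetic study conditions

The generator emulates every input the pipeline consumes, under the study
conditions: 15 time points over one 2.5 h cycle, phases OX (short), RB, RC;
kLa = 225 h⁻¹, growth 0.1 h⁻¹; a planted oscillatory qO2 between 2 and
8 mmol gDW⁻¹ h⁻¹ peaking in OX. The DO trace is forward-integrated from
the planted qO2 at high resolution (RK45, rtol 10⁻⁹) and sampled onto the
grid. The "mini-cell" network (22 reactions) carries glucose, oxygen and
methionine exchanges, lumped glycolysis/fermentation/respiration, glycogen
and trehalose storage, biomass, and designated acetylation/methylation
sinks, with subsystem labels and GPRs. Expression profiles are log-normal
oscillations keyed to the network's genes, emitted on a 16-point grid whose
duplicated columns exercise the averaging alignment. Enrichment matrices
plant per-gene correlation ρ to the realized cosubstrate flux series as
ρ·z(flux) + √(1−ρ²)·noise on standardized scales, affinely mapped to
nonnegative units; ground truth ρ is returned alongside. The default
scenario plants ρ = 0.8 in 60 of 300 genes.

What the generator does **not** emulate: read-level noise, peak structure
and background in real ChIP/ATAC coverage; genome-realistic coordinates
(two toy chromosomes only); regulatory structure beyond a single planted
correlation; protein-level effects that decouple FPKM from enzyme
abundance. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure at the stated noise
level — not that real YMC data would yield the same effect sizes.

## Problem sizes and runtime

The default test and acceptance workloads use the mini-cell network
(≈25 flux components), 15 solver calls per pipeline run, 300–1000 genes
for dominance statistics, and 10³–10⁴ permutation draws for the
distributional checks; the full suite runs in well under a minute of
solver time. The same code paths accept genome-scale SBML models — solver
cost grows with component count, and the interior-point solve on a
1577-reaction model is substantially slower but structurally identical.

## Known limitations

- The mini-cell regression baseline is a frozen record of the solver's own
  converged output (uniqueness verified by multi-start); exhaustive
  grid-search oracles are only computable on the ≤3-free-dimension toys.
- c* and X defaults are assumptions; absolute qO2 values scale with them.
- GPR semantics (min/sum) are the standard complex/isoenzyme convention;
  other conventions (e.g. geometric mean) would shift weights.
- The dominance null permutes time points, which destroys autocorrelation;
  with n = 15 smooth series the null is mildly optimistic about
  independence — an inherent property of the ratio criterion itself.
- DO probe dynamics are not deconvolved from the trace.
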