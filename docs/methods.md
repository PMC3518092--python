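# Methods

## Flux balance analysis

The network is a stoichiometric matrix **S** (metabolites × reactions);
entry (i, j) is the signed coefficient of metabolite i in reaction j
(negative = consumed). FBA assumes pseudo-steady state (S·v = 0) and
optimizes a linear objective cᵀv — by convention the biomass reaction,
whose flux is interpreted as the specific growth rate (h⁻¹) — over box
bounds α ≤ v ≤ β in mmol·gDCW⁻¹·h⁻¹. The LP is solved with HiGHS
(scipy.optimize.linprog) at primal/dual feasibility tolerance 1e-9.
Fluxes with magnitude below 1e-6 are treated as zero wherever a
discrete call is made (essentiality, activation); the gap between the
two tolerances separates genuine zeros from round-off. The solver
returns an optimal vertex; nothing downstream relies on which vertex of
a degenerate optimal face is returned (FVA explicitly explores the whole
face).

Assumptions inherited from the formalism: mass balance only (no
regulation, no kinetics, no thermodynamic feasibility beyond
irreversibility flags), a fixed biomass composition, and exchange
reactions as the only boundary terms (negative exchange flux = uptake).

## Bounds, media, maintenance

Default bounds are ±1000 (reversible) or [0, 1000]; a reaction is
reversible iff its lower bound is negative. A medium is a map from
exchange ids to (lb, ub); applying it closes uptake on every exchange
not listed while leaving secretion open.

Maintenance energy: the ATP-hydrolysis maintenance reaction is pinned to
exactly NGAM (both bounds), and the biomass reaction's ATP terms are set
so the growth-associated demand equals GAM per unit biomass. NGAM is
per hour (flux units); GAM is per gram biomass. Estimation regresses
ATP production (uptake × ATP yield per substrate, default 18.5 for fully
oxidized glycerol) on dilution rate: slope = GAM, intercept = NGAM; at
least two distinct dilution rates are required, and negative fitted
values are clamped to zero.

## Dead-end classification

Per metabolite instance (id + compartment): *producible* = appears with
positive coefficient in some irreversible reaction or participates in
any reversible one; *consumable* analogously. A participating
metabolite that is not both is a dead-end. The dead-end test runs
first; non-dead-ends touching only reversible reactions are labelled
`oneSub_Product` (exactly one) or `ManySub_Product` (two or more) as
curation cues. Dead-ends whose base id (compartment tag stripped)
exists in more than one compartment are labelled `may_need_transport`
instead of `is_deadend`, keeping the five labels mutually exclusive
while both kinds count as dead-ends.

Exchange reactions are excluded by default (configurable): an open
exchange makes its metabolite trivially producible and consumable, and
dead-end detection is meant to expose gaps in *internal* pathways.
Consequently the boundary species themselves (metabolites touched by an
exchange) are labelled `ok` — the environment supplies and absorbs them.

## Balance audit and redundancy

Element deficits are Σ coefficient × element count over a reaction;
charge analogously. Formula symbols are an uppercase letter plus
lowercase run, so non-standard moieties (R groups, polymer units) ride
along as opaque conserved tokens. Exchange and biomass reactions are
intrinsically one-sided and are skipped; missing formulas make a
reaction unauditable, not failed. A deficit of exactly k hydrogens with
matching charge deficit triggers the dropped-proton fix suggestion.

Duplicates: stoichiometric vectors normalized by the coefficient of the
lexicographically first metabolite, compared within 1e-9 — this catches
scalar multiples and direction flips. Isolated reactions are those all
of whose metabolites occur in no other reaction.

## Minimal media and screening

Greedy elimination in deterministic lexicographic order over candidate
exchanges: open all, close one at a time, keep closed iff growth stays
above the threshold (default 1e-6). The result is verified by a final
solve and is locally minimal; global minimum cardinality is not claimed
(the test suite checks agreement with exhaustive enumeration on small
candidate pools, where the minimal set is unique). Designated free
exchanges (e.g. water, CO₂, protons) can be exempted from elimination.
Screened substrates get lb = −20 (the default carbon uptake setting);
missing exchange reactions are auto-added, but transporters are not
(adding a transporter is a curation decision) unless a flag enables
naive diffusion for toy models.

## Essentiality and knockout ranking

GPR rules are infix and/or trees, case-insensitive, `and` binding
tighter. Deleting gene set G sets those leaves False and every other
gene True; reactions whose rule evaluates False get both bounds pinned
to zero; rule-less reactions are never disabled. Classification
thresholds on the growth ratio r = Z_ko/Z_wt: essential r < 1e-6,
non-essential r > 1 − 1e-3, else partially essential. Infeasible
knockout LPs count as zero growth.

FVA at fraction γ adds cᵀv ≥ γ·Z_max and solves 2n LPs. For mutant
strains the floor uses the *mutant's own* optimum: after a knockout the
wild-type optimum is generally unreachable, and the interesting question
is how the mutant redistributes flux at its own best growth. γ defaults
to 1.0 (strain-design setting).

The SD score for gene j averages, over reactions i whose wild-type FVA
bounds are both nonzero (|bound| > 1e-9),

    Δmax_i = |v_max,mut − v_max,wt| / |v_max,wt|
    Δmin_i = |v_min,mut − v_min,wt| / |v_min,wt|
    SD_j   = mean_i (Δmax_i + Δmin_i) / 2

with the count of usable reactions reported as n_used. Averaging over
the computable subset (rather than all n reactions) is a deliberate
choice: reactions with a zero wild-type bound have no well-defined
relative deviation and are routed to Group I/II discovery instead.
The formula sits behind one function so alternative aggregations can be
swapped in. Group I pairs are reactions with |v_min,wt| ≤ 1e-9 and
|v_min,mut| > 1e-6 (Group II for maxima); the two thresholds again
separate numerical noise from genuine activation.

## Synthetic networks

The generator's core template is a two-compartment network: glucose
exchange and transport, two parallel glycolysis-like routes (the
efficient one yields 2 ATP + 2 pyruvate per glucose, the bypass 1 ATP +
2 pyruvate), respiration (3 ATP per pyruvate), a pinned ATP-maintenance
drain, CO₂ export and a biomass drain consuming b_p pyruvate + GAM ATP.
Default parameters: uptake 10, GAM 2, NGAM 0.5, b_p 1 (template units).
The growth optimum has the closed form

    Z* = min( (8u − NGAM)/(GAM + 3·b_p),  2u/b_p ),   feasible iff 8u ≥ NGAM

derived by eliminating the pyruvate and ATP balances by hand; the
generator requires GAM > b_p, which keeps the closed form (and the
respiration knockout's zero-growth ground truth) exact. Metabolite
formulas use a synthetic element alphabet chosen so every internal
reaction balances by construction.

Randomized models grow from this core: reversible appendix chains
(exercise the oneSub/ManySub labels without enabling flux), produce-only
dead-end branches, isolated two-metabolite fragments (each necessarily
adds two dead-ends, which the ledger records), scaled duplicate copies
(coefficients ×2, same GPR so essentiality truth is untouched; only
flux-safe targets are copied so FVA ground truth stays derivable), extra
AND-genes on the transporter (planted essentials) and an optional
respiration isozyme (planted OR-redundancy). The seed fully determines
the artefact; the ledger is complete by construction — the test suite
asserts zero false positives and negatives for every audit.

What the generator does *not* emulate: realistic network size (hundreds
of reactions), realistic biochemistry or cofactor diversity, blocked
cycles and thermodynamically infeasible loops, noisy or conflicting
annotation, and alternate-optima degeneracy beyond the single planted
bypass. Passing the recovery benchmarks therefore demonstrates
correctness of the algorithms under clean, known truth — not predictive
accuracy on a real reconstruction, which depends on curation quality.

Chemostat simulation: uptake(D) = (NGAM + GAM·D)/yield with
multiplicative Gaussian noise of relative sd σ (default truth GAM
86.7881, NGAM 7.8625, yield 18.5; 20 dilution rates spanning
0.02–0.25 h⁻¹, σ = 2 %).

## Validation oracles

`fluxkit.validation` provides brute-force ground truth that shares no
code with the simplex path: every vertex of {S·v = 0, lb ≤ v ≤ ub} has
n − rank(S) coordinates at bounds, so exhaustive enumeration over
coordinate subsets and bound assignments (dense linear algebra only)
yields the exact LP optimum and, with the objective floor folded in as
a bounded slack column, exact FVA intervals. This is exponential and
restricted to ≤14 reactions; the acceptance checks compare the LP path
against it on 100 random small polytopes (agreement within 1e-8) and on
the core template.

## Numerical and design choices

* LP tolerance 1e-9, reported-zero 1e-6, duplicate comparison 1e-9,
  FVA activation 1e-6 — see above for the rationale of each gap.
* Greedy-elimination order, gene iteration order and ranking tie-breaks
  are lexicographic, making every report deterministic; pipeline reports
  print floats at 6 significant digits so re-runs are byte-identical.
* Census convention: reversible + irreversible counts partition the
  non-transport, non-exchange reactions; each reaction is assigned to a
  single compartment (the outermost it touches, e > c > m) so
  per-compartment counts partition the reaction list.
* Compartment-restricted connectivity reports the species of that
  compartment; a species' count includes every reaction touching it,
  transport included.
* SBML ids are sanitized (`M_`/`R_`/`G_` prefixes, compartment suffix);
  the tabular dialect is the lossless interchange format for ids outside
  the SBML identifier alphabet.

## Known limitations

No MOMA/ROOM-style quadratic knockout models, no double-deletion scans,
no thermodynamic or regulatory constraints, no gap-filling — the audits
report problems, the curator fixes them. The greedy minimal medium can
return a non-minimum-cardinality set on networks with interchangeable
nutrient pairs. Vertex-enumeration validation does not scale past toy
networks; at genome scale correctness rests on the HiGHS solver and on
the invariant checks (steady-state residual, bound satisfaction,
monotonicity, FVA nesting) that run at any size.
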