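# Methods

This note records the models implemented in misokit, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## Reaction thermodynamics

The engine evaluates ΔGr = ΔGr° + RT·ln Qr for redox reactions written over
named chemical species.  ΔGr° = Σ νᵢ·ΔGf°ᵢ is formed from a pinned species
table (`misokit/data/species_dg0.tsv`) whose 25 °C formation energies come
from the NBS thermochemical tables and standard aquatic-chemistry
compilations; ferrihydrite is treated compositionally as Fe(OH)₃ with the
free energy of amorphous ferric hydroxide (−699 kJ/mol).  Any table with the
same columns may be substituted, so refined mineral free energies can be
tested without code changes.  Temperature enters only through the RT term;
no temperature correction of ΔGf° is attempted, so results are meaningful
near 25 °C.

Activities: a(H⁺) = 10^−pH, a = 1 for water and solids, and
a = γ·C/C° (C° = 1 M) for dissolved ions.  γ defaults to the Davies
equation, log₁₀γ = −0.509·z²(√I/(1+√I) − 0.3I), adequate up to roughly
seawater ionic strength (0.7 M); a (charge, I)→γ override table takes
precedence when tabulated coefficients are preferred.  The reaction quotient
is accumulated in log space so the extreme quotients produced by ν(H⁺) = −15
remain exact.

The four preset reactions are the balanced forms forced by element, charge
and electron bookkeeping:

* `reaction1`: HS⁻ + 8 Fe(OH)₃ + 15 H⁺ → SO₄²⁻ + 8 Fe²⁺ + 20 H₂O (8 e⁻)
* `reaction2`: HS⁻ + 2 Fe(OH)₃ + 5 H⁺ → S⁰ + 2 Fe²⁺ + 6 H₂O (2 e⁻)
* `reaction3`: S₂O₃²⁻ + 8 Fe(OH)₃ + 14 H⁺ → 2 SO₄²⁻ + 8 Fe²⁺ + 19 H₂O (8 e⁻)
* `formate`: HCOO⁻ + 2 Fe(OH)₃ + 5 H⁺ → CO₂ + 2 Fe²⁺ + 6 H₂O (2 e⁻)

Reactions are written with HS⁻; its activity is total dissolved sulfide
times the HS⁻ fraction from the diprotic speciation (pKa 7.04 / 11.96).  pH
sweeps therefore hold *total* sulfide fixed and let speciation vary — the
alternative (holding HS⁻ activity fixed) is obtainable by passing custom
conditions keyed directly on HS⁻-free scenarios, but the speciated
convention is the default because the speciation computation exists for
exactly this purpose.  Environmental presets: marine (I = 0.7 M, sulfide
100 µM, sulfate 28 mM, thiosulfate 1 µM, Fe²⁺ 10 µM) and freshwater
(I = 0.001 M, sulfate 100 µM, otherwise identical), both at 298.15 K.  The
default sweep grid is 201 points over pH 5–10.

## Ortholog-clade calling and model calibration

A clade is called on a rooted, bootstrap-labelled tree when (1) its support
is strictly greater than the cut-off (default 70; "over 70%" is read as
> 70), (2) it contains at least one biochemically verified ingroup tip and
no verified outgroup tip, and (3) its context is consistent: at least 80%
(configurable) of the neighbourhood-tagged members share a gene-context
label with the verified ingroup member(s), and no member carries a trait
label set disjoint from the ingroup trait set.  Criterion 3 is a majority
rule because context "consistency" is inherently qualitative; the fraction
is a tunable parameter rather than a hidden constant.  When nested nodes
all satisfy the criteria only the most inclusive one is reported, since all
descendants of a called clade are regarded as functional orthologs.
Unlabelled internal nodes are never called.  Calls are invariant to tip
order; rerooting along branches outside called clades does not change
memberships.

Gathering thresholds are chosen from candidate cut-points (midpoints
between adjacent distinct scores plus one sentinel beyond each extreme) by
maximizing Youden's J = sensitivity + specificity − 1, with ties resolved
toward the higher threshold to favour specificity.  J-maximization is one
of several defensible readings of "optimizes the sensitivity and
specificity"; it is documented and isolated in a single function so an
F-score criterion can be swapped in.  A hit passes at score ≥ threshold
(gathering-threshold semantics).  Inseparable inputs return the degenerate
J = 0 operating point instead of raising, so batch calibration over many
models does not abort on one pathological score set.

Module completeness is the fraction of satisfied top-level steps of the
logic expression (space = AND between steps, comma = OR, `+` required
complex component, `-` optional component).  A module is present iff all
listed diagnostic genes are detected (configurable to "any") AND
completeness is strictly greater than 0.70.

## Haem-motif screen

CXnCH motifs (n = 2–5) are counted by a non-overlapping, leftmost,
shortest-spacer-first regex scan; positions are 1-based.  The ambiguity
residue X may occupy spacer positions but never matches the anchoring C or
H.  Multi-haem cytochrome (MHC) means strictly more than one CXnCH motif;
extracellular-EET candidacy requires at least four of the short-spacer
CXXCH motifs *and* outer-membrane or extracellular localization — two
deliberately distinct motif definitions, both configurable.  Proteins with
unknown localization are reported indeterminate, never positive.
Localization is consumed as an external annotation column; no predictor is
run.

## Incubation analytics

Sulfide decay is fitted as C(t) = C₀e^(−kt) by nonlinear least squares with
k ≥ 0, seeded from a log-linear regression (which makes noiseless recovery
exact to machine precision).  No plateau term is included by default — the
model is pure first order.  Growth rates are the OLS slope of
ln(N_t/N₀) versus time; the fit window defaults to the full series and can
be restricted to an apparent exponential phase.  Fits are per replicate with
a mean ± SD summary, matching triplicate experimental designs.  Control
correction is Δ(t) = (T(t)−T(0)) − (C(t)−C(0)) with optional linear
interpolation onto the treatment grid; negative deltas are preserved.
Predicted Fe(II):product ratios come solely from the balanced reaction's
coefficients (8 for sulfide → sulfate, 2 for the formate couple), so the
stoichiometry test is consistent with the balance checker by construction.
Per-cell rates convert µM over hours at a cell density to fmol cell⁻¹ h⁻¹
(1 µM = 10⁶ fmol/ml).

## Isotope statistics

Atom% per ROI is 100·b/(2a+b) with a = ¹²C₂⁻ and b = ¹²C¹³C⁻ counts; the
reported counting error is σ = √(a²b + b²a)/(2a+b)² (fractional scale,
×100 next to atom%).  A cell is enriched iff its value strictly exceeds the
control mean + 3 control SD (sample, n−1) and 3σ_Pois is strictly smaller
than its distance from the control mean.  Control statistics pool all
supplied control ROIs.

**Known limitation.**  The conventional σ formula above is exactly half the
delta-method standard deviation of the ratio b/(2a+b) under independent
Poisson (or fixed-total multinomial) counting: the partial derivatives
∂/∂a = −2b/(2a+b)² and ∂/∂b = 2a/(2a+b)² each carry a factor 2 that the
formula omits, and simulation confirms empirical SD = 2σ to three digits.
The formula is retained as the field's reported convention — the package
validates the factor-2 relation in its test suite rather than silently
"correcting" the screen — but users should note that the enrichment
criterion 2 is effectively a 1.5σ counting gate, slightly more permissive
than a nominal 3σ test.  At typical ROI depths (10⁵ counts) this has no
practical effect because criterion 1 (biological control spread) dominates;
the null false-positive rate measured on simulated control-vs-control data
remains well under 1%.

## Synthetic data

Noise models: multiplicative lognormal (mean-one) for concentrations and
cell densities, Poisson for ion counts, Gaussian for bit scores.  All
generators take one integer seed (NumPy `default_rng`) and return planted
truth; identical seed and configuration give byte-identical output.

Defaults mirror the study conditions: growth at 0.288 day⁻¹ (the 1 mM
sulfide + ferrihydrite condition), daily counts over 4 days, triplicates,
10% noise; sulfide spike-chase sampling at 2, 10, 20, 35, 50 and 70
minutes with a default rate of 3 h⁻¹, fast enough to consume most of a
1 mM spike within the window (a slow rate on this short grid would be
unidentifiable by design, and the decay-bias recovery test is accordingly
run at the fast kinetics the schedule was built for); product accumulation
at the 1:8 sulfate:Fe(II) ratio; ROI counts at natural abundance (1.1
atom%) versus 5 atom% labelled at 10⁵-count depth.  Tree generation places
high supports (85–100) inside planted clades and low supports (30–70) on
backbone joins, so planted clades are exactly the maximal callable ones;
score classes are exercised at d′ = 4 for the clean-recovery property,
where the expected Youden operating point (Φ(2) ≈ 0.977) clears the 0.95
bar (at d′ = 3 it would sit at Φ(1.5) ≈ 0.93 by construction).

What passing tests show: the estimators recover parameters under the
stated noise models, and the screens/callers reproduce planted truth
exactly.  What they do not show: robustness to structured real-data
effects — phylogenetic correlation of supports, compositional bias of real
proteomes, instrument drift, or deviations from first-order kinetics.

## Problem sizes

The default test and acceptance runs use 500-simulation recovery studies,
10⁴-draw error-propagation checks, ≤ 12-tip trees for exhaustive clade
verification, ≤ 100-score sets for exhaustive ROC verification, 100-protein
proteomes and a one-off 10⁴-tip tree round-trip; the whole suite completes
in well under a minute on one core.
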