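# Methods

## Stochastic engine

The simulator is Gillespie's direct method over integer copy numbers: the
propensity of reaction j is aⱼ = cⱼ·hⱼ where hⱼ is the exact number of
distinct reactant combinations (∏ᵢ C(Xᵢ, νᵢ); plain Xᵢ for first-order,
binomial coefficients for stoichiometric coefficients ≥ 2; zero-order
reactions have hⱼ = 1). The waiting time is drawn from Exp(a₀), a₀ = Σaⱼ,
and the firing index proportionally to aⱼ. a₀ = 0 is a regular halt, not
an error.

Two extensions support the transcription/translation network:

* **Immediate reactions** are logical rules, not kinetic events: whenever
  every trigger species holds at least its trigger coefficient, the rule
  fires instantly, consuming the trigger and emitting its products.
  After every kinetic firing and every timed action, immediates are
  scanned in declaration order; each firing rescans from the first
  declaration, and the cascade runs to quiescence before the clock moves.
  Declaration order is therefore the deterministic tie-break between
  simultaneously satisfiable immediates, and it round-trips through the
  text format. A cascade exceeding a configurable cap (default 10⁶
  firings) aborts with a model error — that signature almost always means
  an immediate replenishes its own trigger, which the validator flags
  statically.
* **Timed control actions** add or remove molecules, or replace a rate
  constant, at a prescribed time. When the next sampled waiting time
  would cross an event time, the draw is discarded and the clock is set
  to the event time; by memorylessness of the exponential this is exact.
  Events sharing a timestamp apply in declaration order, with immediate
  quiescence re-established after each — the scheduling convention is
  ours, chosen for determinism.

Trajectories are sampled last-value-carried-forward onto a fixed grid
(`sample_dt`), together with cumulative per-reaction firing counters;
this bounds output size for multi-million-event runs while keeping every
conservation identity exact at the sample points. The inner loop is
numba-compiled; the RNG is seeded once per run, so a (model, seed) pair
gives a bit-identical trajectory. Replicate i of a set uses seed
root + i.

Propensities are recomputed in full each step (O(R) with R ≈ 160 for the
default network); at ~10⁶ events per vesicle-hour this costs a second or
two per run, which we preferred over the bookkeeping complexity of a
dependency-graph (next-reaction) scheme.

## Network construction

The template is discretized into elongation sites of 80 bp. The default
gene is 720 bp — GFP's ≈239 codons rounded to a multiple of 80 — giving
9 sites of ≈27 codons; a non-multiple length keeps ⌊L/80⌋ sites and
absorbs the remainder into the last site's incorporation counts.

**Transcription.** Per site i the polymerase cycles through four states:
GTP binding (10⁶ M⁻¹s⁻¹), GTP incorporation (28 s⁻¹, emitting Pi and the
tracker gtrᵢ), then the ATP pair likewise (tracker atrᵢ). Only GTP and
ATP are modeled — the two energy currencies — with 20 + 20 incorporations
per 80-bp site; adding explicit CTP/UTP roughly doubles the species count
without changing the observable outputs. An immediate gate consumes
20 gtrᵢ + 20 atrᵢ, advances the polymerase state to site i+1 (requiring
the DNAᵢ₊₁ token free), emits the RNAᵢ site token and releases DNAᵢ₋₁.
Because a moving polymerase holds its current and previous site tokens,
two polymerases on one template are always ≥ 80 bp apart. The terminal
gate releases the polymerase and both held tokens. Initiation is
T7 + DNA₁ (10⁷ M⁻¹s⁻¹, config default).

**Translation.** Per site, the printed twelve-step cycle: ternary-complex
delivery (10⁸ M⁻¹s⁻¹) and proofreading (79, 207, 3.45 s⁻¹), EF-Tu GTP
hydrolysis (100 s⁻¹), accommodation (638, 15 s⁻¹), peptidyl transfer
(20 s⁻¹), EF-G binding (1.5×10⁸ M⁻¹s⁻¹; 140, 250 s⁻¹) and translocation
(20 s⁻¹, emitting the TRANSLᵢ tracker). The gate consumes 27 TRANSLᵢ,
the RNAᵢ₊₁ token and the PEPTᵢ₋₁ length marker, emits PEPTᵢ and releases
RNAᵢ₋₁ — enforcing ≥ 27-codon ribosome spacing and coupling translation
to the transcription front (a ribosome cannot pass site i before RNAᵢ₊₁
exists). A ribosome carrying PEPTᵢ holds a nascent chain of 27i to
27(i+1)−1 amino acids. The final gate yields a pre-termination state
whose release-factor-assisted termination emits GFP; GFP can only appear
after all site gates have been traversed. Site tokens are pooled across
molecules (the model does not track which strand a site belongs to),
matching the observation that per-strand occupancy statistics are
unchanged between 1 and ~20 templates.

**Lumped machinery.** Amino acids, tRNAs, aminoacyl-tRNA synthetases and
release factors are single species each. Charging is a three-step ARS
cycle consuming one ATP and one amino acid per aa-tRNA; ternary-complex
formation binds EF-Tu·GTP to aa-tRNA; EF-Tu and EF-G recycle by GTP
exchange (each elongated amino acid costs 2 GTP + 1 ATP). NDK catalyzes
the near-equilibrium phosphotransfer ATP + GDP ⇌ ADP + GTP with both
half-reactions reversible; an irreversible variant would pump the entire
ATP pool into GTP regardless of demand, which is unphysical. Ribosome
inactivation — experimentally observed after roughly three hours — is a
first-order Rib → inactive reaction declared with rate 0 and switched on
by a timed rate action at t = 10 800 s (default rate 5×10⁻⁴ s⁻¹,
configurable, applied to free ribosomes).

**Units.** Printed bimolecular magnitudes (10⁶, 10⁸, 1.5×10⁸) are
interpreted as deterministic M⁻¹s⁻¹ constants — their magnitudes match
diffusion-limited association — and converted per volume by
c = k/(N_A·V); first-order constants are volume-independent; zero-order
would scale as k·N_A·V. Initial copy numbers are round(concentration ×
N_A × V) after class scaling; a `min_one_dna` option forces at least one
template copy, since a vesicle without a complete template is inert.

## Standard composition and calibrated defaults

Standard concentrations (editable config defaults, not published facts):
template DNA 100 nM; T7 RNAP 1.5 µM; ribosomes 1.2 µM; EF-Tu 10 µM;
EF-G 0.5 µM; lumped ARS 0.3 µM; release factor 0.5 µM; NDK 0.05 µM
(deliberately very low); GTP and ATP 2 mM each; lumped amino acids 6 mM
(20 × 0.3 mM); lumped tRNA 100 µM. The combination code scales the three
classes — DNA; enzymes; consumables (NTPs, amino acids, tRNAs) — by
(digit+1)/3.

Two defaults were calibrated, once, to the qualitative behavior reported
for this class of system rather than taken from a printed table:

* **T7 RNAP at 1.5 µM** keeps the polymerase pool in excess of template
  promoters, so transcription flux is limited by DNA site availability at
  high template levels. This reproduces the characteristic trade-off:
  more DNA ⇒ faster RNA production but faster NTP exhaustion and lower
  final protein yield.
* **Translation initiation as two steps** — ribosome–RBS binding at
  10⁵ M⁻¹s⁻¹ followed by a slow maturation of the bound initiation
  complex into an elongating ribosome at 10⁻³ s⁻¹. The slow step lumps
  30S positioning, mRNA unfolding and 50S joining and makes initiation
  the rate-limiting step of protein production, consistent with the
  well-documented low ribosome utilization of reconstituted systems.
  Without it, translation converts the energy pool so fast that yield
  becomes insensitive to the enzyme class.

With these defaults the model's emergent behavior at 10⁻¹⁶ L matches the
reported phenomenology: transcription dominates NTP consumption; final
yields are tens of GFP molecules (≈55 for "022", ≈0.9 µM); "022" (low
DNA, full enzymes, full consumables) is the best producer of the 27-code
grid; and yield falls monotonically as either the consumables or the
enzymes digit drops. Absolute published yield values depend on effective
constants that are not publicly tabulated and are *not* reproduced
quantitatively — the package's tests gate conversions, exact
stoichiometric identities, distributional exactness of the engine,
literature ranges for elongation rates, fit quality, and the yield
orderings, never the absolute yields.

## Measurements

* **Sigmoid fits.** Nonlinear least squares (scipy, positive-bounded) of
  the 3-parameter logistic y = GFPmax/(1+e^(−(x−x₀.₅)/b)), initialized at
  GFPmax⁰ = max(y), x₀.₅⁰ = first time y ≥ max/2, b⁰ = (t₉₀−t₁₀)/4;
  failed fits retry once from a perturbed start. R² = 1 − SSres/SStot,
  computed on the replicate-averaged trace (per-replicate fits are also
  available). We implement b strictly as the logistic scale parameter of
  the printed equation; descriptions of b as "the maximum slope" conflate
  it with GFPmax/(4b), which the fit object exposes separately as
  `max_slope`.
* **Elongation rates.** Measurement protocol (ours; the original is not
  specified): transcription nt/s = 2 × (cumulative gtr+atr tracker
  incorporations) / ∫(active polymerase count)dt — the factor 2 because
  only 2 of the 4 nucleotide classes are modeled; translation aa/s =
  27 × (site-gate firings) / ∫(active ribosome count)dt. "Active" means
  any per-site elongation state; a bound pre-initiation complex is not
  active, but a stalled (e.g. NTP-starved) elongation state is. Both
  integrals use the piecewise-constant sampled trajectory. Over a 1-h
  window at 10⁻¹⁶ L the standard model gives ≈4.5 nt/s and ≈0.04 aa/s —
  inside the experimental ranges (2.2–250 nt/s, 0.03–15 aa/s); the
  stall time after NTP exhaustion is included in the denominator, which
  pulls the window average well below the instantaneous rate (≈56 nt/s
  for a saturated polymerase).
* **Energy budgets.** Every NTP-consuming reaction is classified at
  build time (transcription, translation, charging, NDK) from its
  partner species; budgets are integer identities over firing counters:
  pool(0) − pool(end) + regenerated = Σ consumed, checked exactly per
  nucleotide on every trajectory.

## Numerical and design choices

* Sampling grid: LVCF; a sample falling exactly on an event time records
  the pre-event state.
* Seeds: one root seed per run set; replicate i uses root + i; grid code
  at index c uses root + 8c + i. All seeds stay below 2³¹.
* Rounding of initial counts: nearest integer (so 15 nM in 10⁻¹⁶ L is
  0.90 → 1 template — discretization is a real phenomenon at this
  scale, not an artifact to be hidden).
* Degenerate inputs: genes shorter than two sites are rejected; a class
  scaling that discretizes an essential species to zero copies is
  permitted (and produces a legitimate zero-yield vesicle) rather than
  raised as an error.
* Problem sizes in the test suite: the composition grid runs 27 codes ×
  8 replicates × 2 simulated hours at 10⁻¹⁶ L; engine exactness uses a
  birth–death chain with 10⁵ stationary samples and a 10³-replicate
  decay ensemble. These sizes give ≈3σ margins on the ordering checks.

## What the simulations do and do not show

The generator emulates a single, well-mixed vesicle of fixed volume with
a deterministic initial composition. It does not model the encapsulation
process itself (anomalous co-entrapment statistics across a vesicle
population), membrane growth or division, sequence-specific codon usage,
explicit CTP/UTP, or mRNA/protein degradation. Passing tests therefore
validate the reaction-network mechanics and the intra-vesicle kinetics,
not the distribution of compositions across real liposome populations —
the package is the forward model that a reverse-engineering analysis of
such populations would invoke per vesicle.

Known limitations: site tokens are pooled across DNA/RNA molecules, so
per-strand occupancy is enforced only statistically when several
templates are present; initiation/termination/charging constants are
effective lumped values; immediate-reaction scheduling between
simultaneous timed events follows our declaration-order convention.
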