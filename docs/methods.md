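# Methods

This note records the models, parameter choices, and numerical conventions
behind `alpharep`, and what the synthetic data used by the test suite does
and does not establish about real libraries.

## Degenerate codons and cassette mixtures

A degenerate codon is expanded as the Cartesian product of its per-symbol
base sets and translated codon-by-codon under the standard genetic code;
the pool is assumed equimolar within a symbol (the standard behaviour of
mixed-base oligonucleotide synthesis). Mixing proportions act only
*between* cassettes. Stop codons are handled by an explicit policy:

- `drop-renormalize` (default): stop-containing codons are removed and the
  distribution renormalized over coding codons — the right model when
  truncation products are lost from a displayed library;
- `amber-as-Gln`: TAG is read through as Gln, the behaviour of supE
  amber-suppressor hosts commonly used for phage display; TAA/TGA always
  truncate;
- `error`: any stop is a hard failure, for schemes that must be stop-free.

One documented quirk: the N-cap codon `dht` literally encodes 9 residues
(N, T, I, D, A, V, Y, S, F), whereas the residue list usually quoted for
that cap position set (A, D, E, F, I, K, L, M, N, S, T, V, Y) is exactly
what `dhk` encodes once amber is dropped. Both codons ship as presets
(`NCAP_CODON_22_23_26` and `..._ALT`); the toolkit does not guess which
was intended.

## Natural-collection statistics and the synthetic generator

Per-position distributions are empirical frequencies over a curated aligned
collection; curation drops modules with more than `max_indels` gap
characters (default 3). Gap bookkeeping is deliberately simple and
auditable: a module's indel count is its gap-character count, and gapped
positions are excluded per-module from frequency denominators. Dipeptide
tables at the adjacent pairs (18–19, 22–23) are joint empirical
frequencies, ranked with lexicographic tie-breaking so top-N queries are
deterministic.

The synthetic generator emulates the *statistical shape* of a natural
repeat-module collection: independent per-position draws from configurable
marginals at the six variable positions, optional coupling of adjacent
pairs through a supplied joint table (a `coupling` fraction of rows is
drawn jointly), consensus residues elsewhere with a 5% substitution rate,
and an optional gap rate for exercising the curation rule. The default
collection size is 1719 modules, a realistic curated-collection scale. The
shipped default marginals are synthetic: they encode only the qualitative
biases described for natural repeat families (Pro most common at 18 and
absent from 22–30, small side chains enriched at 23, large polar residues
at 30). Passing tests therefore demonstrate that the pipeline recovers
whatever distribution generated the data (within total-variation sampling
bounds of ~0.05 at n≈2000), not that these particular numbers describe any
natural family. Aromatic enrichment relative to the natural frequencies is
exposed as an explicit per-residue multiplier (`boost_residues`) rather
than a hard-coded factor, since the appropriate enrichment is a design
choice.

## Cassette selection and weight fitting

Budget-limited dipeptide coverage is a weighted maximum-coverage problem.
The selector is greedy (largest newly covered weight first) followed by
single-swap local search to a fixed point; ties break lexicographically on
codon strings, so results are reproducible. Greedy alone guarantees
(1−1/e) of the optimum for coverage objectives; the swap phase only
improves it, and on enumerable toy instances the tests compare against
brute force. Mixing weights are fitted on the probability simplex by SLSQP
with analytic gradients, minimizing either squared distance (default) or
KL(target‖achieved), objective tolerance 1e-9; target mass on dipeptides
no cassette can encode is reported as `irreducible_mass` rather than
silently ignored. Forbidden residues (Cys everywhere; Pro at 22, 23, 26)
make a cassette infeasible at enumeration time — designs are rejected, not
repaired.

The published scheme's counts (87 dipeptides at 18–19 from 26 cassettes,
60 at 22–23 from 24) are treated as lower bounds for the selector, since
the actual cassette identities behind those counts are not public; the
coverage maximizer exceeds both comfortably (110 and 128 from the same
codon lists and budgets).

## Diversity arithmetic

All space computations use Python integers (exact at any magnitude). The
expected number of distinct variants in a library of size L sampled
uniformly from a space of size S is S(1−(1−1/S)^L), evaluated via
`expm1`/`log1p` so it remains accurate when S ≫ L (e.g. the 7-repeat
space of ~10³⁸ against a 1.7×10⁹ library). Uniform sampling is an
idealization — real clone frequencies are skewed by growth competition —
so reported coverages are upper bounds.

## Assembly, filtration and shuffling model

Each module carries an independent frame-shift defect with probability
ε_mod (caps: ε_cap, default 0); a clone is coding iff all flags are clear.
This is the minimal model sufficient for the standard library
characterization columns, and deliberately does not distinguish error
mechanisms (synthesis vs mis-assembly). The module-count distribution is
configurable; the default is a truncated geometric p(n) ∝ q^n on 0..10
with q = 0.75, chosen once to give a realistic assembly profile (~25% of
clones with no internal module; mean coding-clone length near 2 when 20%
of motifs are defective). The analytic in-frame fraction is
(1−ε_cap)²·Σ_n p(n)(1−ε_mod)^n; simulations at 10⁵ clones agree within
3σ binomial error.

Filtration retains exactly the in-frame clones (idempotent by
construction). Shuffling re-assembles fresh clones from the pooled,
defect-free modules with new length draws; each ligation acquires a defect
with ε_lig (default 0.03, i.e. 97% correct motifs after re-assembly).
Because (1−ε_lig)^n decays much more slowly than (1−ε_mod)^n, the shuffled
library has both a higher in-frame fraction and a longer mean coding
clone — the trend the two-step construction is designed to produce. The
helper `independent_module_inframe(q, n̄) = q^n̄` checks the internal
consistency of characterization rows (e.g. 0.97^2.3 ≈ 0.93).

## Clone annotation

Because the module length is fixed at 31, segmentation is exact length
arithmetic once the N-cap is anchored by a sliding consensus match;
profile HMMs would add nothing here. Mismatches at non-variable positions
are tolerated up to 20% per segment (default). The C-cap may be matched as
a prefix (`min_ccap_length`) to accommodate the C-terminal proteolytic
truncation seen in some purified repeat proteins. The shipped scaffold
consensus is synthetic (real cap/module sequences arrive via config); its
back-translation table is fixed per residue and chosen so that a
KpnI-style `GGTACC` site spans every segment junction, which lets the DNA
frame checker localize a frame shift to the first module whose downstream
junction is corrupted. Frame diagnostics: total length mod 3, inter-cap
region mod 93, in-frame stop codons, junction-site integrity.

## Binding models

**One-site ITC.** The 1:1 equilibrium is solved by the exact quadratic.
Dilution follows the perfusion (overflow) convention: an injection of dv
into the fixed cell volume V₀ multiplies existing concentrations by
(1−dv/V₀) and adds titrant at [syringe]·dv/V₀; injection heat is
V₀·ΔH·([RL]ᵢ−[RL]ᵢ₋₁(1−dv/V₀)), counting complex displaced into the
overflow. Defaults: V₀ = 200 µL (the nominal cell of the instrument
class; a published "0.24 µL" cell figure is treated as a typo), 20 × 2 µL
injections from a 40 µL syringe. Fits use Levenberg–Marquardt on
(log₁₀K_d, n, ΔH) with tolerances 1e-10, initialized from curve
heuristics (ΔH from the first injection, n from the half-total-heat molar
ratio). Noise is Gaussian with σ a stated fraction of the largest
injection heat. At Wiseman c ≈ 190 a single 2%-noise titration determines
K_d only to ~10–30%; recovery tests therefore average the estimate over
10 seeded replicates, which is also the estimator the DSC recovery uses.
The titration ΔH values used in simulations default to −10 kcal/mol, a
typical exothermic protein–protein binding enthalpy; K_d recovery is
insensitive to this choice.

**Displacement ITC.** The ternary single-site competition equilibrium is
solved by `brentq` on the receptor mass balance (strictly increasing in
free receptor, bracketed on [0, R_total], xtol 1e-12 relative); an
unbracketed balance signals inconsistent concentrations and raises. The
weak ligand's K_d, ΔH and concentration are held fixed during fitting, as
in a real displacement analysis where the weak binder is characterized
first. The apparent constant K_app = K_a^tight/(1+K_a^weak[weak]) moves a
low-nanomolar affinity into the measurable micromolar range (3.7 nM with
141 nM competitor at 43 µM → apparent K_d ≈ 1.13 µM).

**DSC.** Two-state excess heat capacity
ΔC_p(T) = K(T)ΔH_cal·ΔH_vH/[(1+K(T))²RT²] with the van't Hoff constant
anchored at the midpoint, K(T) = exp[(ΔH_vH/R)(1/T_m−1/T)], the only
parameterization that makes the curve peak at T_m (up to the ~0.1 K shift
from the 1/T² factor) with height ΔH_cal·ΔH_vH/(4RT_m²). The curve
integrates to ΔH_cal (verified to 0.1% by quadrature); ΔH_vH/ΔH_cal is
the usual cooperativity diagnostic. Simulated scans follow the standard
protocol: 20–120 °C at 0.1 K steps.

**SPR.** 1:1 Langmuir kinetics with the classical separate-phase fit:
k_off globally from the dissociation phases (shared rate, per-curve
amplitude), then k_on (log-scaled) and R_max from the association phases
with k_off fixed. Default timing 120 s association, 10 min dissociation;
default analyte series 71.3–1426 nM. K_d = k_off/k_on.

**Thermodynamics.** R = 1.9872 cal mol⁻¹ K⁻¹ throughout (kcal units
internally); the ΔG° = ΔH° − TΔS° identity is enforced to 1e-9 on
constructed states.

All simulators are deterministic at zero noise, and every fitter recovers
its generating parameters exactly (relative error < 1e-5) on noise-free
data — the basic self-consistency property the test suite asserts for all
four models.

## Problem sizes

Test-suite and acceptance-script workloads are sized to run in seconds on
one core: assembly simulations at 10⁵ clones (binomial 3σ checks),
synthetic collections of 1719–5000 modules, 10 replicate fits per
stochastic recovery, Monte-Carlo occupancy at 10⁵ repetitions, and
exhaustive brute-force oracles only on toy instances (≤8 cassettes,
≤64-codon expansions, simplex grids at 0.05 resolution).

## Known limitations

- The defect model is binary per module; nucleotide-level error mechanisms
  and phage growth-competition biases are out of scope.
- Uniform-sampling coverage is an upper bound for real libraries.
- ITC K_d values for self-associating targets are composite (homodimer
  dissociation coupled to binding); the models here treat the measured
  apparent constant as a single-site parameter and do not decompose it.
- Multi-site/cooperative ITC, mass-transport-limited SPR, and non-two-state
  DSC baselines are not modeled.
- The cassette selector optimizes coverage, not the authors' (unpublished)
  exact cassette identities; agreement is therefore on counts, not sets.
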