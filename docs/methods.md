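# Methods

This note records the models implemented in `oricompat`, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The copy-number model

Co-resident ColE1-type origins are treated as competing populations of
replicons inside one cell:

    dX_i/dt = r_i · X_i · (1 − a_i X_i + Σ_{j≠i} c_ij X_j)

* **X_i** — copy number of origin *i* (plasmids per cell; continuous
  between divisions).
* **r_i** — intrinsic replication rate, per host generation. Default
  **5 gen⁻¹**, so copy number re-equilibrates well within a cell cycle;
  configurable. Time is measured in host generations throughout.
* **a_i = 1/K_i** — self-limitation, the reciprocal of the expected copy
  number K_i measured in single-plasmid strains. With no interference an
  origin settles exactly at its K.
* **c_ij ≤ 0** — phenomenological cross-interference of origin *i* by
  origin *j* (RNAI_j acting on RNAII_i). Zero is maximum compatibility.
  The matrix is *not* required to be symmetric: the RNAI_A/RNAII_B duplex
  has no thermodynamic obligation to cost the same as RNAI_B/RNAII_A, and
  directional compatibility falls out of that asymmetry. Positive entries
  are rejected at construction — the model admits interference or
  indifference, never mutual promotion.

The functional form is the minimal one consistent with these constraints:
logistic self-limitation plus linear non-positive cross terms inside the
growth bracket. Mechanistic RNAI/RNAII hybridisation kinetics and host
factors (Rom/Rop, uncharged tRNAs) are deliberately outside the model;
the plasmids being described carry neither *rop* nor *cer*.

### Equilibria and classification

The interior equilibrium solves (diag(a) − C)X = 1. For n = 2 the closed
form is X₁* = (a₂ + c₁₂)/(a₁a₂ − c₁₂c₂₁) (and symmetrically), giving
analytic criteria: positive interior with a₁a₂ > c₁₂c₂₁ → stable
coexistence; positive interior with the inequality reversed → a saddle,
i.e. bistability; otherwise exclusion, the survivor read off boundary
invasion rates r_j(1 + c_ji K_i).

`classify_outcome` deliberately takes the *numerical* route — Jacobian
eigenvalues at the interior, then at every boundary equilibrium, then
long-run integration from randomized interior starts — so the closed-form
criteria can serve as an independent cross-check (the suite sweeps 1000
random parameter sets and demands agreement). Eigenvalue real parts
within ±1e−9 are treated as marginal and resolved by simulation; the
boundary-eigenvalue step matters because exclusions arbitrarily close to
the stability boundary decay too slowly for any finite integration
horizon to see.

### Numerics

`simulate` uses adaptive RK45 (rtol 1e−9, atol 1e−12) with per-component
extinction events: when a coordinate decays through 1e−12 the integration
stops, the coordinate is pinned to zero (extinction is absorbing) and
integration resumes — no silent truncation inside the integrator's error
control. Whole-population integration (`integrate_copy_numbers`) is a
vectorised fixed-step RK4 (default dt 0.05 generations) over an
(n_cells × n_origins) matrix, clamped non-negative per step; it agrees
with the adaptive path to ~1e−4 relative over the durations the
segregation simulator uses, and is what makes thousand-cell passaging
simulations cheap.

## Segregation and serial passaging

The simulator alternates deterministic intracellular replication with
stochastic division:

1. **Replicate**: integrate the LV system for one generation from the
   cell's integer counts, then stochastically round (floor + Bernoulli on
   the fractional part — unbiased). Origins at zero stay at zero.
2. **Divide**: each origin assorts independently, Binomial(n, 1/2) per
   daughter. Totals are conserved; the per-division loss probability for
   an origin at n copies is exactly 2^(1−n).
3. **Select**: daughters missing any selected origin are removed at the
   generation boundary (instant antibiotic action; assay readouts are
   24 h endpoints, so no phenotypic lag is modelled).
4. **Cap**: populations above the cap (default 10 000; most tests use
   500–2000) are uniformly subsampled with the passed RNG.

A passage dilutes 1:100 (1% v/v inoculum) and regrows; the number of
division rounds per passage is round(log₂(dilution)) = 7 for the default
1:100. A full Gillespie treatment of replication events is out of scope —
no per-origin rate constants exist to parameterise it — and the
hybrid deterministic/stochastic scheme preserves the two quantities the
assays measure: equilibrium copy number and partition statistics.

Retention curves record, per passage (including t = 0), the fraction of
live cells carrying each origin and the fraction carrying all. A
population wiped out by selection truncates the curve and sets an
explicit `extinct` flag.

## The reporter assay

The TetR/GFP circuit is modelled at its logical core: GFP is ON in a cell
iff the regulatory plasmid is absent and the reporter plasmid present.
No TetR dilution lag is modelled (a config hook exists in principle;
endpoint readouts make it irrelevant at default). Plate readings are
od600 ∝ live cells and fluorescence = background + signal·(GFP-on cells)
+ truncated Gaussian noise; media presets differ only in background and
noise level. Normalised fluorescence is (fluorescence − background)/OD,
rejecting effectively empty wells.

`cross_compat_matrix` simulates every ordered (reporter, regulatory) pair
under reporter-side selection and calls a pair incompatible when
regulatory retention at assay end falls below **0.5** (the screen itself
ranks wells; no printed cutoff exists, so the midpoint is the declared
default and threshold monotonicity is tested). Diagonal self-pairs share
a single replication-control pool — modelled as c = −1/K both ways, a
degenerate LV system neutral along X₁ + X₂ = K — and are called
incompatible by definition of an incompatibility group, irrespective of
how far drift happens to get within a short simulated assay.

The orthogonality score of a pair is the (interpolated) number of
passages until the unselected origin's retention crosses 0.5, capped at
the protocol length: a continuous measure of "how compatible", monotone
in interference strength.

## Parameter-space scans

Grids span [−2/K_min, 0] per interaction axis (21 steps by default):
from maximum compatibility at zero to well past the n = 2 exclusion
boundary at −1/K. Feasible-region scans evaluate each grid point either
analytically (closed-form pairwise criteria) or by replaying the
serial-passage assay at fixed seed. The higher-order search (3 origins,
6 free axes, 6 grid levels by default) prefilters candidates with the
closed-form pairwise-coexistence test, then requires an origin to fall
below 10⁻³ of its K in *every* one of 10 seeded 200-generation
integrations from randomized interior starts before reporting a witness;
witnesses re-verify under independent simulation.

Curve fitting is transparent grid least squares between observed and
simulated retention curves, all candidates sharing one seed so
differences reflect parameters rather than sampling noise; ties break
toward weaker (closer-to-zero) interactions — the conservative call when
data cannot distinguish interference strengths. The recovery study uses
K = [20, 20] (low enough that segregation loss is informative within a
4-passage assay), a 6-level grid, 200-cell populations and Gaussian
observation noise of 0.02 on retention fractions — plate-count-scale
noise.

## Quantification

dPCR: λ = −ln(1 − positives/partitions) per channel; copy number per
genome is λ_FAM/λ_HEX. Saturated channels are rejected, not extrapolated
(λ is undefined at p = 1). The 95% CI is a percentile bootstrap over
binomial resampling of both channels (default 10 000 replicates): the
vendor's "rare mutation analysis" interval construction is undocumented,
and the bootstrap is the assumption-light substitute. Resamples that
saturate or empty a channel are dropped (vanishingly rare at realistic
occupancies). Plating retention uses exact Clopper–Pearson intervals;
double/single ratios above 1 are clamped with a warning.

## Sequence-side conventions

* Coordinates are 0-based half-open everywhere; FASTA/FASTQ are read via
  Biopython and never rewritten in place. T and U are equivalent on
  input; the internal alphabet is DNA.
* **Hairpin loops** are terminal loops only: the unpaired run enclosed by
  an innermost pair. Bulges, internal loops and unpaired linkers are
  excluded — "loop length" means the loops a kissing interaction can
  initiate from, and the regression target is their sum. Whether the few
  unpaired bases outside hairpins should count is not settled; the
  terminal-only rule is this package's documented choice.
* **Library sizing** is exact integer arithmetic; combined designs add
  (an upper bound on the union — duplicates across sub-libraries are not
  collapsed, matching the "maximum size of the search space" reading).
  The default loop-restricted design shipped as
  `LOOP_RESTRICTED_TEMPLATES` is a reconstruction: 13 N and 6 K positions
  over the three loop regions, chosen to realise the published aggregate
  (4^13·2^6 = 4 294 967 296 ≈ 4.3 × 10⁹) with the degeneracy vocabulary
  (N, K) the design used; the per-position layout of the original
  libraries is available only graphically.
* **NGS counting** fixes the pipeline order: 3'-end sliding-window
  quality trim (window 10, a read is trimmed while the window mean is
  ≤ 20, and discarded if it ends up shorter than the window), then the
  four constant flank motifs must appear in order (exact string match —
  the workflow is filter-based, not alignment-based), then the region
  between the outer motifs is deduplicated and counted. Ties in the
  ranked table break lexicographically, which makes top-k fractions
  deterministic.

## Synthetic data

Generators emulate the statistical structure the analyses assume, not
sequence-level realism:

* `gen_origin_set`: three-hairpin scaffold with perfectly paired random
  stems; loop lengths uniform on 4–9 nt per hairpin; copy number
  K = 260 − 8·(loop sum) + N(0, 5), truncated at 1 — spanning roughly
  40–200 copies/genome, the qualitative high-copy, Rom/Rop-free range.
  These coefficients are synthetic calibrations, not measurements.
* `gen_reads`: reads are flank₁ + variant region + flank₄ with the four
  constant motifs; per-base substitution errors at a stated rate; flat
  Phred 38 with an optional low-quality 3' tail to exercise the trimmer.
  Read counts per variant are allocated by largest-remainder rounding of
  the weights (so a 60/30/10 mixture is recoverable exactly at zero
  error) and the read order is shuffled under the seed. No indel model:
  the observed deletion hotspot in real libraries is noted but not
  emulated.
* `gen_dpcr_chip`: per-channel positives ~ Binomial(n, 1 − e^(−λ)), with
  the genome channel's λ tied to genome equivalents.
* `gen_two_plasmid_population`: Poisson-around-K counts, minimum 1 — a
  freshly double-selected culture.

Every generator draws from a named substream of the master seed
(CRC32-tagged `SeedSequence`), so adding a generator or reordering calls
never perturbs existing fixtures. Because the generators realise exactly
the model's assumptions, passing tests demonstrate internal consistency
and correct implementation — not that real plasmid populations obey the
LV form, which is a hypothesis the wet assays address.

## Problem sizes

Defaults used by the test suite and the acceptance script: populations of
200–2000 cells (cap 10 000 available), 3–4 passages, 10⁵ divisions per
Monte-Carlo loss estimate, 1000-point classification sweeps, 100
noise-replicates for recovery, 200 chips × 2000 bootstrap replicates for
coverage, and a 6⁶-point (prefiltered) higher-order grid. These sizes
were chosen so every statistical check keeps comfortable 3σ margins.

## Known limitations

* Interactions are phenomenological; the model cannot predict c_ij from
  sequence, only infer feasible regions from outcomes.
* No spatial structure, conjugation, multimer resolution or plasmid
  burden (burden is measurable but not modelled).
* The assay layer models media effects as noise presets only, and
  represents multi-colour flow experiments by per-origin presence flags,
  not spectra.
* Whether dead (selection-killed) cells contribute to bulk OD in the wet
  assay is unknown; the simulator counts live cells only.
* The integer rounds-per-passage convention (7 for 1:100) slightly
  overshoots the dilution arithmetic (2⁷ = 128×); the population cap
  absorbs the difference.
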