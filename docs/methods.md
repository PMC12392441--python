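# Methods

## Scope and model structure

The package couples three layers:

1. **Closed-form kinetics** (`kinetics`): pseudo-first-order •OH attack on
   monomeric units, k₁ = k_M·[•OH]_SS, giving the scission extent
   SiC̄(t) = (1 − e^(−k₁t))·M̄n(t₀)/MW_monomer and M̄n(t) = M̄n(t₀)/(SiC̄+1).
   The model assumes every monomeric unit of every chain reacts with equal
   probability and that each reacted unit produces exactly one backbone
   scission; it carries no information about the distribution around M̄n.
2. **Stochastic ensemble simulation** (`ensemble`, `simulate`): an
   event-driven Monte Carlo over a multiset of integer chain lengths with
   chain-selection probabilities proportional to the piecewise rate law
   k(n) (linear below 30 units, ∝n^0.57 above, continuous at the break)
   and uniform cut-bond choice. The simulator has no time axis; runs are
   parameterized by the termination extent SiC̄, and calendar time is
   attached, when needed, through the closed form.
3. **Data reduction and inference** (`distributions`, `peaks`, `fitting`,
   `fixtures`): wt%/nr% histograms and right-continuous cumulative curves,
   ingestion of censored oligomer peak tables, and grid-search estimation
   of SiC̄ by least squares on cumulative-curve residuals.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| k_M | 2.1×10⁹ | M⁻¹s⁻¹ | experimental •OH + PEG-unit rate constant |
| [•OH]_SS | user-set | M | 10⁻¹⁷–10⁻¹⁵ spans sunlit surface waters |
| MW_monomer | 44 | Da | ethylene-oxide repeat; chain MW = n·44 exactly (no end groups), the convention shared by both model layers |
| m | 5000 | chains | averaged-run ensemble size; 20 for network illustrations |
| λ, σ | 145, 9.09 | units | from the 6380 ± 400 Da starting material (Da/44) |
| prefactor, breakpoint, exponent | 0.8, 30, 0.57 | — | the k(n) law; taken as given constants, exposed on `RateModel` |
| replicates | 50 | — | averaged distributions and fitted curves |
| SiC̄ grid | 0:8:0.1 | — | fitting resolution |
| censor bounds | 2000, 6400 | Da | resolved chromatographic window |
| repeat/end/adduct mass | 46.05 / 18.01 / 1.007 | Da | ¹³C₂ repeat, water end groups, protonation; MS assignment only — never used in the kinetics or the simulator |

## Numerical and design choices

- **Units.** SI seconds internally; the CLI accepts `s/h/d` suffixes.
  1 − e^(−x) is computed via `expm1` and clamped to exactly 1 for
  x > 700 to avoid underflow.
- **Initial ensemble discretization.** The normal length density is
  evaluated at integer n ≥ 1 and renormalized (not bin-integrated); at
  σ ≈ 9 the difference is far below sampling noise. Counts are
  apportioned by largest remainder (ties to the smaller length), which is
  deterministic and bit-reproducible across platforms; multinomial
  sampling is available for realism studies.
- **Monomer exclusion.** Length-1 chains are the terminal product and are
  never selectable for scission, even though the k(n) formula would
  assign them a nonzero rate — the only reading consistent with ethylene
  glycol being an end product. At SiC̄ ≤ 8 with λ = 145 the monomer pool
  stays tiny, so the practical effect of this choice is negligible.
- **State representation.** The scalable engine keeps a length→count
  histogram with class weights m(n)·k(n) and samples a class by inverse
  CDF, then a bond uniformly; this is exactly equivalent to per-chain
  selection (asserted against a brute-force per-chain sum in the tests)
  and handles 5000 chains × 40 000 events in about a second. Small runs
  can instead track individual chain identities for genealogy/network
  output; tracking is capped at 1000 initial chains to bound memory.
- **Event budget.** round(SiC̄·m), round-half-up; the achieved SiC̄ (events
  per initial chain) is reported alongside the request and differs from
  it by at most 1/(2m).
- **Seeding.** One `numpy.random.SeedSequence` per run, split into
  independent streams for ensemble initialization, simulation and (in the
  fixture generator) noise; replicate r's stream derives deterministically
  from the base seed, so any replicate is reproducible in isolation. No
  global RNG state is used anywhere.
- **Checkpointing.** Trajectories over a SiC̄ grid and the fitting grid
  reuse one simulation per replicate with checkpoints at each grid value:
  scission events are cumulative and the process is Markovian in the
  ensemble, so nested checkpoints sample the same law as independent
  runs, at a fraction of the cost, and give the fit common random numbers
  across the grid (a smooth SSE profile with a reproducible argmin).
- **95% bands** are 2.5/97.5 percentiles across replicates. Note this
  estimates the spread of a single replicate, not the standard error of
  the mean, and therefore does not narrow as the replicate count grows.
- **Cumulative curves** are right-continuous steps (a chain of MW x
  counts at every point ≥ x); histograms use (lo, hi] bins so exact
  multiples of the repeat mass land on upper edges. Threshold fractions
  ("wt% below X Da") are strict (<), matching the censored-lump
  definition, and evaluation at arbitrary MW uses the step value at the
  greatest tabulated point ≤ the query (experimental MWs are not
  multiples of 44 Da).
- **Fitting.** Plain least squares on cumulative wt% residuals over the
  grid, evaluated at the experimental MW points plus two boundary points:
  the low-MW lump intercept at the lower censor bound and the high-MW
  complement (100 − lump_high) at the upper bound; uniform weights; ties
  in the SSE profile break to the smaller SiC̄. More elaborate residual
  schemes (e.g. PLS-style projections) were considered and rejected:
  with a one-dimensional parameter on a fixed grid, ordinary least
  squares is the transparent choice, and the recovery harness shows it is
  accurate to about one grid step.

## What the synthetic-data generator does and does not emulate

`generate_fixture_peak_table` simulates an ensemble to a known extent,
turns per-oligomer wt% inside the resolved window into mass-proportional
"integrals" (the mass-proportional, MW-independent detector response of
a charged aerosol detector), lumps the censored mass into single low/high
rows, and applies multiplicative lognormal noise (σ = `noise_rel`) to
every integral; the truth goes into a sidecar file only, keeping recovery
experiments blind. It does **not** emulate chromatographic co-elution or
drifting baselines, MS adduct/end-group mass structure (fixture MWs sit
on the 44-Da simulation lattice), partial peak overlap near the window
edges, or any detector nonlinearity. Passing recovery tests therefore
demonstrate that the inference machinery is self-consistent under the
stated noise model, not that real chromatograms carry equally clean
information.

## Problem sizes used in tests and the acceptance script

Network-scale checks use 20 chains; averaged distributions, trajectories
and fitting use 50 replicates × 5000 chains with the 0.1-step grid (the
study conditions); module-level unit tests exercise the same code paths
at 300–1000 chains with coarser grids. The noisy-recovery experiment runs
10 independent fixtures per truth at 5% integral noise.

## Known limitations

- Scission is a pure length-partition event: no branching, end-group
  chemistry, −2 Da/+16 Da oxidation products, or mineralization channel.
- The closed form and the simulator share the no-end-group MW convention;
  absolute MWs of real oligomers (46.05-Da labeled repeat + end groups)
  appear only in the MS-assignment layer.
- The fitted SiC̄ inherits the grid resolution (±0.05 at best) and the
  residual-weighting choice; no uncertainty beyond the replicate envelope
  and grid step is quantified.
- The wt% trajectory of the intermediate 4400-Da class peaks near
  SiC̄ ≈ 2 under these defaults; the peak location is broad and flat
  (formation and destruction nearly balance over SiC̄ ≈ 1.5–2.5), so its
  argmax is the least sharply determined quantity the package reports.
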