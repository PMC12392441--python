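# pegscission

Modeling hydroxyl-radical-induced chain scission of water-soluble
polymers — closed-form kinetics, a stochastic Monte Carlo ensemble
simulator, and scission-extent estimation from chromatographic oligomer
peak tables.

Poly(ethylene glycol) (PEG) and other water-soluble polymers reaching
sunlit surface waters are attacked by photochemically produced hydroxyl
radicals (•OH), which cleave the backbone into progressively shorter
chains. Because biodegradability depends strongly on molecular weight,
predicting how the full MW distribution evolves during photooxidation —
not just its average — matters for assessing environmental fate. This
package is for environmental chemists and polymer scientists who want to
(i) compute scission extents expected at realistic •OH exposures,
(ii) simulate the resulting MW distributions chain by chain, and
(iii) infer the scission extent of a real, partially degraded sample from
HPLC-CAD(-HRMS) oligomer peak integrals.

## The model

**Closed form.** •OH attack on the monomeric units is pseudo-first order
with rate constant k₁ = k_M·[•OH]_SS (k_M = 2.1×10⁹ M⁻¹ s⁻¹). The
average number of scissions per initial chain after time t is

    SiC̄(t) = (1 − e^(−k₁ t)) · M̄n(t₀) / MW_monomer,

the fraction of reacted units times the initial degree of polymerization
(MW_monomer = 44 Da for the ethylene-oxide repeat), and since each
scission adds one chain,

    M̄n(t) = M̄n(t₀) / (SiC̄(t) + 1).

**Monte Carlo.** An ensemble of m chains with integer lengths n drawn
from a normal length distribution is evolved event by event: chain i is
selected with probability P_i = k(n_i)/Σ_j k(n_j), where

    k(n) = 0.8·k_M·n                  for n ≤ 30
    k(n) = 0.8·k_M·30·(n/30)^0.57     for n > 30,

and is cut at one of its n−1 bonds uniformly at random; the two
fragments rejoin the pool. A run terminates after round(SiC̄·m) events.
Mass and chain-count conservation make the simulated M̄n reproduce the
closed-form 1/(SiC̄+1) decay exactly, while resolving the full nr%/wt%
MW distribution, chain genealogies (generation labels, Intermediate vs
Final chains) and replicate-to-replicate variability.

**Fitting.** The scission extent of a measured sample is estimated by
simulating cumulative wt% MW curves on a SiC̄ grid (default 0–8 in 0.1
steps, 50 replicates of 5000 chains) and minimizing squared residuals
against the experimental cumulative curve, including the censored
low-MW (<2000 Da) and high-MW (>6400 Da) lump integrals as boundary
points.

## Worked example

`examples/04_fit_scission_extent.py` generates a synthetic peak table at
a known truth and recovers it (scaled to 1000 chains / 10 replicates for
speed):

```
synthetic table: 102 rows (lump_low = 22.8 wt%, lump_high = 8.5 wt%)
true SiC = 2.1; fitted SiC = 2.2 (SSE = 260.7 over 102 curve points)
SSE profile near the optimum:
 sic     sse
2.00  683.45
2.10  260.97
2.20  260.75
2.30  694.32
2.40 1451.31
2.50 2553.40
```

The table's 22.8 wt% low-MW lump is the mass that left the resolved
window after ~2 scissions per chain; the SSE profile is sharply convex
around the truth and the grid argmin lands within one 0.1 step of it.
The other examples print the closed-form kinetics table (SiC̄ = 2.607
after one day at [•OH]_SS = 10⁻¹⁶ M, M̄n 6380 → 1769 Da), a 20-chain
reaction network (20 events → 40 final chains, with the
Intermediate/Final bookkeeping identities), and replicate-averaged
distributions (by SiC̄ = 8, ~94 wt% of mass below 4000 Da).

A console script exposes the same functionality from the shell:

```
pegscission kinetics --oh-ss 1e-16 --mn0 6380 --times 0s,1d,10d
pegscission simulate --m 20 --mn0-da 6380 --sigma-da 400 --sic 1 \
    --seed 7 --track-network --out-prefix runs/net
pegscission fixture --true-sic 2.1 --noise-rel 0.05 --out peaks.csv
pegscission fit --curve peaks.csv --grid 0:8:0.1 --out fit.json
```

## Peak CSV schema

Columns `kind` (resolved | lump_low | lump_high), `mw_da`, `mz`, `z`,
`integral`, optional `rt_min` (passthrough). A resolved row needs either
`mw_da` or an (`mz`, `z`) pair — `mw_da` wins if both are present; the
m/z assignment uses repeat mass 46.05 Da (¹³C₂-labeled repeat), end-group
mass 18.01 Da and a 1.007 Da proton adduct per charge, all overridable.

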