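# Methods

## The synthetic world

`synthgenome` plants TE copies and gene loci into random background
sequence, deterministically for a fixed seed. The default fixture is two
500 kb chromosomes carrying three TE families — Tc1-like (1,610 bp
consensus × 31 copies), Tc3-like (2,335 bp × 22) and Cele14-like
(1,000 bp × 60) — plus 20 genes of 2–6 kb, one of which is a 4 kb
`control_gene` (a p53-like non-TE locus used as the gene-class reference in
the assays). The Tc1/Tc3 copy numbers are the haploid counts of the
nematode families they emulate; Cele14 stands in for a genuinely high-copy
family (~2,000 genomic copies) scaled down to 60 so the fixture stays
desk-sized while preserving the copy-number hierarchy. Element lengths are
fixture choices (the copy numbers, not the lengths, carry the biology
here).

Copies diverge from their consensus by independent substitutions at 2% per
base, a realistic family structure that never touches `GATC` or `CAGCTG`
motifs — the assayed sites must survive divergence for the
restriction-based assay to address all copies. Each consensus carries one
planted `GATCC` (DpnI site whose blunt `GA^TC` cut leaves the genomic head
`TCC`) and one `CAGCTG` (PvuII). Strand of each planted copy is random;
placement uses a shuffled greedy assignment to chromosomes and
stars-and-bars gap sampling, so features never overlap and an infeasible
configuration fails with a sizing error.

Coordinates are 0-based half-open internally and 1-based inclusive in the
GFF3 output (`source=temeth-age`, types `te_copy`/`gene`/`control_gene`,
attribute `family_id=`). The repeat table is a Dfam-hit-style TSV (one row
per copy with percent identity), not a byte-level replica of any database
format.

## Methylation trajectories

Per-site 6mA probability by locus class and genotype (all defaults, units:
probability per assayable site, age in adult days):

| parameter | value | why |
|---|---|---|
| TE baseline p₁ | 0.03 | sets day-1 level; with k gives the calibrated fold |
| TE growth k | 0.45 /day | p(11)/p(1) = 1 + 10k·…  = 5.5, midpoint of the 5–6-fold band |
| gene baseline p₁g | 0.06 | genes carry twice the TE 6mA at day 1 |
| gene decay λ | −ln(0.35)/4 ≈ 0.2625 /day | makes p_te(5)/p_gene(5) exactly 4 |
| nmad-1 plateau | 0.165 | demethylase-null: constant at the aged wild-type level |
| damt-1 residual | 0.01 (day < 5), 0.001 (≥ 5) | methyltransferase-null: weak day-1 band, then near zero |
| background p_bg | 0.001 | off-feature call rate |
| excision β | 0.005 /day | hazard coefficient; keeps day-1 excision below detection and day-14 above |
| stress multiplier | 1 (2 when stressed) | heat stress scales p(t); a config knob, not a calibrated value |

Wild-type TE loci: p(t) = p₁(1 + k(t−1)); *daf-2* replaces k by k/2 (the
long-lived mutant accumulates 6mA at half rate); gene loci:
p(t) = p₁g·e^{−λ(t−1)}, genotype-independent. All values are clipped to
[0, 1]. The *nmad-1* plateau is the spec'd constant-high level; note that
the wild-type line crosses it after day 11, so the genotype ordering
nmad-1 ≥ wild-type ≥ daf-2 ≥ damt-1 is asserted over days 1–11, the range
the assays cover.

Excision is a per-molecule event with hazard proportional to current
methylation: cumulative excised fraction e(t) = 1 − exp(−β·Σ_{u=1..t}
p(u)). This encodes the causal chain (methylation → mobilization) as the
generator's ground truth. At wild-type defaults e(1) ≈ 1.5×10⁻⁴, below the
detection threshold δ = 0.005, and e(14) ≈ 8.2×10⁻³, above it. Excised
molecules carry no element and therefore cannot be methylated at the
assayed site; this (1 − e(t)) coupling biases measured methylated fractions
by ≤ 0.6% at day 11, negligible at every stated tolerance.

Methylation state is assigned per site, both strands jointly;
hemimethylation is not modeled (whether DpnI in this assay requires full
methylation is unknown; all reported quantities are ratios, so the
per-strand factor cancels). Modification-call emission writes one record
per strand per adenine, with placeholder score/coverage fields
(`score = 20 + 200·frac`, `coverage = 50`) — the density statistics use
only positions.

## Density statistics

`segment_density` counts calls in [start, end) on either strand over the
segment length. `family_density` pools all copies and divides by
consensus length × copy count exactly as defined, even though diverged
copies could in principle differ in length. Relative tables normalize to
the mean gene density; `control_gene` is a member of the gene class.
Rankings sort by density descending with lexicographic id tie-break.
Site-map offsets are genome-forward (not element-orientation-corrected);
orientation handling is out of scope.

One caveat for real-data reuse: per-gene density here uses genomic length;
the synthetic world has no introns, so the genomic/spliced distinction is
moot in-package but matters on a real annotation.

## Assay model

PCR is deterministic geometric amplification: signal = templates ×
(1+efficiency)^cycles, capped at a saturation level (default 10¹⁵
arbitrary units, efficiency 1.0, 32 cycles). Target templates are the
methylated (cut-and-ligated, ligation efficiency fixed at 1.0) molecules;
control templates are all molecules. One cycle count applies to both
target and control, which makes the relative level equal the methylated
fraction exactly in the linear regime — the estimator identity the tests
pin down; split cycle regimes (more target than control cycles) can be
expressed by overriding `cycles` per call, and the simulator warns whenever
the control saturates while the target does not, since ratios are then no
longer linear. No stochastic PCR noise is modeled: the sampling noise of
the molecule pool is the only randomness, which is what the ratio-based
quantification is sensitive to.

The packaged junction designs reproduce published primer chemistry from
first principles: the linker primer arm
`TATGAAACTCTCTTACCGTTAGGTCAGATCTA` with a 22 nt tail plus the 3-base
genomic head `TCC` past a `GA^TC` cut yields
`TCTTACCGTTAGGTCAGATCTATCC`, and the PvuII control design's head is
necessarily `CTG` (the cut is `CAG^CTG`). Primer specificity is exact
string matching (head + 10 bases, both strands, unique-occurrence
threshold); no thermodynamics. TE-targeted primers are intentionally
multi-copy and flagged non-unique.

## Expression model

Family transcript output λ = (b + γ·p(t; genotype)) × knockdown residuals
× stress, with defaults b = 0.2, γ = 10 and knockdown residual 0.5 (RNAi
roughly halves transcript levels). A per-family onset day (default 1)
shifts the trajectory for late-activating families. Reads are error-free
uniform substrings of the consensus library plus a constant-level
reference gene — the reference's constancy across age and genotype is a
modeling assumption mirroring reference-gene practice. Assignment is exact
unique-substring matching (either strand); ambiguous and unassigned reads
are counted, and counts are conserved. Group comparisons: two-sided
Student's t (equal variance; the identical-constant-groups degenerate case
returns t = 0, p = 1) or Mann–Whitney U (exact for small tie-free
samples), Bonferroni-adjusted (p_adj = min(1, m·p)).

## Survival model

Gompertz hazard h(t) = m·A·e^{Gt} with G = 0.25/day and A solved so the
control expected lifespan is 17 days (20 °C profile) or 13 days (25 °C
profile) — absolute scale is a fixture choice; only ratios matter.
Intervention multipliers act proportionally on A (a frailty-style single
knob) and are calibrated by Brent root finding so the continuous expected
lifespan hits the target extension to within 0.1 percentage points:
single-TE RNAi +10%, double knockdown +20% (additive), somatic Piwi +30%
(20 °C) and +20% (25 °C, reporter-free construct), daf-2 +100%. The
nmad-1 (−15%) and damt-1 (+10%) entries are directional placeholders (no
printed percentages exist for them) and are excluded from recovery
targets.

Cohorts are inverse-transform samples rounded *up* to whole days (daily
scoring); the rounding adds ≈ 0.5 day to both arms, which compresses
recovered extensions slightly (e.g. ≈ 9.7% for a 10% continuous target) —
well inside the recovery tolerances. Estimation: product-limit curves,
censored animals leave the risk set at their censor day with deaths
preceding censorings at ties; censor-free means are arithmetic with
sd/√n SEM, censored means are KM restricted means with Greenwood-based
variance; Mantel–Cox log-rank with 1 df.

## Orchestration and problem sizes

Named scenarios (`assay_age_fold`, `density_ratios`, `methylation_slope`,
`lifespan_recovery`) tie the stages together; stage seeds derive from the
master seed as the first 4 bytes of SHA-256("seed:stage") mod 2³¹, so
adding a stage never perturbs another's draws, and a rerun of the same
config is byte-identical. Default problem sizes — 10,000 molecules per
assay site, 20,000 reads, cohorts of 120 × 20 replicates, 5 replicate
seeds for density and slope recovery — were chosen so that each recovered
quantity's sampling error is several times smaller than its recovery
tolerance while a full run stays in the seconds-to-a-minute range on a
single core.

## What the generator does and does not show

Passing recovery tests demonstrates that the estimators are correct and
unbiased *under the generator's assumptions*: site-level Bernoulli
methylation, error-free reads, exact restriction/ligation chemistry,
proportional excision hazard, Gompertz mortality. Real data adds
sequencing error, kinetic-call artifacts, hemimethylation, PCR efficiency
drift, mapping ambiguity across diverged copies, and non-proportional
hazards — none of which are modeled. The package validates the analysis
pipeline, not the biology.

Known open tensions, noted rather than resolved: the PCR-based gene-locus
levels are described as nearly constant with age while the SMRT-based
analysis implies gene demethylation between days 1 and 5; the generator
follows the demethylation reading (λ > 0) because both SMRT ratio targets
require it. Score/coverage semantics of real kinetic callers are not
reproduced; placeholders are emitted.
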