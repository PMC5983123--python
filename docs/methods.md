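# Methods

## Model and assumptions

The score models post-transcriptional competition at a steady state: in each
round the cell presents a fresh pool of free miRNAs, and every transcript
with a complementary MRE pulls on that pool in proportion to its binding
mass. For gene *g* and miRNA *μ* the mass is

    M_g,μ = E_g · Σ_{MREs of g for μ} b,     b = c · |e| · a · s,

where `E_g` is the gene's arithmetic mean abundance over all samples (so a
single scalar summarizes the cohort; within-cohort expression heterogeneity
does not enter the score, only the correlation screen), `c` is the site's
conservation score, `e` its hybridization free energy, `a` its alignment
score and `s` the seed-type weight. The multiplicative form keeps the
affinity proportional under proportional changes of any feature; the free
energy enters by magnitude so that a more negative (stronger) duplex raises
the affinity. A transcript's several MREs for the same miRNA are additive.

For a directed pair (GOI, PCC), each miRNA in the pair's competed pool
splits its abundance `E_μ` in proportion to the two masses; the signed
excess captured by the candidate is

    term(μ) = E_μ · (M_PCC,μ − M_GOI,μ) / (M_PCC,μ + M_GOI,μ),

and the non-normalized score is the sum of these terms. The per-miRNA term
is bounded by ±E_μ, antisymmetric in the pair, monotone in either mass, and
defined as 0 when both masses vanish (the miRNA pulls on nothing). By
construction the raw score is antisymmetric under swapping GOI and PCC and
exactly zero for pairs with an empty competed pool.

The competed pool defaults to the *shared* miRNAs — those with at least one
MRE on both genes and a row in the miRNA expression matrix (miRNAs with
sites but no measured expression are skipped with a warning). A *union*
mode is available in which a one-sided miRNA hands its whole pool to the
gene that binds it; this makes one-sided sponging visible but breaks the
"no shared pool ⇒ zero" null, so shared is the default. A gene with zero
expression or all-zero affinities has zero mass everywhere and the partner
captures each shared pool entirely — complete dominance, not an error; a
gene absent from the MRE table altogether cannot be scored and raises.

Per gene of interest, raw scores are normalized by the maximum |raw score|
over that GOI's candidates, landing in [−1, +1] with at least one candidate
at magnitude 1 (all zero if every raw score is zero). The normalized score
is therefore *relative to the GOI's candidate set*: swapping GOI and PCC
negates the raw score but generally not the normalized one, because the two
orientations normalize within different families.

The relative binding affinity `b_PCC·z/(b_GOI+b_PCC)` with z = 2 (calibrated
so a gene against itself scores exactly 1) and the expression-weighted total
binding affinity built from it are exposed as standalone per-MRE
diagnostics. The headline score deliberately uses the mass-ratio form
above — the two formulations are not algebraically interchangeable, and the
mass-ratio form is the one whose degenerate-case semantics (null pool,
complete dominance, sign) are guaranteed and tested.

## Correlation screen

Candidate pairs must be positively co-expressed: Spearman ρ > 0 (average
ranks for ties; robust to the heavy-tailed, non-normal expression profiles
of tumors) with Benjamini–Hochberg adjusted p ≤ 0.001. P-values use the
two-sided t-approximation t = ρ·√((n−2)/(1−ρ²)) on n−2 df, standard at
cohort sample sizes; an exact permutation p (full enumeration) is available
opt-in for n ≤ 10. The BH family is the set of positively correlated pairs
only, since negative pairs are discarded on mechanistic grounds before any
testing; genome-wide correction is the default, with a per-GOI mode (family
= that gene's positive pairs) for the single-query use case. Genes constant
across samples or never expressed are excluded — rank correlation is
undefined on them.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| seed weights | 1.0 / 0.75 / 0.5 / 0.25 | weight `s` for 8mer / 7mer-m8 / 7mer-A1 / 6mer; the model fixes only the efficacy ordering, the evenly spaced defaults are this package's convention and are user-overridable |
| q_threshold | 0.001 | BH-adjusted p cutoff of the correlation screen |
| z | 2 | relative-affinity coefficient; fixed by the self-competition calibration |
| dominance_cutoff | 0.5 | \|score\| at or above which a pair is labeled *dominant* rather than *dependent*; the dominance/dependency distinction is qualitative and this numeric cutoff is a reporting convention of this package |
| score band | [0.00403, 0.88367], off by default | optional \|score\| filter spanning the validated-pair range |
| mirna_pool_mode | shared | competed pool: shared or union (see above) |

## Synthetic data

The generator emulates the statistical shape the scorer consumes, not
RNA-Seq mechanics. Gene expression uses a Gaussian copula with lognormal
marginals (default meanlog 1.5, sdlog 1.0 — median ≈ 4.5 with a heavy right
tail, an RPKM/RSEM-like shape): a planted block's target Spearman ρ_s is
converted to the latent Pearson r = 2·sin(π·ρ_s/6), and block rows are
built as √r·shared + √(1−r)·own, which is exact for a single-ρ block and
degenerates cleanly to co-monotone rows at ρ_s = 1; the monotone marginal
transform preserves ranks, so the Spearman target carries through.
miRNA rows are independent lognormal. MRE tables draw Poisson(mre_rate)
background sites per (gene, miRNA) with uniform features — energies in
[−30, −5] kcal/mol-like, conservation in [0, 1], alignment in [120, 200],
seed types at (0.15, 0.25, 0.25, 0.35) for (8mer, 7mer-m8, 7mer-A1, 6mer),
weaker matches the more frequent as in genome-wide scans — plus forced
sites to plant shared pools. All randomness descends from one integer seed
(expression stream `SeedSequence([seed, 0])`, site stream
`SeedSequence([seed, 1])`).

What the generator does *not* emulate: count noise and library-size
effects, sample-level covariation between miRNA and gene expression,
realistic MRE clustering along transcripts, and negative or zero-inflated
correlation structure. Passing tests therefore demonstrate the
correctness of the computation and the recoverability of planted structure,
not predictive performance on real tumor data.

## Numerical choices

Scores accumulate in double precision with compensated summation over
per-miRNA terms; antisymmetry is asserted at |sum| ≤ 1e−9·max(1, |raw|) and
scorer-vs-oracle agreement at the same relative tolerance. Degenerate
denominators (both masses zero; both affinities zero in the relative form)
are defined as 0 and an error respectively, as motivated above. Ranking
ties break by shared-miRNA count (more first), then candidate name, making
sorts stable and runs byte-for-byte reproducible. Expression matrices must
be complete; missing cells are an error, never imputed. The brute-force
reference evaluator (`ground_truth_scores`) shares no code with the scorer
and is capped at 10 genes × 10 miRNAs by design.

## Known limitations

The score uses cohort-mean expression, so it cannot distinguish
subpopulations in which competition reverses direction. Seed-weight values
beyond their ordering are unconstrained by the model; rankings can shift
under extreme user weights. The per-GOI normalization makes scores
comparable within one GOI's candidate list, not across GOIs or cohorts
(raw scores are comparable only under a fixed miRNA expression scale —
rescaling all miRNA abundances by k rescales raw scores by k and leaves
normalized scores unchanged). Kinetic simulation of the binding steady
state, transcript-class annotation and hypergeometric shared-miRNA testing
are out of scope.

## Problem sizes in the test and acceptance runs

The suite validates on many small instances rather than few large ones:
100 seeded instances of ≤ 5 genes × ≤ 5 miRNAs for oracle equivalence,
antisymmetry and normalization bounds; 50 replicates of a 50-gene,
100-sample cohort with a planted 5-gene block at ρ_s = 0.9 for screen
sensitivity; the acceptance script uses a 10-gene, 5-miRNA, 60-sample
instance. These sizes exercise every code path while keeping the whole
suite in the seconds-to-minutes range.
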