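# socer

Quantify and rank the **competing endogenous RNA (ceRNA)** propensity of
genes that share a miRNA pool, from RNA-Seq expression matrices and miRNA
target-site features.

Transcripts carrying miRNA response elements (MREs) for the same miRNAs
compete — "tug of war" — for that shared pool: when one transcript soaks up
more of a miRNA, its partner is de-repressed. Most ceRNA predictors only
propose candidate pairs; this package additionally says **which gene of a
pair sequesters more** and **how one-sided** the competition is, as a single
signed score per (gene of interest, candidate) pair.

## The model

For one MRE with conservation *c*, binding free energy *e* (≤ 0),
alignment score *a* and seed type weighted *s* (8mer ≥ 7mer-m8 ≥ 7mer-A1 ≥
6mer), the binding affinity is the product

```
b = c · |e| · a · s
```

For a gene *g* and miRNA *μ*, the binding mass is `M_g,μ = E_g · Σ b` (mean
expression across samples times the summed affinity of g's MREs for μ). The
non-normalized score of a (GOI, PCC) pair sums, over their shared miRNAs,
each miRNA's pool split by relative mass:

```
score_raw(GOI, PCC) = Σ_μ  E_μ · (M_PCC,μ − M_GOI,μ) / (M_PCC,μ + M_GOI,μ)
```

It is antisymmetric under swapping the pair and exactly zero when no miRNA
is shared. Per GOI, scores are divided by the largest absolute raw score, so
the reported score lies in **[−1, +1]**: −1 means the GOI monopolizes the
shared pools, +1 the candidate does, and values near zero mean the genes
pull with comparable strength (ceRNA *dependency* rather than *dominance*).

Candidate pairs are pre-filtered by co-expression: Spearman ρ > 0 with
Benjamini–Hochberg adjusted p ≤ 0.001 (ceRNA partners are positively
co-expressed; Spearman is robust to the heavy tails of tumor expression
profiles). Relative/total binding affinities (`b·2/(b_GOI+b_PCC)` per MRE,
expression-weighted sums) are exposed as standalone diagnostics, and an
optional filter keeps pairs with |score| in the recommended band
[0.00403, 0.88367] spanned by experimentally validated ceRNA pairs.

## Worked example

`examples/01_score_one_pair.py` builds a pair sharing two miRNAs — the
candidate has the stronger site for miR-a, the GOI two decent sites for
miR-b — and prints:

```
shared miRNAs: ('miR-a', 'miR-b')
  miR-a: term = +9.146  (pool of 12.0, PCC pulls harder)
  miR-b: term = -28.939  (pool of 30.0, GOI pulls harder)
raw score  = -19.794
normalized = -1.000  (sole candidate, so magnitude saturates at 1)
```

Each term is the signed share of that miRNA's pool (its mean expression)
captured by the candidate; miR-b's larger pool and the GOI's two sites
outweigh the candidate's advantage on miR-a, so the GOI is the stronger
sponge overall. `examples/02_rank_candidates.py` chains the co-expression
screen and scorer to rank all candidates of one gene, and
`examples/03_full_pipeline.py` runs the end-to-end pipeline from TSV files.

## Command line

```bash
socer simulate --out fixture --seed 7 --n-genes 20 --block 0,1,2:0.9
socer correlate --genes fixture/genes.tsv --out pairs.tsv
socer run --genes fixture/genes.tsv --mirnas fixture/mirnas.tsv \
          --sites fixture/sites.tsv --out results --goi G0000 --band on
```

Inputs are plain TSV: a gene matrix and a miRNA matrix (rows = entities,
columns = samples, RPKM/RSEM-like values) and a miRanda/mirSVR-style MRE
table (`mirna`, `gene`, `conservation`, `energy`, `alignment_score`,
`seed_type`). `socer run` writes `pairs.tsv`, `scores.tsv`,
`per_mirna_terms.tsv` and a `manifest.yaml`, atomically.

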