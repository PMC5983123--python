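"""Run the whole screen from TSV files on disk, the way the CLI does.

Writes a synthetic fixture (gene matrix, miRNA matrix, MRE table), builds a
RunConfig, and calls run_pipeline, which chains correlation -> scoring ->
ranking and writes pairs.tsv, scores.tsv, per_mirna_terms.tsv and a
manifest. Equivalent shell invocation:

    socer simulate --out fixture --seed 7 --block 0,1,2:0.95
    socer run --genes fixture/genes.tsv --mirnas fixture/mirnas.tsv \
              --sites fixture/sites.tsv --out results --goi G0000
"""

import tempfile
from pathlib import Path

from socer import (
    RunConfig,
    SimulationConfig,
    read_records,
    run_pipeline,
    simulate_expression,
    simulate_target_sites,
    write_expression,
    write_target_sites,
)

workdir = Path(tempfile.mkdtemp(prefix="socer-example-"))
config = SimulationConfig(
    n_genes=15,
    n_mirnas=8,
    n_samples=70,
    mre_rate=1.2,
    planted_blocks=(((0, 1, 2), 0.95),),
    seed=7,
)
genes, mirnas = simulate_expression(config)
sites = simulate_target_sites(config, shared_pairs=[("G0000", "G0001", ["miR-1"])])
write_expression(genes, workdir / "genes.tsv")
write_expression(mirnas, workdir / "mirnas.tsv")
write_target_sites(sites, workdir / "sites.tsv")

run = RunConfig(
    gene_expression=str(workdir / "genes.tsv"),
    mirna_expression=str(workdir / "mirnas.tsv"),
    target_sites=str(workdir / "sites.tsv"),
    output_dir=str(workdir / "results"),
    goi="G0000",
    fdr_mode="per_goi",
    q_threshold=0.001,
)
manifest = run_pipeline(run)

print("stage counts:", manifest["counts"])
records = read_records(
    workdir / "results" / "scores.tsv", workdir / "results" / "per_mirna_terms.tsv"
)
print(f"\nranked candidates of {run.goi}:")
for r in records:
    print(
        f"  {r.pcc}: norm = {r.norm_score:+.3f}, raw = {r.raw_score:+.2f}, "
        f"{r.n_shared_mirna} shared miRNA, {r.dominance_class.value}"
    )
print(f"\nresults written under {workdir / 'results'}")
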