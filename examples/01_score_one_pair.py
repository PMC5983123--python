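"""Score a single hand-built ceRNA pair and read off its tug-of-war terms.

Two genes share two miRNAs. For each shared miRNA the score weighs the
genes' binding masses (mean expression x summed site affinity) against each
other and hands the miRNA's pool to the stronger side in proportion to the
imbalance. Positive terms mean the candidate (PCC) out-sequesters the gene
of interest (GOI); negative terms mean the GOI does.
"""

from socer import AffinityTable, SeedType, TargetSite, normalize_scores, socer_raw

sites = [
    # miR-a: the candidate's site is far stronger (8mer, better energy)
    TargetSite("miR-a", "GOI", conservation=0.6, energy=-12.0, alignment_score=140, seed_type=SeedType.MER6),
    TargetSite("miR-a", "PCC", conservation=0.9, energy=-22.0, alignment_score=165, seed_type=SeedType.MER8),
    # miR-b: the GOI carries two decent sites, the candidate one weak site
    TargetSite("miR-b", "GOI", conservation=0.8, energy=-18.0, alignment_score=150, seed_type=SeedType.MER7_M8),
    TargetSite("miR-b", "GOI", conservation=0.7, energy=-15.0, alignment_score=145, seed_type=SeedType.MER7_A1),
    TargetSite("miR-b", "PCC", conservation=0.3, energy=-8.0, alignment_score=125, seed_type=SeedType.MER6),
]

mean_expression = {"GOI": 35.0, "PCC": 20.0}   # RPKM-like averages over samples
mirna_expression = {"miR-a": 12.0, "miR-b": 30.0}

table = AffinityTable.from_sites(sites, mean_expression)
pair = socer_raw("GOI", "PCC", table, mirna_expression)
(pair,) = normalize_scores([pair])

print(f"shared miRNAs: {pair.shared_mirnas}")
for mirna, term in pair.per_mirna_terms.items():
    winner = "PCC" if term > 0 else "GOI"
    print(f"  {mirna}: term = {term:+.3f}  (pool of {mirna_expression[mirna]}, {winner} pulls harder)")
print(f"raw score  = {pair.raw_score:+.3f}")
print(f"normalized = {pair.norm_score:+.3f}  (sole candidate, so magnitude saturates at 1)")
print("negative => the GOI sequesters more of the shared pool than the candidate")
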