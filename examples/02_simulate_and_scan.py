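"""Simulate a dataset with a planted epistatic pair and scan all SNP pairs.

The simulator plants a pure-epistasis interaction (penetrance model 1,
no marginal effects) in SNPs 1-2 of a 10-SNP, 200-case/200-control dataset;
the exhaustive scan should rank that pair first by u(I_OR).
"""

from force_epistasis import (PairFilterConfig, SimConfig, exhaustive_scan,
                             simulate_dataset)

gm, truth = simulate_dataset(SimConfig(model_id=1, seed=42))
print(f"simulated {gm.n_samples} samples x {gm.n_snps} SNPs; "
      f"planted pair: {truth['planted_pairs'][0]}")

# the genome-scale sparsity filters are meant for large case-control panels;
# at this toy size we disable them to score every pair
result = exhaustive_scan(gm, model="dominant",
                         filters=PairFilterConfig(0, 0, 0), top_k=5)
print(f"evaluated {result.n_evaluated} of {result.n_candidate_pairs} pairs\n")
print(result.pairs[["snp1", "snp2", "u_ior", "ior"]].to_string(index=False))
print()
print("the planted pair should top the ranking with u(I_OR) far above the")
print("null pairs, which hover near 1.")
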