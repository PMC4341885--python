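"""A reduced run of the power/FWER simulation benchmark.

Estimates detection power (planted pair at empirical P < 0.001) and
family-wise error rate (any other pair detected) over replicate datasets
for two penetrance models, with and without phenocopy noise.  The full
protocol uses 100 datasets per condition; 25 keep this example quick.
"""

from force_epistasis import power_table

table = power_table(model_ids=[1, 2], noise_conditions=[(), ("PC",)],
                    genetic_model="dominant", n_datasets=25,
                    n_perm=1000, alpha=0.001, seed=11)
print(table[["condition", "model", "power", "fwer"]].to_string(index=False))
print()
print("without noise both models are detected nearly always with FWER near")
print("the nominal ~0.04; phenocopy (half the cases non-genetic) roughly")
print("halves model-2 power and collapses model-1 power.")
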