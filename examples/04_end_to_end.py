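"""Full pipeline: structures -> clash profile -> NDRs -> match -> effects.

Runs every stage on a synthetic genome whose CpG methylation is coupled
(probability 0.8) to the idealized clash profile inside nucleosome-dense
territory, and prints the effect-size summary table: Cohen's d per
region class for nucleosome-dense (HNDR) vs nucleosome-depleted (LNDR)
windows of expressed genes, for sliding windows with 10-20 CpGs at c5m0.

Run:  python examples/04_end_to_end.py   (~20 s)
"""

from nucsteric import RunConfig, run_pipeline

cfg = RunConfig(out_dir="scratch/example_run", seed=17, n_genes=12, coupling=0.8)
report = run_pipeline(cfg)

table = report[
    (report["ncpg_bin"] == "10-20") & (report["expression_class"] == "expressed")
]
cols = ["region_class", "ndr_kind", "cohens_d", "wilcoxon_p", "n_exp", "size_class"]
print(table[cols].round(3).to_string(index=False))

# HNDR strata show a large effect (methylation tracks accessibility where
# nucleosomes are present); LNDR strata are the negative control: with no
# nucleosome there is no steric constraint for methylation to follow.
print("\noutputs written under scratch/example_run/ (TSV + BED with provenance headers)")
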