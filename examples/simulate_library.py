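"""Simulate a cDNA clone library and inspect its ground truth.

Builds a small synthetic transcriptome (with one recent paralog pair and
one divergent type-B allele), runs the clone-library model — geometric
reverse-transcriptase drop-off from the mRNA 3' end, 0.7 kb size
selection, paired Sanger-style reads with substitution errors — and
prints what the truth tables record.
"""
from fullorf import LibraryParams, simulate_clone_library, simulate_gene_set

genome, specs, gene_truth = simulate_gene_set(
    6, seed=11, paralog_pairs=1, ab_pairs=1
)
params = LibraryParams(n_clones_per_gene=12, rt_dropoff_p=0.001,
                       error_rate=0.01, seed=12)
ests, clone_truth = simulate_clone_library(specs, params)

print(f"genes simulated:     {len(specs)} "
      f"(incl. 1 paralog copy, 1 type-B allele)")
print(f"genome size:         {sum(len(s) for s in genome.values())} bp")
print(f"clones surviving     {clone_truth.shape[0]} "
      f"(size selection removes inserts < {params.min_insert_bp} bp)")
print(f"end reads:           {len(ests)}")
full = clone_truth["full_orf"].mean()
print(f"full-ORF fraction:   {full:.2f} "
      "(clones whose insert reaches 5' of the initiator ATG)")
print("\nfirst truth rows (t5 = 5' truncation point on the mRNA):")
print(clone_truth.head(4).to_string(index=False))
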