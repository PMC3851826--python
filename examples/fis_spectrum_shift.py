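"""Show how splitting merged homeologs repairs the Fis spectrum.

Before splitting, fixed divergence between the two merged copies appears
as SNPs with a heterozygote excess (Fis near -1 or below the homologous
threshold).  After splitting and re-mapping, those sites vanish and the
genuine within-genome SNPs of this selfing panel come out at Fis ~ +1.
"""

from homeosplit import (
    best_split,
    find_questionable_sites,
    fis_spectrum,
    is_questionable_contig,
    remapped_dataset,
    simulate_dataset,
)

dataset, truths = simulate_dataset(
    n_contigs=30, fraction_mixed=0.5, length=300, n_divergent=10,
    n_accessions=30, coverage_lambda=30.0, error_rate=0.005, seed=7,
)

results = {}
for contig in dataset:
    qset = find_questionable_sites(contig)
    if is_questionable_contig(qset):
        results[contig.contig_id] = best_split(contig, qset, mode="heuristic")

before, _ = fis_spectrum(dataset)
after, _ = fis_spectrum(remapped_dataset(dataset, truths, results))

for label, table in (("before split", before), ("after split", after)):
    fis = table["fis"].dropna()
    frac = (fis > 0.6).mean() if len(fis) else float("nan")
    print(f"{label:>12}: {len(fis):4d} bi-allelic SNPs with defined Fis, "
          f"{100 * frac:5.1f}% homologous (Fis > 0.6)")
# The drop in SNP count is the point: the spurious "SNPs" caused by merged
# homeologs disappear, and nearly all surviving SNPs are usable markers.
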