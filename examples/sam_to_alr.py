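"""Convert per-accession SAM mappings to ALR counts and screen them.

Emits error-free reads from a contig for three "accessions", pileup-counts
each SAM into the shared ALR matrix, writes/reads the ALR file, and runs
the heterozygosity screen (all monomorphic here, as expected without
homeolog mixing).
"""

import tempfile
from pathlib import Path

import numpy as np

from homeosplit import (
    find_questionable_sites,
    read_alr,
    sam_to_alr,
    write_alr,
    write_reads_sam,
)

rng = np.random.default_rng(0)
sequence = "".join(rng.choice(list("ACGT"), size=400))

workdir = Path(tempfile.mkdtemp())
ref_fasta = workdir / "ref.fa"
ref_fasta.write_text(f">gene1\n{sequence}\n")

sam_paths = []
for a in range(3):
    path = workdir / f"accession{a + 1}.sam"
    write_reads_sam(sequence, n_reads=60, read_length=80, path=path,
                    contig_id="gene1", seed=a)
    sam_paths.append(path)

dataset = sam_to_alr(sam_paths, ref_fasta, min_base_quality=20, min_mapping_quality=10)
alr_path = workdir / "mapping.alr"
write_alr(dataset, alr_path)
dataset = read_alr(alr_path)

contig = dataset.contigs[0]
qset = find_questionable_sites(contig)
print(f"accessions: {contig.accession_ids}")
print(f"contig {contig.contig_id}: {contig.length} sites, "
      f"mean coverage {contig.mean_coverage():.1f}X")
print(f"questionable sites: {qset.n_questionable} "
      "(0 expected: one clean gene copy, no homeolog mixing)")
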