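"""Synthetic allo-tetraploid RNA-seq count data with known homeolog truth.

The generator emulates the biological regime the splitter targets: two
sub-genome gene copies at ~97.5% identity, expressed in the same contig by
a panel of ~30 near-inbred accessions, each with its own expression bias
between the copies.  Per accession and site, total coverage is Poisson,
reads are allocated to the two copies binomially by the accession's bias,
and a small uniform sequencing-error rate scatters reads onto the other
three nucleotides.  Optional homologous SNPs place a derived allele on one
copy, fixed within carrier accessions (selfing), which reproduces the
trimodal Fis structure of real selfing panels.

Every draw is governed by a single integer seed (numpy's PCG64 generator),
so datasets are byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alr_io import AlrDataset, ContigCounts
from .nucleotides import NUCLEOTIDES, OTHER_INDICES, indices_to_seq, seq_to_indices
from .splitter import SplitResult

import pandas as pd

#: Dataset-level default for homologous (within-genome) SNPs: density per
#: non-divergent site, with minor-allele frequency drawn uniformly.
DEFAULT_HOMOLOGOUS_SNPS = {"rate": 0.005, "maf_range": (0.1, 0.5)}

#: Default per-accession expression-bias distribution: Beta(6, 2) (mean
#: 0.75), orientation-flipped per accession with probability 1/2, so the
#: dominant copy differs between accessions and the pooled signal blurs.
DEFAULT_BIAS = {"kind": "beta", "a": 6.0, "b": 2.0, "flip": True}


@dataclass
class SimTruth:
    """Ground truth of one simulated contig.

    ``divergent_sites`` holds ``(site, (nuc_a, nuc_b))`` with 1-based
    nucleotide indices of the two homeologs at each planted divergent
    site; ``biases`` is the true per-accession proportion of homeolog A.
    ``counts_by_copy`` (2 x M x N x 4) records which copy every counted
    base came from, enabling count-level re-mapping emulation.
    ``hom_snps`` lists the planted homologous SNPs as dicts with keys
    site, copy (0=A, 1=B), derived (1-based), carriers (bool array), maf.
    """

    contig_id: str
    homeolog_a: str
    homeolog_b: str
    divergent_sites: list[tuple[int, tuple[int, int]]]
    biases: np.ndarray
    params: dict
    hom_snps: list[dict] = field(default_factory=list)
    counts_by_copy: np.ndarray | None = None

    @property
    def is_mixed(self) -> bool:
        return len(self.divergent_sites) > 0


def _draw_biases(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec is None:
        spec = DEFAULT_BIAS
    if isinstance(spec, (list, tuple, np.ndarray)) and not isinstance(spec, dict):
        biases = np.asarray(spec, dtype=float)
        if biases.shape != (n,):
            raise ValueError("explicit bias array must have one entry per accession")
    else:
        kind = spec.get("kind")
        if kind == "beta":
            biases = rng.beta(spec["a"], spec["b"], size=n)
        elif kind == "uniform":
            biases = rng.uniform(spec["low"], spec["high"], size=n)
        elif kind == "fixed":
            biases = np.full(n, float(spec["value"]))
        else:
            raise ValueError(f"unknown bias distribution {spec!r}")
        if spec.get("flip"):
            flip = rng.random(n) < 0.5
            biases = np.where(flip, 1.0 - biases, biases)
    if ((biases < 0) | (biases > 1)).any():
        raise ValueError("biases must lie in [0, 1]")
    return biases


def simulate_contig(
    length: int = 1000,
    n_divergent: int | None = None,
    n_accessions: int = 30,
    coverage_lambda: float = 30.0,
    error_rate: float = 0.005,
    bias_distribution=None,
    homologous_snps: dict | None = None,
    seed: int = 0,
    contig_id: str = "contig",
    accession_ids: Sequence[str] | None = None,
) -> tuple[ContigCounts, SimTruth]:
    """Simulate one contig's count matrix plus its ground truth.

    ``n_divergent`` defaults to 2.5% of the length (the typical divergence
    between the two sub-genome references).  ``homologous_snps`` is either
    None (no within-genome polymorphism) or a dict with ``rate`` (per
    non-divergent site) and ``maf_range``.  The returned
    :class:`ContigCounts` carries the global consensus as ``ref_seq`` —
    the sequence a de novo assembly of the pooled reads would produce.
    """
    if n_divergent is None:
        n_divergent = round(0.025 * length)
    if n_divergent > length:
        raise ValueError("n_divergent cannot exceed the contig length")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    m = n_accessions

    base_a = rng.integers(0, 4, size=length)
    base_b = base_a.copy()
    div_sites = np.sort(rng.choice(length, size=n_divergent, replace=False))
    for s in div_sites:
        base_b[s] = OTHER_INDICES[base_a[s]][rng.integers(0, 3)]

    hom_snps: list[dict] = []
    if homologous_snps is not None and homologous_snps.get("rate", 0) > 0:
        available = np.setdiff1d(np.arange(length), div_sites)
        n_hom = rng.binomial(len(available), homologous_snps["rate"])
        hom_sites = rng.choice(available, size=n_hom, replace=False)
        lo, hi = homologous_snps.get("maf_range", (0.1, 0.5))
        for s in np.sort(hom_sites):
            copy = int(rng.integers(0, 2))
            ref_base = (base_a, base_b)[copy][s]
            derived = int(OTHER_INDICES[ref_base][rng.integers(0, 3)])
            maf = rng.uniform(lo, hi)
            carriers = rng.random(m) < maf
            hom_snps.append(
                {
                    "site": int(s),
                    "copy": copy,
                    "derived": derived + 1,
                    "carriers": carriers,
                    "maf": float(maf),
                }
            )

    biases = _draw_biases(bias_distribution, m, rng)
    counts_by_copy = np.zeros((2, m, length, 4), dtype=np.int64)
    positions = np.arange(length)
    for a in range(m):
        copy_seqs = [base_a.copy(), base_b.copy()]
        for snp in hom_snps:
            if snp["carriers"][a]:
                copy_seqs[snp["copy"]][snp["site"]] = snp["derived"] - 1
        totals = rng.poisson(coverage_lambda, size=length)
        n_a = rng.binomial(totals, biases[a])
        for copy, n_reads in ((0, n_a), (1, totals - n_a)):
            seq = copy_seqs[copy]
            if error_rate > 0.0:
                correct = rng.binomial(n_reads, 1.0 - error_rate)
                errors = rng.multinomial(n_reads - correct, [1 / 3] * 3)
            else:
                correct = n_reads
                errors = None
            counts_by_copy[copy, a, positions, seq] += correct
            if errors is not None:
                others = OTHER_INDICES[seq]  # (length, 3)
                for j in range(3):
                    counts_by_copy[copy, a, positions, others[:, j]] += errors[:, j]

    counts = counts_by_copy.sum(axis=0)
    global_counts = counts.sum(axis=0)  # (length, 4)
    consensus = global_counts.argmax(axis=1)
    uncovered = global_counts.sum(axis=1) == 0
    consensus[uncovered] = base_a[uncovered]

    if accession_ids is None:
        accession_ids = [f"acc{a + 1:02d}" for a in range(m)]
    contig = ContigCounts(
        contig_id=contig_id,
        accession_ids=list(accession_ids),
        ref_seq=indices_to_seq(consensus),
        counts=counts,
    )
    truth = SimTruth(
        contig_id=contig_id,
        homeolog_a=indices_to_seq(base_a),
        homeolog_b=indices_to_seq(base_b),
        divergent_sites=[
            (int(s), (int(base_a[s]) + 1, int(base_b[s]) + 1)) for s in div_sites
        ],
        biases=biases,
        params={
            "length": length,
            "n_divergent": int(n_divergent),
            "n_accessions": m,
            "coverage_lambda": coverage_lambda,
            "error_rate": error_rate,
            "homologous_snps": homologous_snps,
            "seed": seed,
        },
        hom_snps=hom_snps,
        counts_by_copy=counts_by_copy,
    )
    return contig, truth


def simulate_dataset(
    n_contigs: int = 50,
    fraction_mixed: float = 0.4,
    length: int = 1000,
    n_divergent: int | None = None,
    n_accessions: int = 30,
    coverage_lambda: float = 30.0,
    error_rate: float = 0.005,
    bias_distribution=None,
    homologous_snps: dict | None = DEFAULT_HOMOLOGOUS_SNPS,
    seed: int = 0,
) -> tuple[AlrDataset, list[SimTruth]]:
    """Simulate a dataset mixing merged-homeolog and clean contigs.

    A fraction ``fraction_mixed`` of the contigs are mixed homeolog pairs
    (with ``n_divergent`` divergent sites each); the rest are clean
    single-copy contigs (all reads from one copy, no divergent sites).
    Homologous SNPs are planted on both kinds.  All contigs share one
    accession panel; the whole dataset is deterministic by ``seed``.
    """
    if not 0.0 <= fraction_mixed <= 1.0:
        raise ValueError("fraction_mixed must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_mixed = round(fraction_mixed * n_contigs)
    mixed_flags = np.zeros(n_contigs, dtype=bool)
    mixed_flags[:n_mixed] = True
    mixed_flags = mixed_flags[rng.permutation(n_contigs)]
    accession_ids = [f"acc{a + 1:02d}" for a in range(n_accessions)]

    contigs = []
    truths = []
    for i, mixed in enumerate(mixed_flags):
        child_seed = int(rng.integers(0, 2**31 - 1))
        kwargs = dict(
            length=length,
            n_accessions=n_accessions,
            coverage_lambda=coverage_lambda,
            error_rate=error_rate,
            homologous_snps=homologous_snps,
            seed=child_seed,
            contig_id=f"contig_{i + 1:04d}",
            accession_ids=accession_ids,
        )
        if mixed:
            contig, truth = simulate_contig(
                n_divergent=n_divergent,
                bias_distribution=bias_distribution,
                **kwargs,
            )
        else:
            contig, truth = simulate_contig(
                n_divergent=0,
                bias_distribution={"kind": "fixed", "value": 1.0},
                **kwargs,
            )
        contigs.append(contig)
        truths.append(truth)
    return AlrDataset(contigs), truths


def recovery_report(
    results: list[SplitResult], truths: list[SimTruth]
) -> pd.DataFrame:
    """Compare splits with the planted truth, orientation-free.

    Per contig: the fraction of planted divergent sites whose unordered
    nucleotide pair {Ck1, Ck2} equals the planted pair (sites the screen
    missed count as unrecovered), and the bias-estimation mean absolute
    error |p1 - true bias| minimised over the two pattern orientations.
    """
    truth_by_id = {t.contig_id: t for t in truths}
    rows = []
    for result in results:
        if result.contig_id not in truth_by_id:
            raise KeyError(f"no truth for contig {result.contig_id!r}")
        truth = truth_by_id[result.contig_id]
        site_pos = {int(s): j for j, s in enumerate(result.sites)}
        n_planted = len(truth.divergent_sites)
        recovered = 0
        for site, pair in truth.divergent_sites:
            j = site_pos.get(site)
            if j is None:
                continue
            if {int(result.ck1[j]), int(result.ck2[j])} == set(pair):
                recovered += 1
        defined = ~np.isnan(result.p1)
        if defined.any():
            e_direct = np.abs(result.p1[defined] - truth.biases[defined]).mean()
            e_swapped = np.abs(
                (1.0 - result.p1[defined]) - truth.biases[defined]
            ).mean()
            bias_mae = float(min(e_direct, e_swapped))
        else:
            bias_mae = float("nan")
        rows.append(
            {
                "contig_id": result.contig_id,
                "n_divergent": n_planted,
                "n_recovered": recovered,
                "site_accuracy": recovered / n_planted if n_planted else float("nan"),
                "bias_mae": bias_mae,
                "method": result.method,
            }
        )
    return pd.DataFrame(rows)


def remap_split_counts(
    truth: SimTruth, result: SplitResult
) -> tuple[ContigCounts, ContigCounts]:
    """Emulate re-mapping reads onto the two split contigs, at count level.

    Each (accession, copy) read population is assigned wholly to the split
    sequence its true copy sequence (including the accession's homologous
    alleles) matches best at the questionable sites — the count-level
    analogue of a mapper's best-hit choice, exact here because all reads
    of one copy in one accession are identical up to sequencing error.
    Ties go to the first split contig.  A chimeric split attracts both
    copies to the same output contig and so keeps the heterozygote excess.
    """
    if truth.counts_by_copy is None:
        raise ValueError("truth does not carry per-copy counts")
    q = result.sites
    split_idx = [seq_to_indices(result.seq1)[q], seq_to_indices(result.seq2)[q]]
    base = [seq_to_indices(truth.homeolog_a), seq_to_indices(truth.homeolog_b)]
    m = len(truth.biases)
    n = len(truth.homeolog_a)
    counts = [np.zeros((m, n, 4), dtype=np.int64) for _ in range(2)]
    for a in range(m):
        for copy in range(2):
            copy_q = base[copy][q].copy()
            for snp in truth.hom_snps:
                if snp["copy"] == copy and snp["carriers"][a]:
                    j = np.nonzero(q == snp["site"])[0]
                    if len(j):
                        copy_q[j[0]] = snp["derived"] - 1
            d1 = int((copy_q != split_idx[0]).sum())
            d2 = int((copy_q != split_idx[1]).sum())
            target = 0 if d1 <= d2 else 1
            counts[target][a] += truth.counts_by_copy[copy, a]
    accession_ids = [f"acc{a + 1:02d}" for a in range(m)]
    return (
        ContigCounts(f"{truth.contig_id}_1", accession_ids, result.seq1, counts[0]),
        ContigCounts(f"{truth.contig_id}_2", accession_ids, result.seq2, counts[1]),
    )


def remapped_dataset(
    dataset: AlrDataset,
    truths: list[SimTruth],
    results: dict[str, SplitResult],
) -> AlrDataset:
    """Dataset after splitting: split contigs re-mapped, the rest unchanged."""
    truth_by_id = {t.contig_id: t for t in truths}
    contigs = []
    for contig in dataset:
        result = results.get(contig.contig_id)
        if result is None:
            contigs.append(contig)
        else:
            c1, c2 = remap_split_counts(truth_by_id[contig.contig_id], result)
            c1 = ContigCounts(c1.contig_id, contig.accession_ids, c1.ref_seq, c1.counts)
            c2 = ContigCounts(c2.contig_id, contig.accession_ids, c2.ref_seq, c2.counts)
            contigs.append(c1)
            contigs.append(c2)
    return AlrDataset(contigs)


def write_reads_sam(
    sequence: str,
    n_reads: int,
    read_length: int,
    path,
    contig_id: str = "ref",
    seed: int = 0,
    base_quality: int = 40,
    mapping_quality: int = 60,
) -> np.ndarray:
    """Emit error-free reads from a sequence as a SAM file (one accession).

    Reads are exact substrings at uniformly drawn start positions, written
    with constant base and mapping qualities.  Returns the (N, 4)
    bookkeeping count matrix the resulting pileup must reproduce, so the
    emitter doubles as an oracle for SAM-to-ALR conversion.
    """
    import pysam

    n = len(sequence)
    if read_length > n:
        raise ValueError("read_length exceeds the sequence length")
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(0, n - read_length + 1, size=n_reads))
    counts = np.zeros((n, 4), dtype=np.int64)
    seq_idx = seq_to_indices(sequence)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": contig_id, "LN": n}],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, start in enumerate(starts):
            read = pysam.AlignedSegment(header)
            read.query_name = f"read{i:06d}"
            read.query_sequence = sequence[start : start + read_length]
            read.flag = 0
            read.reference_id = 0
            read.reference_start = int(start)
            read.mapping_quality = mapping_quality
            read.cigarstring = f"{read_length}M"
            read.query_qualities = pysam.qualitystring_to_array(
                chr(33 + base_quality) * read_length
            )
            out.write(read)
            span = np.arange(start, start + read_length)
            counts[span, seq_idx[span]] += 1
    return counts
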