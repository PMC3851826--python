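"""Evaluate splits against diploid reference consensus sequences.

When consensus sequences of the two progenitor-like references are
available for a contig (``uk`` for the A-genome-like reference, ``sk``
for the B-genome-like one), a split can be scored by how much closer its
two sequences are to that "golden standard" than the original contig was:

    diffSym(Ck) = max(sim(Ck1,Uk) + sim(Ck2,Sk),
                      sim(Ck2,Uk) + sim(Ck1,Sk))
                - (sim(Ck,Uk) + sim(Ck,Sk))

with ``sim`` the percentage of identical nucleotides along the overlap of
two pre-aligned sequences.  The max makes even random splits average
slightly positive, so two seeded random-split baselines are provided for
paired comparisons on identical contigs.

All sequences entering these functions must be pre-aligned on common
coordinates (equal length, ``-`` for gaps); any external aligner can feed
this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alr_io import ContigCounts
from .site_screen import QuestionableSet
from .splitter import SplitResult, split_log_likelihood

GAP = "-"


@dataclass
class HomeologReferencePair:
    """Aligned consensus sequences of the two diploid-like references.

    ``uk`` and ``sk`` must be on the same coordinates as the contig under
    test (same length; gaps allowed).  By construction of a usable
    benchmark each overlaps the contig by at least ``min_overlap`` (100)
    non-gap columns.
    """

    uk: str
    sk: str


def pairwise_similarity(x: str, y: str, gap: str = GAP) -> tuple[float, int]:
    """Percent identity along the overlap of two pre-aligned sequences.

    Overlap counts columns where both sequences are non-gap; similarity is
    100 * identical columns / overlap, NaN when the overlap is empty.
    """
    if len(x) != len(y):
        raise ValueError("sequences must be pre-aligned to equal length")
    xa = np.frombuffer(x.encode("ascii"), dtype=np.uint8)
    ya = np.frombuffer(y.encode("ascii"), dtype=np.uint8)
    g = ord(gap)
    both = (xa != g) & (ya != g)
    overlap = int(both.sum())
    if overlap == 0:
        return float("nan"), 0
    identical = int(((xa == ya) & both).sum())
    return 100.0 * identical / overlap, overlap


def diff_sym(
    ck: str,
    ck1: str,
    ck2: str,
    refs: HomeologReferencePair,
    min_overlap: int = 100,
) -> float:
    """Similarity gain of a split over the original contig (NaN if undefined).

    Requires every contig/reference overlap to reach ``min_overlap``
    non-gap columns, mirroring the >= 100 bp benchmark filter; contigs
    failing it are excluded from evaluation.
    """
    sims = {}
    for name, seq in (("ck", ck), ("ck1", ck1), ("ck2", ck2)):
        for rname, ref in (("uk", refs.uk), ("sk", refs.sk)):
            sim, overlap = pairwise_similarity(seq, ref)
            if overlap < min_overlap:
                return float("nan")
            sims[name, rname] = sim
    split_score = max(
        sims["ck1", "uk"] + sims["ck2", "sk"],
        sims["ck2", "uk"] + sims["ck1", "sk"],
    )
    return split_score - (sims["ck", "uk"] + sims["ck", "sk"])


def _observed_nucleotides(contig: ContigCounts, site: int) -> np.ndarray:
    """1-based indices of nucleotides with a positive global count at a site."""
    return np.nonzero(contig.counts[:, site, :].sum(axis=0) > 0)[0] + 1


def random_split_same_count(
    contig: ContigCounts,
    qset: QuestionableSet,
    n_changed: int,
    rng_seed: int,
) -> SplitResult:
    """Baseline: flip ``n_changed`` random questionable sites of the consensus.

    The changed sites are drawn uniformly without replacement; each flips
    to a uniformly chosen *different* nucleotide observed at that site.
    Scored with the standard likelihood; reproducible by seed.
    """
    if n_changed > qset.n_questionable:
        raise ValueError("n_changed exceeds the number of questionable sites")
    rng = np.random.default_rng(rng_seed)
    counts_q = contig.counts[:, qset.questionable_sites, :]
    mf1g = counts_q.sum(axis=0).argmax(axis=1) + 1  # consensus at questionable sites
    pattern = mf1g.copy()
    chosen = rng.choice(qset.n_questionable, size=n_changed, replace=False)
    for j in chosen:
        site = int(qset.questionable_sites[j])
        observed = _observed_nucleotides(contig, site)
        alternatives = observed[observed != pattern[j]]
        if len(alternatives):
            pattern[j] = int(rng.choice(alternatives))
    return split_log_likelihood(contig, qset, pattern, method="random-same-count")


def random_split_per_site(
    contig: ContigCounts,
    qset: QuestionableSet,
    rng_seed: int,
) -> SplitResult:
    """Baseline: draw every questionable site uniformly among observed bases."""
    if qset.n_questionable == 0:
        raise ValueError("no questionable sites to randomise")
    rng = np.random.default_rng(rng_seed)
    pattern = np.empty(qset.n_questionable, dtype=np.int64)
    for j, site in enumerate(qset.questionable_sites):
        observed = _observed_nucleotides(contig, int(site))
        pattern[j] = int(rng.choice(observed))
    return split_log_likelihood(contig, qset, pattern, method="random-per-site")
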