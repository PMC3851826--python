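"""Detect heterozygous sites, questionable sites and questionable contigs.

When two homeologous gene copies are merged into one contig, accessions
appear heterozygous at every site where the two sub-genomes diverge.  In a
highly selfing panel genuine heterozygosity is rare, so an excess of
heterozygous accessions at a site flags it as *questionable*, and a contig
holding at least one such site (with adequate coverage) as a candidate
merged homeolog pair.

Rules (all thresholds user-tunable):

* an accession is heterozygous at a site when at least two different
  nucleotides are each observed at least ``min_allele_count`` (5) times;
* a site is questionable when at least ``het_fraction`` (1/8) of the
  genotyped accessions are heterozygous there, with "genotyped" meaning
  site coverage >= ``min_genotyped_coverage`` (10);
* a contig is questionable when it has >= 1 questionable site and a mean
  coverage of at least ``min_mean_coverage`` (5X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alr_io import ContigCounts
from .nucleotides import MISSING


@dataclass
class SiteSummary:
    """Per-site global and per-accession summaries of the count matrix.

    Nucleotide indices are 1-based (A=1..T=4), 0 meaning missing.
    """

    site_index: int
    mf1_global: int
    mf2_global: int
    mf1_per_accession: np.ndarray
    het_flags: np.ndarray
    genotyped_flags: np.ndarray
    total_coverage: int


@dataclass
class QuestionableSet:
    """Questionable sites of one contig plus its mean coverage.

    ``questionable_sites`` holds strictly increasing 0-based site indices;
    ``n_het``/``n_genotyped`` are the per-questionable-site accession
    counts behind the decision (aligned with ``questionable_sites``).
    """

    contig_id: str
    questionable_sites: np.ndarray
    mean_coverage: float
    n_het: np.ndarray | None = None
    n_genotyped: np.ndarray | None = None

    def __post_init__(self):
        self.questionable_sites = np.asarray(self.questionable_sites, dtype=np.int64)
        if len(self.questionable_sites) > 1 and not (
            np.diff(self.questionable_sites) > 0
        ).all():
            raise ValueError("questionable site indices must be strictly increasing")

    @property
    def n_questionable(self) -> int:
        return len(self.questionable_sites)


def _mf_indices_2d(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (mf1, mf2) over a (K, 4) count array, 1-based, 0 missing.

    Ties are broken toward the smallest index (A < C < G < T).
    """
    counts = np.asarray(counts, dtype=np.int64)
    mf1 = counts.argmax(axis=1)
    masked = counts.copy()
    masked[np.arange(len(counts)), mf1] = -1
    mf2 = masked.argmax(axis=1)
    mf1_out = np.where(counts[np.arange(len(counts)), mf1] > 0, mf1 + 1, MISSING)
    mf2_out = np.where(masked[np.arange(len(counts)), mf2] > 0, mf2 + 1, MISSING)
    return mf1_out.astype(np.int64), mf2_out.astype(np.int64)


def most_frequent_indices(count_vector) -> tuple[int, int]:
    """Indices of the most and second most frequent nucleotide (1-based).

    Ties are broken toward the smallest index.  An all-zero vector yields
    ``(0, 0)`` (missing marker); a vector with a single observed
    nucleotide yields ``(mf1, 0)``.
    """
    vec = np.asarray(count_vector, dtype=np.int64)
    if vec.shape != (4,):
        raise ValueError("count_vector must have exactly 4 entries")
    if (vec < 0).any():
        raise ValueError("counts must be non-negative")
    mf1, mf2 = _mf_indices_2d(vec[None, :])
    return int(mf1[0]), int(mf2[0])


def is_heterozygous(count_vector, min_allele_count: int = 5) -> bool:
    """True when at least two nucleotides each reach ``min_allele_count``."""
    vec = np.asarray(count_vector, dtype=np.int64)
    return int((vec >= min_allele_count).sum()) >= 2


def summarize_sites(contig: ContigCounts, sites=None) -> list[SiteSummary]:
    """Compute :class:`SiteSummary` for the given sites (default: all)."""
    if sites is None:
        sites = np.arange(contig.length)
    sites = np.asarray(sites, dtype=np.int64)
    counts = contig.counts[:, sites, :]  # (M, K, 4)
    global_counts = counts.sum(axis=0)  # (K, 4)
    mf1g, mf2g = _mf_indices_2d(global_counts)
    het = (counts >= 5).sum(axis=2) >= 2
    cov = counts.sum(axis=2)
    out = []
    for j, s in enumerate(sites):
        mf1a, _ = _mf_indices_2d(counts[:, j, :])
        out.append(
            SiteSummary(
                site_index=int(s),
                mf1_global=int(mf1g[j]),
                mf2_global=int(mf2g[j]),
                mf1_per_accession=mf1a,
                het_flags=het[:, j].copy(),
                genotyped_flags=(cov[:, j] >= 10).copy(),
                total_coverage=int(global_counts[j].sum()),
            )
        )
    return out


def _site_het_stats(
    contig: ContigCounts,
    min_allele_count: int,
    min_genotyped_coverage: int,
    denominator: str,
) -> tuple[np.ndarray, np.ndarray]:
    het = (contig.counts >= min_allele_count).sum(axis=2) >= 2  # (M, N)
    cov = contig.counts.sum(axis=2)
    if denominator == "genotyped":
        n_genotyped = (cov >= min_genotyped_coverage).sum(axis=0)
    elif denominator == "all":
        n_genotyped = np.full(contig.length, contig.n_accessions, dtype=np.int64)
    else:
        raise ValueError("denominator must be 'genotyped' or 'all'")
    return het.sum(axis=0), n_genotyped


def find_questionable_sites(
    contig: ContigCounts,
    min_allele_count: int = 5,
    het_fraction: float = 1 / 8,
    min_genotyped_coverage: int = 10,
    denominator: str = "genotyped",
) -> QuestionableSet:
    """Return the questionable sites of a contig.

    A site is questionable iff the number of heterozygous accessions is
    >= max(1, het_fraction * number of genotyped accessions at the site).
    With ``denominator="all"`` the fraction is taken over all M accessions
    instead of the genotyped ones.
    """
    n_het, n_genotyped = _site_het_stats(
        contig, min_allele_count, min_genotyped_coverage, denominator
    )
    threshold = np.maximum(1.0, het_fraction * n_genotyped)
    mask = n_het >= threshold
    sites = np.nonzero(mask)[0]
    return QuestionableSet(
        contig_id=contig.contig_id,
        questionable_sites=sites,
        mean_coverage=contig.mean_coverage(),
        n_het=n_het[sites],
        n_genotyped=n_genotyped[sites],
    )


def is_questionable_contig(qset: QuestionableSet, min_mean_coverage: float = 5.0) -> bool:
    """True iff the contig has >= 1 questionable site and >= 5X mean coverage."""
    return qset.n_questionable >= 1 and qset.mean_coverage >= min_mean_coverage


def questionable_set_from_sites(contig: ContigCounts, sites) -> QuestionableSet:
    """Build a :class:`QuestionableSet` from externally supplied site indices.

    Supports pipelines that detect questionable sites with another tool;
    ``sites`` are 0-based and must be valid for the contig.
    """
    sites = np.asarray(sorted(set(int(s) for s in sites)), dtype=np.int64)
    if len(sites) and (sites[0] < 0 or sites[-1] >= contig.length):
        raise ValueError("site index out of range")
    n_het, n_genotyped = _site_het_stats(contig, 5, 10, "genotyped")
    return QuestionableSet(
        contig_id=contig.contig_id,
        questionable_sites=sites,
        mean_coverage=contig.mean_coverage(),
        n_het=n_het[sites],
        n_genotyped=n_genotyped[sites],
    )


def screen_table(
    contig: ContigCounts,
    min_allele_count: int = 5,
    het_fraction: float = 1 / 8,
    min_genotyped_coverage: int = 10,
    denominator: str = "genotyped",
) -> pd.DataFrame:
    """Per-site screening statistics for sites with >= 1 heterozygous accession.

    Columns: contig_id, position (1-based), n_het, n_genotyped, questionable.
    """
    n_het, n_genotyped = _site_het_stats(
        contig, min_allele_count, min_genotyped_coverage, denominator
    )
    threshold = np.maximum(1.0, het_fraction * n_genotyped)
    questionable = n_het >= threshold
    keep = n_het >= 1
    return pd.DataFrame(
        {
            "contig_id": contig.contig_id,
            "position": np.nonzero(keep)[0] + 1,
            "n_het": n_het[keep],
            "n_genotyped": n_genotyped[keep],
            "questionable": questionable[keep],
        }
    )
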