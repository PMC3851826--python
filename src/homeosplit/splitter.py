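"""Maximum-likelihood splitting of merged homeologous contigs.

A *split* of a questionable contig assigns one nucleotide per questionable
site to the first reconstructed homeolog (the pattern Ck1); the second
homeolog (Ck2) is the per-site complement: the globally most frequent
nucleotide unless Ck1 already uses it, in which case the second most
frequent.

The model: within an accession ``a`` the two gene copies are expressed at
a roughly constant ratio along the contig, so a fraction ``p1[a]`` of the
reads carries the Ck1 copy.  ``p1[a]`` is estimated as the mean of the
per-site proportions of the Ck1 nucleotide over well-covered questionable
sites.  Given ``p1[a]`` (and ``p2[a] = 1 - p1[a]``) the probability of the
observed counts at one site is the product of two binomial terms,

    P(Nb[a][s] | Ck1, Ck2) = C(n, k1) p1^k1 (1-p1)^(n-k1)
                           * C(n, k2) p2^k2 (1-p2)^(n-k2),

with ``n`` the accession's total count at the site and ``k1``/``k2`` the
counts of the Ck1/Ck2 nucleotides.  Sites and accessions are independent;
the split likelihood is the product over both.  Keeping both terms is what
protects against picking a sequencing-error nucleotide: the first term may
then be high, but the complementary term collapses.

Two searches are provided: an exhaustive scan over all combinations of
per-site candidate nucleotides (those seen >= 5 times in at least one
accession), and a heuristic that scores at most M+1 patterns (each
accession's majority sequence plus the global majority).  The global
majority pattern alone is the baseline "majority split".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .alr_io import AlrDataset, ContigCounts
from .nucleotides import MISSING, NUCLEOTIDES
from .site_screen import (
    QuestionableSet,
    SiteSummary,
    _mf_indices_2d,
    find_questionable_sites,
    is_questionable_contig,
    questionable_set_from_sites,
)

logger = logging.getLogger(__name__)

#: Proportions are clamped into [P_EPS, 1 - P_EPS] before the log-likelihood;
#: the plain estimator can hit exactly 0 or 1, where the binomial log is
#: undefined.  Clamping preserves the ordering of candidate splits.
P_EPS = 1e-6


class IntractableSearchError(RuntimeError):
    """Exhaustive search space exceeds the cap; use the heuristic search."""


@dataclass
class SplitResult:
    """A scored split: pattern, complement, proportions and likelihood.

    ``ck1``/``ck2`` are 1-based nucleotide indices over the questionable
    sites ``sites`` (0-based contig positions).  ``p1`` holds the raw
    per-accession proportion estimates (NaN when an accession has no
    questionable site with coverage >= 10).  ``seq1``/``seq2`` are the two
    full-length reconstructed homeolog sequences; they differ from the
    input consensus only at questionable sites.
    """

    contig_id: str
    sites: np.ndarray
    ck1: np.ndarray
    ck2: np.ndarray
    p1: np.ndarray
    log_likelihood: float
    seq1: str
    seq2: str
    method: str
    second_best_log_likelihood: float | None = None

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.ck1 = np.asarray(self.ck1, dtype=np.int64)
        self.ck2 = np.asarray(self.ck2, dtype=np.int64)
        self.p1 = np.asarray(self.p1, dtype=float)
        if (self.ck1 == self.ck2).any():
            raise ValueError("ck2 must differ from ck1 at every site")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood must be finite")

    @property
    def p2(self) -> np.ndarray:
        return 1.0 - self.p1


def _counts_at_sites(contig: ContigCounts, qset: QuestionableSet) -> np.ndarray:
    if qset.n_questionable == 0:
        raise ValueError(f"contig {contig.contig_id!r} has no questionable site")
    return contig.counts[:, qset.questionable_sites, :]


def _global_mf(counts_q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Global (mf1, mf2) per questionable site, 1-based, 0 missing."""
    return _mf_indices_2d(counts_q.sum(axis=0))


def _complement_from_global(
    ck1: np.ndarray, mf1g: np.ndarray, mf2g: np.ndarray
) -> np.ndarray:
    ck2 = np.where(ck1 != mf1g, mf1g, mf2g)
    if (ck2 == MISSING).any():
        bad = int(np.nonzero(ck2 == MISSING)[0][0])
        raise ValueError(
            f"cannot complement pattern at site {bad}: fewer than two nucleotides observed"
        )
    return ck2


def complement_pattern(ck1, site_summaries: list[SiteSummary]) -> np.ndarray:
    """Derive the complement Ck2 of a pattern from global site summaries.

    Per site: the global most frequent nucleotide, unless Ck1 already uses
    it, in which case the global second most frequent.
    """
    ck1 = np.asarray(ck1, dtype=np.int64)
    if len(ck1) != len(site_summaries):
        raise ValueError("pattern and summaries must have the same length")
    mf1g = np.array([s.mf1_global for s in site_summaries], dtype=np.int64)
    mf2g = np.array([s.mf2_global for s in site_summaries], dtype=np.int64)
    return _complement_from_global(ck1, mf1g, mf2g)


def estimate_p1(
    contig: ContigCounts,
    qset: QuestionableSet,
    ck1,
    min_site_coverage: int = 10,
) -> np.ndarray:
    """Per-accession proportion of the Ck1 nucleotides (NaN when undefined).

    The mean, over questionable sites where the accession's coverage is
    >= ``min_site_coverage``, of count(Ck1 nucleotide) / total count.
    """
    counts_q = _counts_at_sites(contig, qset)
    ck1 = np.asarray(ck1, dtype=np.int64)
    _, p1 = _score_patterns(counts_q, ck1[None, :], min_site_coverage)
    return p1[0]


def site_log_prob(
    count_vector, ck1_nuc: int, ck2_nuc: int, p1a: float, p2a: float
) -> float:
    """Natural log of the two-binomial site probability (always finite).

    ``n`` is the total count, ``k1``/``k2`` the counts of the Ck1/Ck2
    nucleotides; computed in log space via log-gamma.
    """
    vec = np.asarray(count_vector, dtype=np.int64)
    if (vec < 0).any():
        raise ValueError("counts must be non-negative")
    if ck1_nuc == ck2_nuc:
        raise ValueError("ck1_nuc and ck2_nuc must differ")
    if not (0.0 < p1a < 1.0 and 0.0 < p2a < 1.0):
        raise ValueError("p1a and p2a must lie strictly inside (0, 1)")
    n = int(vec.sum())
    k1 = int(vec[ck1_nuc - 1])
    k2 = int(vec[ck2_nuc - 1])
    out = 0.0
    for k, p in ((k1, p1a), (k2, p2a)):
        out += (
            gammaln(n + 1)
            - gammaln(k + 1)
            - gammaln(n - k + 1)
            + k * np.log(p)
            + (n - k) * np.log1p(-p)
        )
    return float(out)


def _score_patterns(
    counts_q: np.ndarray,
    patterns: np.ndarray,
    min_site_coverage: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood and raw p1 estimates for a batch of patterns.

    ``counts_q``: (M, Nq, 4) counts at the questionable sites.
    ``patterns``: (K, Nq) 1-based Ck1 nucleotide indices.
    Returns ``(loglik (K,), p1 (K, M))``; accessions without any
    questionable site at coverage >= ``min_site_coverage`` get NaN in p1
    and contribute nothing to the likelihood.
    """
    m, nq, _ = counts_q.shape
    patterns = np.asarray(patterns, dtype=np.int64)
    k_pat = patterns.shape[0]
    mf1g, mf2g = _global_mf(counts_q)
    ck2 = np.empty_like(patterns)
    for i in range(k_pat):
        ck2[i] = _complement_from_global(patterns[i], mf1g, mf2g)

    c = counts_q.transpose(1, 2, 0)  # (Nq, 4, M)
    rows = np.arange(nq)
    k1 = c[rows[None, :], patterns - 1]  # (K, Nq, M)
    k2 = c[rows[None, :], ck2 - 1]
    tot = counts_q.sum(axis=2).T[None, :, :]  # (1, Nq, M)

    qual = tot >= min_site_coverage
    n_qual = qual[0].sum(axis=0)  # (M,)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(qual, k1 / np.maximum(tot, 1), 0.0)
        p1_raw = prop.sum(axis=1) / n_qual  # (K, M)
    p1_raw = np.where(n_qual > 0, p1_raw, np.nan)

    p1c = np.clip(np.nan_to_num(p1_raw, nan=0.5), P_EPS, 1.0 - P_EPS)
    p2c = 1.0 - p1c
    lp1 = np.log(p1c)[:, None, :]
    lp2 = np.log(p2c)[:, None, :]
    ll = (
        gammaln(tot + 1)
        - gammaln(k1 + 1)
        - gammaln(tot - k1 + 1)
        + k1 * lp1
        + (tot - k1) * lp2
        + gammaln(tot + 1)
        - gammaln(k2 + 1)
        - gammaln(tot - k2 + 1)
        + k2 * lp2
        + (tot - k2) * lp1
    )
    ll = ll * (n_qual > 0)[None, None, :]
    return ll.sum(axis=(1, 2)), p1_raw


def _build_sequences(
    contig: ContigCounts, sites: np.ndarray, ck1: np.ndarray, ck2: np.ndarray
) -> tuple[str, str]:
    seq1 = list(contig.ref_seq)
    seq2 = list(contig.ref_seq)
    for s, n1, n2 in zip(sites, ck1, ck2):
        seq1[s] = NUCLEOTIDES[n1 - 1]
        seq2[s] = NUCLEOTIDES[n2 - 1]
    return "".join(seq1), "".join(seq2)


def split_log_likelihood(
    contig: ContigCounts,
    qset: QuestionableSet,
    ck1,
    min_site_coverage: int = 10,
    method: str = "custom",
) -> SplitResult:
    """Score one pattern: estimate p1, derive Ck2, sum the site log-probs.

    Accessions with no questionable site at coverage >= 10 are excluded
    from the likelihood (their p1 is NaN); the returned result carries the
    two full-length reconstructed sequences.
    """
    counts_q = _counts_at_sites(contig, qset)
    ck1 = np.asarray(ck1, dtype=np.int64)
    if len(ck1) != qset.n_questionable:
        raise ValueError("pattern length must equal the number of questionable sites")
    mf1g, mf2g = _global_mf(counts_q)
    ck2 = _complement_from_global(ck1, mf1g, mf2g)
    loglik, p1 = _score_patterns(counts_q, ck1[None, :], min_site_coverage)
    seq1, seq2 = _build_sequences(contig, qset.questionable_sites, ck1, ck2)
    return SplitResult(
        contig_id=contig.contig_id,
        sites=qset.questionable_sites,
        ck1=ck1,
        ck2=ck2,
        p1=p1[0],
        log_likelihood=float(loglik[0]),
        seq1=seq1,
        seq2=seq2,
        method=method,
    )


def heuristic_candidates(
    contig: ContigCounts, qset: QuestionableSet
) -> list[np.ndarray]:
    """At most M+1 candidate patterns: global majority plus one per accession.

    Each accession contributes its own majority nucleotide at every
    questionable site (falling back to the global majority where the
    accession has no coverage); duplicates are removed.
    """
    counts_q = _counts_at_sites(contig, qset)
    mf1g, _ = _global_mf(counts_q)
    patterns: list[np.ndarray] = []
    seen: set[tuple] = set()

    def _add(pat: np.ndarray):
        key = tuple(int(x) for x in pat)
        if key not in seen:
            seen.add(key)
            patterns.append(pat.astype(np.int64))

    _add(mf1g.copy())
    for a in range(contig.n_accessions):
        mf1a, _ = _mf_indices_2d(counts_q[a])
        _add(np.where(mf1a == MISSING, mf1g, mf1a))
    return patterns


def count_exhaustive_combinations(
    contig: ContigCounts, qset: QuestionableSet, min_allele_count: int = 5
) -> int:
    """Size of the exhaustive search space (product of per-site alphabets)."""
    alphabets = _site_alphabets(contig, qset, min_allele_count)
    total = 1
    for alpha in alphabets:
        total *= len(alpha)
    return total


def _site_alphabets(
    contig: ContigCounts, qset: QuestionableSet, min_allele_count: int
) -> list[list[int]]:
    counts_q = _counts_at_sites(contig, qset)
    mf1g, mf2g = _global_mf(counts_q)
    alphabets = []
    for j in range(qset.n_questionable):
        per_acc_max = counts_q[:, j, :].max(axis=0)
        alpha = [n + 1 for n in range(4) if per_acc_max[n] >= min_allele_count]
        if len(alpha) < 2:
            # Only reachable with externally supplied site lists; fall back
            # to the two globally most frequent nucleotides.
            alpha = sorted(set(alpha) | {int(mf1g[j]), int(mf2g[j])} - {MISSING})
        alphabets.append(alpha)
    return alphabets


def exhaustive_candidates(
    contig: ContigCounts,
    qset: QuestionableSet,
    min_allele_count: int = 5,
    max_combinations: int = 2**20,
) -> list[np.ndarray]:
    """All combinations of per-site candidate nucleotides.

    A nucleotide is a candidate at a site iff some accession shows it at
    least ``min_allele_count`` times there.  Raises
    :class:`IntractableSearchError` when the product of alphabet sizes
    exceeds ``max_combinations`` (use the heuristic search instead).
    """
    alphabets = _site_alphabets(contig, qset, min_allele_count)
    total = count_exhaustive_combinations(contig, qset, min_allele_count)
    if total > max_combinations:
        raise IntractableSearchError(
            f"{total} combinations exceed the cap of {max_combinations}; "
            "the heuristic search handles large numbers of questionable sites"
        )
    return [np.array(combo, dtype=np.int64) for combo in itertools.product(*alphabets)]


def _select_best(
    contig: ContigCounts,
    qset: QuestionableSet,
    patterns: list[np.ndarray],
    method: str,
    min_site_coverage: int,
) -> SplitResult:
    counts_q = _counts_at_sites(contig, qset)
    mf1g, mf2g = _global_mf(counts_q)
    majority = tuple(int(x) for x in mf1g)
    batch = np.stack(patterns)
    loglik, p1 = _score_patterns(counts_q, batch, min_site_coverage)

    # Ties: prefer the global-majority pattern, then the lexicographically
    # smallest pattern, for deterministic output.  Mathematically exact
    # ties (a pattern and its orientation swap when only two nucleotides
    # are observed) accumulate ~1e-14 float residue in the vectorised sum,
    # so equality is taken within a tolerance far below any model signal.
    tol = 1e-9 + 1e-12 * float(np.abs(loglik).max())
    keys = [
        (tuple(int(x) for x in pat) != majority, tuple(int(x) for x in pat))
        for pat in patterns
    ]
    order = sorted(range(len(patterns)), key=lambda i: keys[i])
    best = order[0]
    for i in order[1:]:
        if loglik[i] > loglik[best] + tol:
            best = i
    second = None
    for i in range(len(patterns)):
        if i == best:
            continue
        if second is None or loglik[i] > second:
            second = float(loglik[i])

    ck1 = batch[best]
    ck2 = _complement_from_global(ck1, mf1g, mf2g)
    seq1, seq2 = _build_sequences(contig, qset.questionable_sites, ck1, ck2)
    return SplitResult(
        contig_id=contig.contig_id,
        sites=qset.questionable_sites,
        ck1=ck1,
        ck2=ck2,
        p1=p1[best],
        log_likelihood=float(loglik[best]),
        seq1=seq1,
        seq2=seq2,
        method=method,
        second_best_log_likelihood=second,
    )


def best_split(
    contig: ContigCounts,
    qset: QuestionableSet,
    mode: str = "auto",
    min_allele_count: int = 5,
    min_site_coverage: int = 10,
    max_combinations: int = 2**20,
    min_mean_coverage: float = 5.0,
) -> SplitResult:
    """Maximum-likelihood split of a questionable contig.

    ``mode`` is ``"exhaustive"``, ``"heuristic"`` or ``"auto"`` (exhaustive
    when tractable under ``max_combinations``, else heuristic).  Ties are
    broken toward the global-majority pattern, then lexicographically.
    """
    if not is_questionable_contig(qset, min_mean_coverage):
        raise ValueError(
            f"contig {contig.contig_id!r} is not questionable; nothing to split"
        )
    if mode not in ("auto", "heuristic", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    resolved = mode
    if mode == "auto":
        n_comb = count_exhaustive_combinations(contig, qset, min_allele_count)
        resolved = "exhaustive" if n_comb <= max_combinations else "heuristic"
    if resolved == "exhaustive":
        patterns = exhaustive_candidates(contig, qset, min_allele_count, max_combinations)
    else:
        patterns = heuristic_candidates(contig, qset)
    return _select_best(contig, qset, patterns, resolved, min_site_coverage)


def majority_split(
    contig: ContigCounts,
    qset: QuestionableSet,
    min_site_coverage: int = 10,
    min_mean_coverage: float = 5.0,
) -> SplitResult:
    """Baseline split: global Mf1 as Ck1, global Mf2 as Ck2.

    By construction Ck1 equals the consensus of the input contig at the
    questionable sites; the result is scored with the same likelihood as
    :func:`best_split` for comparability.
    """
    if not is_questionable_contig(qset, min_mean_coverage):
        raise ValueError(
            f"contig {contig.contig_id!r} is not questionable; nothing to split"
        )
    counts_q = _counts_at_sites(contig, qset)
    mf1g, _ = _global_mf(counts_q)
    return split_log_likelihood(
        contig, qset, mf1g, min_site_coverage, method="majority"
    )


def split_all_contigs(
    dataset: AlrDataset,
    mode: str = "auto",
    min_allele_count: int = 5,
    het_fraction: float = 1 / 8,
    min_genotyped_coverage: int = 10,
    min_mean_coverage: float = 5.0,
    min_site_coverage: int = 10,
    max_combinations: int = 2**20,
    denominator: str = "genotyped",
    sites_override: dict[str, list[int]] | None = None,
    near_tie_delta: float = 0.1,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Screen and split every contig of a dataset.

    Questionable contigs are replaced by two records ``<id>_1``/``<id>_2``;
    the rest pass through unchanged under ``<id>``.  Per-contig failures
    are logged and the contig passed through.  The report lists, per
    contig, the number of questionable sites, the method used, the
    log-likelihood, a p1 summary and a near-tie flag (runner-up within
    ``near_tie_delta`` log units — balanced expression weakens the model).
    """
    records: list[tuple[str, str]] = []
    rows = []
    for contig in dataset:
        row = {
            "contig_id": contig.contig_id,
            "length": contig.length,
            "mean_coverage": contig.mean_coverage(),
            "n_questionable": 0,
            "questionable": False,
            "method": "none",
            "log_likelihood": np.nan,
            "p1_mean": np.nan,
            "p1_min": np.nan,
            "p1_max": np.nan,
            "near_tie": False,
        }
        try:
            if sites_override and contig.contig_id in sites_override:
                qset = questionable_set_from_sites(
                    contig, sites_override[contig.contig_id]
                )
            else:
                qset = find_questionable_sites(
                    contig,
                    min_allele_count=min_allele_count,
                    het_fraction=het_fraction,
                    min_genotyped_coverage=min_genotyped_coverage,
                    denominator=denominator,
                )
            row["n_questionable"] = qset.n_questionable
            if mode == "majority" and is_questionable_contig(qset, min_mean_coverage):
                result = majority_split(
                    contig, qset, min_site_coverage, min_mean_coverage
                )
            elif is_questionable_contig(qset, min_mean_coverage):
                result = best_split(
                    contig,
                    qset,
                    mode=mode,
                    min_allele_count=min_allele_count,
                    min_site_coverage=min_site_coverage,
                    max_combinations=max_combinations,
                    min_mean_coverage=min_mean_coverage,
                )
            else:
                records.append((contig.contig_id, contig.ref_seq))
                rows.append(row)
                continue
        except Exception:
            logger.exception("failed to split contig %s; passing through", contig.contig_id)
            records.append((contig.contig_id, contig.ref_seq))
            rows.append(row)
            continue

        records.append((f"{contig.contig_id}_1", result.seq1))
        records.append((f"{contig.contig_id}_2", result.seq2))
        defined = result.p1[~np.isnan(result.p1)]
        row.update(
            questionable=True,
            method=result.method,
            log_likelihood=result.log_likelihood,
            p1_mean=float(defined.mean()) if len(defined) else np.nan,
            p1_min=float(defined.min()) if len(defined) else np.nan,
            p1_max=float(defined.max()) if len(defined) else np.nan,
            near_tie=(
                result.second_best_log_likelihood is not None
                and result.log_likelihood - result.second_best_log_likelihood
                < near_tie_delta
            ),
        )
        rows.append(row)
    return records, pd.DataFrame(rows)
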