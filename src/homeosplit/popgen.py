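"""Genotype calling, Fis and SNP classification from nucleotide counts.

Fis, the fixation index, is the heterozygosity deficit relative to
panmixia: ``Fis = 1 - Hobs / (2 p (1 - p))`` with ``p`` one of the two
allele frequencies and ``Hobs`` the observed heterozygote fraction among
called accessions (bi-allelic SNPs only).  In a highly selfing panel the
Fis of genuine within-genome SNPs sits near +1, whereas fixed divergence
between two merged homeologous copies masquerades as a SNP with every
accession heterozygous, i.e. Fis = -1; mixtures of both signals land in
between.  The distribution of Fis before and after splitting is therefore
the end-to-end readout of whether homeolog confusion was removed.

The genotype caller here is a deliberately simple count-threshold rule
(coverage > 10 reads; alleles need >= 5 copies and >= 10% of the reads).
It stands in for full probabilistic genotypers; the Fis machinery
downstream is independent of how genotypes were obtained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .alr_io import AlrDataset, ContigCounts
from .nucleotides import NUCLEOTIDES


@dataclass
class GenotypeCall:
    """One accession's genotype at one site (0-based).

    ``alleles`` is an unordered pair of 1-based nucleotide indices (equal
    pair = homozygote), or ``None`` when ``status`` is ``"missing"``.
    """

    accession: str
    site: int
    alleles: tuple[int, int] | None
    status: str  # "called" | "missing"


@dataclass
class SnpRecord:
    """A bi-allelic polymorphic site with its Fis and classification."""

    contig_id: str
    site: int
    alleles: tuple[int, int]
    p: float
    hobs: float
    fis: float  # NaN when undefined
    n_called: int
    classification: str  # homologous | intermediate | homeologous | undefined


def call_genotypes(
    contig: ContigCounts,
    min_call_coverage: int = 10,
    min_allele_count: int = 5,
    min_allele_fraction: float = 0.1,
) -> list[GenotypeCall]:
    """Count-threshold genotypes for every accession x site.

    Missing when coverage <= ``min_call_coverage`` (strictly more than ten
    reads are required by default).  Otherwise the alleles are the
    nucleotides with count >= ``min_allele_count`` and fraction >=
    ``min_allele_fraction``: one passing nucleotide is a homozygote, two a
    heterozygote, zero or three and more are missing.
    """
    cov = contig.counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = contig.counts / np.maximum(cov, 1)[:, :, None]
    passing = (contig.counts >= min_allele_count) & (frac >= min_allele_fraction)
    n_pass = passing.sum(axis=2)
    calls = []
    for a, accession in enumerate(contig.accession_ids):
        for s in range(contig.length):
            if cov[a, s] > min_call_coverage and n_pass[a, s] in (1, 2):
                nucs = np.nonzero(passing[a, s])[0] + 1
                alleles = (int(nucs[0]), int(nucs[-1]))
                calls.append(GenotypeCall(accession, s, alleles, "called"))
            else:
                calls.append(GenotypeCall(accession, s, None, "missing"))
    return calls


def classify_fis(
    fis: float,
    homologous_threshold: float = 0.6,
    homeologous_threshold: float = -0.5,
) -> str:
    """Classify a Fis value into the three expected modes.

    ``homologous`` for Fis strictly above ``homologous_threshold`` (0.6,
    empirical bound for valuable within-genome SNPs in a selfing panel),
    ``homeologous`` for Fis <= ``homeologous_threshold`` (-0.5, a binning
    choice for the fixed-divergence mode near -1), ``intermediate``
    otherwise, ``undefined`` for NaN.
    """
    if np.isnan(fis):
        return "undefined"
    if fis > homologous_threshold:
        return "homologous"
    if fis <= homeologous_threshold:
        return "homeologous"
    return "intermediate"


def classify_snp(
    record: SnpRecord,
    homologous_threshold: float = 0.6,
    homeologous_threshold: float = -0.5,
) -> str:
    """Classification of a :class:`SnpRecord` by its Fis (see classify_fis)."""
    return classify_fis(record.fis, homologous_threshold, homeologous_threshold)


def fis_per_site(
    calls: list[GenotypeCall], contig_id: str = "", site: int | None = None
) -> SnpRecord | None:
    """Fis from the genotype calls at one site.

    Requires at least one called genotype (else an error); sites with more
    than two distinct alleles are rejected (returns None), as are
    monomorphic sites.  ``p`` is the frequency of the lower-index allele;
    Fis is NaN (classification undefined) if ``p`` degenerates to 0 or 1.
    """
    called = [c for c in calls if c.status == "called"]
    if not called:
        raise ValueError("no called genotype at this site")
    alleles = sorted({n for c in called for n in c.alleles})
    if len(alleles) != 2:
        return None
    a1, a2 = alleles
    n_called = len(called)
    n_het = sum(1 for c in called if c.alleles[0] != c.alleles[1])
    copies1 = sum(c.alleles.count(a1) for c in called)
    p = copies1 / (2 * n_called)
    hobs = n_het / n_called
    if p in (0.0, 1.0):
        fis = float("nan")
    else:
        fis = 1.0 - hobs / (2.0 * p * (1.0 - p))
    if site is None:
        site = called[0].site
    return SnpRecord(
        contig_id=contig_id,
        site=site,
        alleles=(a1, a2),
        p=p,
        hobs=hobs,
        fis=fis,
        n_called=n_called,
        classification=classify_fis(fis),
    )


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) of a 2x2 table, df=1."""
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    result = chi2_contingency(table, correction=False)
    return float(result.statistic), 1


def snp_table(
    contig: ContigCounts,
    min_call_coverage: int = 10,
    min_allele_count: int = 5,
    min_allele_fraction: float = 0.1,
    homologous_threshold: float = 0.6,
    homeologous_threshold: float = -0.5,
) -> list[SnpRecord]:
    """All bi-allelic SNPs of a contig with their Fis.

    Vectorised equivalent of calling :func:`call_genotypes` and
    :func:`fis_per_site` site by site (the scalar route is kept as the
    reference in the test suite).
    """
    cov = contig.counts.sum(axis=2)  # (M, N)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = contig.counts / np.maximum(cov, 1)[:, :, None]
    passing = (contig.counts >= min_allele_count) & (frac >= min_allele_fraction)
    n_pass = passing.sum(axis=2)
    called = (cov > min_call_coverage) & ((n_pass == 1) | (n_pass == 2))
    pass_called = passing & called[:, :, None]
    present = pass_called.any(axis=0)  # (N, 4)
    n_alleles = present.sum(axis=1)
    candidates = np.nonzero((n_alleles == 2) & called.any(axis=0))[0]

    records = []
    for s in candidates:
        nucs = np.nonzero(present[s])[0]
        a1, a2 = int(nucs[0]), int(nucs[1])
        mask = called[:, s]
        n_called = int(mask.sum())
        het = mask & (n_pass[:, s] == 2)
        hom1 = mask & (n_pass[:, s] == 1) & passing[:, s, a1]
        copies1 = int(2 * hom1.sum() + (het & passing[:, s, a1]).sum())
        p = copies1 / (2 * n_called)
        hobs = float(het.sum()) / n_called
        if p in (0.0, 1.0):
            fis = float("nan")
        else:
            fis = 1.0 - hobs / (2.0 * p * (1.0 - p))
        records.append(
            SnpRecord(
                contig_id=contig.contig_id,
                site=int(s),
                alleles=(a1 + 1, a2 + 1),
                p=p,
                hobs=hobs,
                fis=fis,
                n_called=n_called,
                classification=classify_fis(
                    fis, homologous_threshold, homeologous_threshold
                ),
            )
        )
    return records


def fis_spectrum(
    dataset: AlrDataset,
    min_call_coverage: int = 10,
    min_allele_count: int = 5,
    min_allele_fraction: float = 0.1,
    homologous_threshold: float = 0.6,
    homeologous_threshold: float = -0.5,
    bin_width: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP Fis table and its histogram over [-1, 1] for a dataset.

    Returns ``(snps, histogram)``: one row per bi-allelic SNP (contig,
    1-based position, alleles, n_called, p, hobs, fis, classification) and
    the binned counts of defined Fis values (clipped into [-1, 1]; the
    formula can stray below -1 for unbalanced heterozygote excess).
    """
    rows = []
    for contig in dataset:
        for rec in snp_table(
            contig,
            min_call_coverage,
            min_allele_count,
            min_allele_fraction,
            homologous_threshold,
            homeologous_threshold,
        ):
            rows.append(
                {
                    "contig_id": rec.contig_id,
                    "position": rec.site + 1,
                    "alleles": NUCLEOTIDES[rec.alleles[0] - 1]
                    + "/"
                    + NUCLEOTIDES[rec.alleles[1] - 1],
                    "n_called": rec.n_called,
                    "p": rec.p,
                    "hobs": rec.hobs,
                    "fis": rec.fis,
                    "classification": rec.classification,
                }
            )
    snps = pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "position",
            "alleles",
            "n_called",
            "p",
            "hobs",
            "fis",
            "classification",
        ],
    )
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    defined = snps["fis"].dropna().to_numpy() if len(snps) else np.array([])
    hist, _ = np.histogram(np.clip(defined, -1.0, 1.0), bins=edges)
    histogram = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
    )
    return snps, histogram
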