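"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's vectorised, log-space code paths:
plain Python loops, math.comb and direct probability products.
"""

import math

import numpy as np

P_EPS = 1e-6


def brute_force_split_probability(contig, qset, ck1):
    """Direct probability product of a split (no log-space tricks).

    Returns the product over questionable sites and accessions of the
    two-binomial site probability, with p1 re-derived independently as the
    plain mean of per-site proportions over sites with coverage >= 10.
    """
    sites = [int(s) for s in qset.questionable_sites]
    ck1 = [int(x) for x in ck1]

    # Complement via an independent sort-based most-frequent rule.
    ck2 = []
    for j, s in enumerate(sites):
        totals = [int(contig.counts[:, s, n].sum()) for n in range(4)]
        order = sorted(range(4), key=lambda n: (-totals[n], n))
        mf1, mf2 = order[0] + 1, order[1] + 1
        ck2.append(mf1 if mf1 != ck1[j] else mf2)

    product = 1.0
    for a in range(contig.n_accessions):
        props = []
        for j, s in enumerate(sites):
            total = int(contig.counts[a, s].sum())
            if total >= 10:
                props.append(contig.counts[a, s, ck1[j] - 1] / total)
        if not props:
            continue  # accession excluded from the likelihood
        p1 = min(max(sum(props) / len(props), P_EPS), 1.0 - P_EPS)
        p2 = 1.0 - p1
        for j, s in enumerate(sites):
            n = int(contig.counts[a, s].sum())
            k1 = int(contig.counts[a, s, ck1[j] - 1])
            k2 = int(contig.counts[a, s, ck2[j] - 1])
            product *= (
                math.comb(n, k1) * p1**k1 * p2 ** (n - k1)
                * math.comb(n, k2) * p2**k2 * p1 ** (n - k2)
            )
    return product


def random_small_instance(rng, max_count=30, max_sites=3, max_accessions=3):
    """A random tiny contig plus a random pattern over all its sites.

    Every site is guaranteed at least two observed nucleotides so the
    complement rule is defined; the pattern picks observed nucleotides.
    """
    from homeosplit import ContigCounts, questionable_set_from_sites

    m = int(rng.integers(1, max_accessions + 1))
    nq = int(rng.integers(1, max_sites + 1))
    counts = np.zeros((m, nq, 4), dtype=np.int64)
    for s in range(nq):
        while True:
            counts[:, s, :] = rng.integers(0, max_count + 1, size=(m, 4))
            if (counts[:, s, :].sum(axis=0) > 0).sum() >= 2:
                break
    contig = ContigCounts(
        "inst", [f"a{i}" for i in range(m)], "A" * nq, counts
    )
    qset = questionable_set_from_sites(contig, list(range(nq)))
    pattern = np.array(
        [
            int(rng.choice(np.nonzero(counts[:, s, :].sum(axis=0) > 0)[0]) + 1)
            for s in range(nq)
        ],
        dtype=np.int64,
    )
    return contig, qset, pattern
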