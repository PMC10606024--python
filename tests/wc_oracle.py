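"""Independent scalar-loop transcription of the Weir-Cockerham (1984)
variance components, kept deliberately naive (per-locus Python loops,
textbook symbols) so it can serve as an oracle for the vectorised
implementation."""

import math

import numpy as np

MISSING = -1


def wc_theta_oracle(calls, pop_of_sample):
    """Multi-locus theta = sum(a) / sum(a+b+c) over informative loci.

    ``calls``: individuals x loci genotype codes (alt dosage, -1 missing).
    ``pop_of_sample``: per-individual population index.
    Returns (theta, per-locus list of (a, b, c) or None).
    """
    calls = np.asarray(calls)
    pops = sorted(set(pop_of_sample))
    r = len(pops)
    per_locus = []
    sum_a = sum_abc = 0.0
    for j in range(calls.shape[1]):
        n = []
        p = []
        h = []
        for pop in pops:
            rows = [i for i, q in enumerate(pop_of_sample) if q == pop]
            gt = [calls[i, j] for i in rows if calls[i, j] != MISSING]
            if len(gt) == 0:
                n = None
                break
            n_i = len(gt)
            p_i = sum(gt) / (2.0 * n_i)
            h_i = sum(1 for x in gt if x == 1) / n_i
            n.append(n_i)
            p.append(p_i)
            h.append(h_i)
        if n is None:
            per_locus.append(None)
            continue
        nbar = sum(n) / r
        if nbar <= 1:
            per_locus.append(None)
            continue
        nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1.0)
        if nc <= 0:
            per_locus.append(None)
            continue
        pbar = sum(n_i * p_i for n_i, p_i in zip(n, p)) / (r * nbar)
        if pbar <= 0.0 or pbar >= 1.0:
            per_locus.append(None)
            continue
        s2 = sum(n_i * (p_i - pbar) ** 2 for n_i, p_i in zip(n, p)) / ((r - 1.0) * nbar)
        hbar = sum(n_i * h_i for n_i, h_i in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        per_locus.append((a, b, c))
        sum_a += a
        sum_abc += a + b + c
    theta = sum_a / sum_abc if sum_abc != 0 else math.nan
    return theta, per_locus
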