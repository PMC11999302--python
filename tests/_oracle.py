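"""Independent naive oracle for the weighted-sum index.

Pure-Python double loops over domains and indicators, with hand-rolled mean /
sample-sd z-scoring — deliberately sharing no code with svikit's vectorized
implementation so the two can cross-check each other.
"""

import math


def naive_mean(xs):
    return sum(xs) / len(xs)


def naive_sd(xs):
    mu = naive_mean(xs)
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / (len(xs) - 1))


def naive_zscores(raw_columns, directions):
    """raw_columns: {indicator: [values]}; directions: {indicator: +1|-1}."""
    out = {}
    for ind, xs in raw_columns.items():
        mu, sd = naive_mean(xs), naive_sd(xs)
        out[ind] = [directions[ind] * (x - mu) / sd for x in xs]
    return out


def naive_svi(raw_columns, directions, domain_of, depleted, n_areas):
    """Evaluate the tiered weighted double sum per area.

    Weights: 1/m per indicator of a domain with m available indicators,
    halved to 1/(2m) when the domain is depleted.  Returns (per-area svi,
    per-area per-domain scores).
    """
    z = naive_zscores(raw_columns, directions)
    domains = {}
    for ind in raw_columns:
        domains.setdefault(domain_of[ind], []).append(ind)
    svi = [0.0] * n_areas
    domain_scores = {d: [0.0] * n_areas for d in domains}
    for dom, inds in domains.items():
        m = len(inds)
        w = 1.0 / (2 * m) if dom in depleted else 1.0 / m
        for a in range(n_areas):
            s = 0.0
            for ind in inds:
                s += w * z[ind][a]
            domain_scores[dom][a] = s
            svi[a] += s
    return svi, domain_scores
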