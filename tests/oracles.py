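"""Independent straight-line re-derivations used as oracles in tests.

Deliberately written with plain Python arithmetic (no calls into the package
and no numpy percentile/SD helpers) so they cannot share a bug with the
implementation under test.
"""

from __future__ import annotations

import math


def percentile_interpolated(values, p):
    """Percentile by linear interpolation on order statistics, h=(n-1)p+1."""
    xs = sorted(values)
    h = (len(xs) - 1) * p
    lo = int(math.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def sample_sd(values):
    m = sum(values) / len(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def ibrt_oracle(df):
    """Brute-force IBR-T from a long biomarker table.

    Returns {(tissue, day, treatment): score} re-deriving every step:
    control median/95th percentile, per-treatment means, log-ratios,
    SD across treatments, threshold inclusion, mean |z|.
    """
    rows = list(df.itertuples(index=False))
    strata = sorted({(r.tissue, r.day) for r in rows})
    scores = {}
    for tissue, day in strata:
        in_stratum = [r for r in rows if r.tissue == tissue and r.day == day]
        biomarkers = sorted({r.biomarker for r in in_stratum})
        treatments = sorted({r.treatment for r in in_stratum})
        z_by_treatment = {t: [] for t in treatments}
        for b in biomarkers:
            ctrl = [r.value for r in in_stratum if r.biomarker == b and r.treatment == "CTRL"]
            reference = percentile_interpolated(ctrl, 0.5)
            threshold = percentile_interpolated(ctrl, 0.95)
            means = {}
            for t in treatments:
                vals = [r.value for r in in_stratum if r.biomarker == b and r.treatment == t]
                means[t] = sum(vals) / len(vals)
            log_ratios = {t: math.log(means[t] / reference) for t in treatments}
            sd = sample_sd(list(log_ratios.values()))
            for t in treatments:
                z = log_ratios[t] / sd if sd > 0 else 0.0
                if means[t] > threshold:
                    z_by_treatment[t].append(abs(z))
        for t in treatments:
            zs = z_by_treatment[t]
            scores[(tissue, day, t)] = sum(zs) / len(zs) if zs else 0.0
    return scores


def kruskal_wallis_oracle(groups):
    """H by direct rank arithmetic with midranks and tie correction."""
    pooled = [v for g in groups for v in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    n = len(pooled)
    offsets, rank_groups = 0, []
    for g in groups:
        rank_groups.append(ranks[offsets : offsets + len(g)])
        offsets += len(g)
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (sum(r) / len(r) - (n + 1) / 2.0) ** 2 for r in rank_groups
    )
    tie_counts = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in tie_counts.values())
    denom = 1.0 - tie / (n**3 - n)
    return h / denom if denom > 0 else 0.0
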