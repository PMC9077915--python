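"""Independent brute-force oracles, written from first principles.

Everything here uses explicit Python loops and textbook formulas only —
no calls into refstab's vectorized implementations — so that agreement
between an oracle and the package is a meaningful cross-check.
"""

import math


def sample_sd(xs):
    """Sample standard deviation with the n-1 denominator, by hand."""
    n = len(xs)
    mean = sum(xs) / n
    return math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))


def genorm_m_oracle(q):
    """Per-gene geNorm M by explicit double loop over gene pairs.

    ``q`` is a dict gene -> list of quantities (same sample order).
    """
    genes = list(q)
    m = {}
    for j in genes:
        v_sum = 0.0
        for k in genes:
            if k == j:
                continue
            ratios = [math.log2(a / b) for a, b in zip(q[j], q[k])]
            v_sum += sample_sd(ratios)
        m[j] = v_sum / (len(genes) - 1)
    return m


def v_series_oracle(q, order):
    """V(n/n+1) recomputed from scratch given the most-stable-first order."""
    n_samples = len(q[order[0]])
    out = {}
    for n in range(2, len(order)):
        ratios = []
        for s in range(n_samples):
            nf_n = 1.0
            for g in order[:n]:
                nf_n *= q[g][s]
            nf_n = nf_n ** (1.0 / n)
            nf_n1 = 1.0
            for g in order[: n + 1]:
                nf_n1 *= q[g][s]
            nf_n1 = nf_n1 ** (1.0 / (n + 1))
            ratios.append(math.log2(nf_n / nf_n1))
        out[f"V{n}/{n + 1}"] = sample_sd(ratios)
    return out


def normfinder_ungrouped_oracle(y):
    """Two-way ANOVA residual variances with the k/(k-2) bias inversion.

    ``y`` is a dict gene -> list of Ct values (same sample order).
    Returns gene -> stability (SD units).  Written with explicit loops:
    residual = y - gene mean - sample mean + grand mean; mean square with
    n-1; sigma^2_g = k/(k-2) * (s2_g - mean(s2)/(k-1)), clipped at 0.
    """
    genes = list(y)
    k = len(genes)
    n = len(y[genes[0]])
    gene_mean = {g: sum(y[g]) / n for g in genes}
    sample_mean = [sum(y[g][i] for g in genes) / k for i in range(n)]
    grand = sum(gene_mean.values()) / k
    s2 = {}
    for g in genes:
        ss = 0.0
        for i in range(n):
            r = y[g][i] - gene_mean[g] - sample_mean[i] + grand
            ss += r * r
        s2[g] = ss / (n - 1)
    s2_mean = sum(s2.values()) / k
    out = {}
    for g in genes:
        sigma2 = k / (k - 2) * (s2[g] - s2_mean / (k - 1))
        out[g] = math.sqrt(max(sigma2, 0.0))
    return out


def normfinder_pair_score_oracle(y, a, b):
    """Ungrouped combined stability of a gene pair: sqrt((s2a + s2b)/4)."""
    stab = normfinder_ungrouped_oracle(y)
    return math.sqrt((stab[a] ** 2 + stab[b] ** 2) / 4.0)


def bestkeeper_oracle(ct, sd_cutoff=1.0, efficiency=2.0):
    """BestKeeper statistics, index and Pearson r from first principles.

    ``ct`` is a dict gene -> list of Ct values, no missing entries.
    Returns (stats dict, index list, r dict).
    """
    genes = list(ct)
    stats = {}
    for g in genes:
        xs = ct[g]
        n = len(xs)
        am = sum(xs) / n
        geo = math.exp(sum(math.log(x) for x in xs) / n)
        sd = sample_sd(xs)
        stats[g] = {
            "geo_mean_ct": geo,
            "arith_mean_ct": am,
            "min_ct": min(xs),
            "max_ct": max(xs),
            "sd_ct": sd,
            "cv_pct": 100.0 * sd / am,
            "fold_variation": efficiency**sd,
            "consistent": sd <= sd_cutoff,
        }
    consistent = [g for g in genes if stats[g]["consistent"]]
    n_samples = len(ct[genes[0]])
    index = []
    for s in range(n_samples):
        prod = 1.0
        for g in consistent:
            prod *= ct[g][s]
        index.append(prod ** (1.0 / len(consistent)))
    r = {}
    for g in genes:
        xs, ys = ct[g], index
        mx = sum(xs) / n_samples
        my = sum(ys) / n_samples
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        sxx = sum((x - mx) ** 2 for x in xs)
        syy = sum((y - my) ** 2 for y in ys)
        r[g] = sxy / math.sqrt(sxx * syy)
    return stats, index, r


def screen_score_oracle(tpm):
    """SD of the mean-standardized TPM row, literally as defined."""
    out = {}
    for g, row in tpm.items():
        mean = sum(row) / len(row)
        standardized = [x / mean for x in row]
        out[g] = sample_sd(standardized)
    return out


def ols_oracle(xs, ys):
    """Closed-form simple OLS slope/intercept."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    slope = sxy / sxx
    return slope, my - slope * mx
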