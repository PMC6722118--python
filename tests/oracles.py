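"""Independent reference computations used to check the implementation.

Everything here is deliberately written the slow, obvious way (explicit
loops, textbook formulas) and shares no code with the package internals.
"""

import numpy as np


def brute_force_otsu(values, n_bins=256):
    """Exhaustive 2-class Otsu over all histogram cuts.

    Mirrors the package's histogramming contract (256 bins over the value
    range, threshold = upper edge of the last lower-class bin, lowest
    maximizing cut wins) but maximizes between-class variance by explicit
    enumeration.
    """
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    counts = counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_k = -np.inf, None
    for k in range(n_bins - 1):
        if counts[k] == 0:
            continue  # same partition as the previous cut
        w0 = counts[: k + 1].sum()
        w1 = counts[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        sb2 = w0 * w1 * (mu0 - mu1) ** 2
        if sb2 > best:
            best, best_k = sb2, k
    return float(edges[best_k + 1])


def paired_t(differences):
    """Textbook paired t: mean / (sd / sqrt(n)), two-sided p, df = n - 1."""
    from scipy import stats

    d = np.asarray(differences, dtype=float)
    n = len(d)
    sd = d.std(ddof=1)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return t, p


def pearson_r(x, y):
    """Definition-level Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def expected_replicate_variation(spec, n_pairs=200_000, seed=0):
    """Population mean absolute difference in percent between two replicate
    cores of one subject, by direct simulation of the generative model.

    Replicates share the subject intercept; the second core stays on the
    same TMA with probability 1/2.  Pairwise differences of triples have the
    same distribution as those of pairs, so pairs suffice.
    """
    rng = np.random.default_rng(seed)
    male = rng.random(n_pairs) < spec.sex_ratio_male
    age = np.clip(rng.normal(*spec.age_mean_sd, n_pairs), 18.0, 95.0)
    mu = (
        spec.intercept_sqrt_scale
        + spec.sex_effect_sqrt_scale * male
        + spec.age_effect_sqrt_scale * age
        + rng.normal(0.0, spec.subject_sd, n_pairs)
    )
    v1 = rng.normal(0.0, spec.tma_sd, n_pairs)
    same = rng.random(n_pairs) < 0.5
    v2 = np.where(same, v1, rng.normal(0.0, spec.tma_sd, n_pairs))
    s1 = np.clip(mu + v1 + rng.normal(0.0, spec.residual_sd, n_pairs), 0, 1)
    s2 = np.clip(mu + v2 + rng.normal(0.0, spec.residual_sd, n_pairs), 0, 1)
    return float(np.mean(np.abs(100 * s1**2 - 100 * s2**2)))
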