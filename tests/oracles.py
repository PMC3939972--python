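"""Independent brute-force oracles, written as direct transcriptions.

These deliberately use explicit Python loops and the plainest possible
arithmetic so they share no code path with the optimised implementations
they check.
"""

import math

import numpy as np


def apen_bruteforce(x, m, r, exclude_self):
    """Approximate entropy by explicit enumeration of all template pairs."""
    x = [float(v) for v in x]
    n = len(x)

    def phi(q):
        n_templates = n - q + 1
        logs = []
        for i in range(n_templates):
            count = 0
            for j in range(n_templates):
                if exclude_self and j == i:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(q))
                if d <= r:
                    count += 1
            if count == 0:
                raise ArithmeticError(f"zero matches for template {i} at q={q}")
            logs.append(math.log(count / n_templates))
        return sum(logs) / n_templates

    return phi(m) - phi(m + 1)


def higuchi_naive(x, k_max):
    """Higuchi curve lengths and dimension via three plain loops."""
    x = [float(v) for v in x]
    n = len(x)
    lengths = []
    for k in range(1, k_max + 1):
        lm_values = []
        for m in range(1, k + 1):
            n_steps = (n - m) // k
            total = 0.0
            for i in range(1, n_steps + 1):
                total += abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
            lm = total * (n - 1) / (n_steps * k) / k
            lm_values.append(lm)
        lengths.append(sum(lm_values) / len(lm_values))
    xs = [math.log(1.0 / k) for k in range(1, k_max + 1)]
    ys = [math.log(v) for v in lengths]
    xbar = sum(xs) / len(xs)
    ybar = sum(ys) / len(ys)
    slope = sum((a - xbar) * (b - ybar) for a, b in zip(xs, ys)) / sum(
        (a - xbar) ** 2 for a in xs
    )
    return lengths, slope


def paired_t_textbook(a, b):
    """Paired t statistic and two-sided p from the textbook formulas."""
    from scipy.stats import t as t_dist

    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    sd = math.sqrt(sum((v - d.mean()) ** 2 for v in d) / (n - 1))
    t_stat = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t_stat), n - 1)
    return t_stat, p


def rbf_kernel_sum(model, X):
    """Decision values straight from the support expansion definition."""
    Z = model.standardise(np.atleast_2d(np.asarray(X, dtype=float)))
    out = []
    for z in Z:
        total = 0.0
        for coef, sv in zip(model.dual_signed, model.support_vectors):
            sq = float(((z - sv) ** 2).sum())
            total += coef * math.exp(-sq / (2.0 * model.sigma**2))
        out.append(total - model.bias)
    return np.array(out)
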