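"""Independent brute-force oracles used by the acceptance tests.

Everything here is deliberately written as direct summation / exhaustive
enumeration, independent of the package's vectorized implementations.
"""

import numpy as np
from scipy.special import comb


def information_oracle(p, lam):
    """I = sum_i p_i (lam_i/lbar) log2(lam_i/lbar) by direct summation."""
    p = np.asarray(p, float)
    lam = np.asarray(lam, float)
    p = p / p.sum()
    lbar = float((p * lam).sum())
    total = 0.0
    for pi, li in zip(p, lam):
        if li > 0:
            total += pi * (li / lbar) * np.log2(li / lbar)
    return total


def decoder_oracle(log_prior, rates, counts, tau):
    """Exhaustive argmax of log P(X) + sum_i n_i log f_i(X) - tau sum_i f_i(X)."""
    best, best_val = 0, -np.inf
    for x in range(len(log_prior)):
        val = log_prior[x]
        for i, n_i in enumerate(counts):
            val += n_i * np.log(rates[i, x])
        val -= tau * rates[:, x].sum()
        if val > best_val + 1e-15:
            best, best_val = x, val
    return best


def binomial_two_tailed_oracle(k, n, p):
    """Two-tailed exact binomial p-value: sum of all outcome probabilities not
    exceeding the observed one."""
    pmf = np.array([comb(n, j, exact=True) * p**j * (1 - p) ** (n - j)
                    for j in range(n + 1)])
    return float(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())
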