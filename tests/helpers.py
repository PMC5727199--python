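"""Shared independent oracles for the test suite."""

import math


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins whose
    hypergeometric probability does not exceed the observed table's.
    """
    r1, r2, n1 = a + b, c + d, a + c
    lo, hi = max(0, n1 - r2), min(r1, n1)

    def pmf(k):
        return (math.comb(r1, k) * math.comb(r2, n1 - k)
                / math.comb(r1 + r2, n1))

    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))
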