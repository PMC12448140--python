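"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written along a different path from the
library implementation: exact rational arithmetic, itertools enumeration,
closed forms.
"""

import itertools
import math
from fractions import Fraction

import numpy as np


def fisher_p_enumeration(counts) -> Fraction:
    """Two-sided Fisher p for any r x c table by exact-Fraction enumeration.

    Enumerates every table with the observed margins via itertools products
    and sums the probabilities of tables as or less probable than observed.
    """
    counts = np.asarray(counts, dtype=int)
    rows, cols = counts.sum(axis=1), counts.sum(axis=0)
    n = counts.sum()

    def prob(tab) -> Fraction:
        num = math.prod(math.factorial(int(x)) for x in rows) * math.prod(
            math.factorial(int(x)) for x in cols
        )
        den = math.factorial(int(n)) * math.prod(math.factorial(int(x)) for x in np.ravel(tab))
        return Fraction(num, den)

    p_obs = prob(counts)
    total = Fraction(0)
    r = counts.shape[0]

    def tables(row_idx, remaining_cols):
        if row_idx == r - 1:
            yield (tuple(remaining_cols),)
            return
        target = rows[row_idx]
        for combo in itertools.product(*(range(min(target, rc) + 1) for rc in remaining_cols)):
            if sum(combo) == target:
                rest = [rc - v for rc, v in zip(remaining_cols, combo)]
                for tail in tables(row_idx + 1, rest):
                    yield (combo,) + tail

    for tab in tables(0, list(cols)):
        if prob(tab) <= p_obs:
            total += prob(tab)
    return total


def fisher_p_hypergeometric_2x2(a, b, c, d) -> Fraction:
    """Two-sided 2x2 Fisher p as an exact hypergeometric tail sum."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k) -> Fraction:
        return Fraction(math.comb(c1, k) * math.comb(n - c1, r1 - k), math.comb(n, r1))

    p_obs = pmf(a)
    return sum(
        (pk for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1) if (pk := pmf(k)) <= p_obs),
        Fraction(0),
    )
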