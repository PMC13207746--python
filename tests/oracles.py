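"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the Fisher oracle
enumerates every 2x2 table with the observed margins and sums exact
factorial-formula probabilities with rational arithmetic.
"""

from fractions import Fraction
from functools import lru_cache
from math import factorial


@lru_cache(maxsize=None)
def _fact(n: int) -> int:
    return factorial(n)


def enumeration_fisher(a: int, b: int, c: int, d: int, direction: str) -> float:
    """One-sided exact p for [[a, b], [c, d]] by exhaustive enumeration.

    Probability of each table with the same margins is
    r1! r2! c1! c2! / (n! a! b! c! d!); the tail sums tables at least as
    extreme toward large d ("positive") or large c ("negative").
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if n == 0:
        return 1.0
    total = Fraction(0)
    for ci in range(0, r2 + 1):
        di = r2 - ci
        ai = c1 - ci
        bi = c2 - di
        if ai < 0 or bi < 0:
            continue
        extreme = (di >= d) if direction == "positive" else (ci >= c)
        if extreme:
            total += Fraction(
                _fact(r1) * _fact(r2) * _fact(c1) * _fact(c2),
                _fact(n) * _fact(ai) * _fact(bi) * _fact(ci) * _fact(di),
            )
    return float(total)


def enumeration_fisher_all_tails(a: int, b: int, c: int, d: int):
    """Both one-sided tails at once (positive, negative)."""
    return (
        enumeration_fisher(a, b, c, d, "positive"),
        enumeration_fisher(a, b, c, d, "negative"),
    )
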