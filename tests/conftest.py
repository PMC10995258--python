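import math

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Independent Fisher oracle: enumerate all tables with the observed
    margins and sum hypergeometric probabilities <= that of the observed
    table (small tolerance for float ties)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_prob(x: int) -> float:
        # P(first cell = x) with fixed margins, via binomial coefficients
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(n, col1)
        )

    lo, hi = max(0, col1 - row2), min(row1, col1)
    p_obs = table_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(1.0, total)


def needleman_wunsch_distance(s: str, t: str) -> int:
    """Brute-force global edit distance (unit costs) for small strings;
    independent check of the alignment library."""
    m, n = len(s), len(t)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (s[i - 1] != t[j - 1]),
            )
        prev = cur
    return prev[n]


@pytest.fixture
def fisher_oracle():
    return fisher_two_sided_enumeration


@pytest.fixture
def edit_distance_oracle():
    return needleman_wunsch_distance
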