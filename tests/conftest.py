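import numpy as np
import pytest

from mutpanel.synthetic_data import synthetic_signature_matrix


@pytest.fixture(scope="session")
def sigs():
    """The synthetic 96 x 12 signature reference (deterministic)."""
    return synthetic_signature_matrix()


def brute_force_microhomology(reference: str, start: int, end: int, max_scan: int = 25) -> int:
    """Independent exhaustive scan: largest m with an m-base junction match."""
    s, e = start - 1, end - 1
    best = 0
    for m in range(max_scan, -1, -1):
        if e + 1 + m > len(reference) or s + m > len(reference):
            continue
        if reference[s : s + m] == reference[e + 1 : e + 1 + m]:
            best = m
            break
    return best


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p.

    Sums P(k) over the full support of tables with the observed margins for
    every k whose probability does not exceed that of the observed table.
    """
    import math

    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    kmin = max(0, col1 - row2)
    kmax = min(col1, row1)

    def log_p(k: int) -> float:
        return (
            math.lgamma(row1 + 1) - math.lgamma(k + 1) - math.lgamma(row1 - k + 1)
            + math.lgamma(row2 + 1) - math.lgamma(col1 - k + 1) - math.lgamma(row2 - col1 + k + 1)
            + math.lgamma(col1 + 1) + math.lgamma(n - col1 + 1) - math.lgamma(n + 1)
        )

    p_obs = math.exp(log_p(a))
    total = 0.0
    for k in range(kmin, kmax + 1):
        pk = math.exp(log_p(k))
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)
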