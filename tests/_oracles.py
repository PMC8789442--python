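"""Independent brute-force oracles used to pin expected values.

These deliberately use plain Python loops and the textbook definitions so
they share no code path with the package implementations they check.
"""

from __future__ import annotations

import math


def sample_entropy_bruteforce(x, m: int, r: float) -> float:
    """Textbook sample entropy by explicit template enumeration.

    Chebyshev distance, strict tolerance, self-matches excluded, the same
    ``N - m`` templates at both dimensions; returns the zero-match cap
    ``-ln(2 / ((N-m)(N-m-1)))`` when either count vanishes.
    """
    x = [float(v) for v in x]
    n = len(x)
    n_templ = n - m
    b = 0
    a = 0
    for i in range(n_templ):
        for j in range(i + 1, n_templ):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m < r:
                b += 1
                d_m1 = max(d_m, abs(x[i + m] - x[j + m]))
                if d_m1 < r:
                    a += 1
    if a == 0 or b == 0:
        return -math.log(2.0 / (n_templ * (n_templ - 1)))
    return -math.log(a / b)
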