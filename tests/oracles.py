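"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized implementations: plain
Python loops over the stated definitions, so they can serve as references.
"""

from __future__ import annotations

import math


def brute_force_peaks(values, z_threshold: float, min_sep_s: float, dt: float) -> list[int]:
    """Exhaustive scan for z-score peaks: z >= threshold, local maximum,
    greedy minimum separation (in whole samples, ceil of min_sep/dt) with the
    earlier peak winning."""
    n = len(values)
    mu = sum(values) / n
    sigma = math.sqrt(sum((v - mu) ** 2 for v in values) / n)  # population sigma
    if sigma == 0:
        return []
    z = [(v - mu) / sigma for v in values]
    min_gap = max(1, math.ceil(min_sep_s / dt - 1e-9)) if min_sep_s > 0 else 0
    kept: list[int] = []
    last = -n
    for i in range(1, n - 1):
        if z[i] >= z_threshold and z[i - 1] <= z[i] and z[i] >= z[i + 1]:
            if i - last >= min_gap:
                kept.append(i)
                last = i
    return kept


def closed_form_paired_t(pre, post) -> tuple[float, int]:
    """Textbook paired t: mean(d) / (sd(d)/sqrt(n)) on d = pre - post."""
    d = [a - b for a, b in zip(pre, post)]
    n = len(d)
    m = sum(d) / n
    s = math.sqrt(sum((x - m) ** 2 for x in d) / (n - 1))
    return m / (s / math.sqrt(n)), n - 1


def brute_force_wellness(signs: list[bool]) -> bool:
    """Direct evaluation of the flourishing rule on 14 binarized items
    (True = sign experienced at least '5-6 times a week')."""
    hedonic = sum(signs[0:3])
    eudemonic = sum(signs[3:14])
    return hedonic >= 1 and eudemonic >= 6
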