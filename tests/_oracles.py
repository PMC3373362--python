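"""Brute-force reference implementations, deliberately naive.

These re-derive the run-length and imputation primitives by exhaustive
scanning so the fast implementations can be checked against an independent
route on random inputs.
"""

import numpy as np


def brute_max_zero_run(zero):
    """Longest all-zero run, by scanning forward from every start index."""
    zero = list(zero)
    n = len(zero)
    best = 0
    for start in range(n):
        length = 0
        for end in range(start, n):
            if not zero[end]:
                break
            length += 1
            best = max(best, length)
    return best


def brute_lenient_zero(values, window):
    """Lenient zero-week classification by checking every (missing, anchor) pair.

    values: list with None for missing.  A missing week is ZERO when some
    responded zero-week lies within `window` weeks in either direction;
    responded weeks are ZERO iff they reported 0.
    """
    n = len(values)
    anchors = [i for i, v in enumerate(values) if v is not None and v == 0]
    out = []
    for i, v in enumerate(values):
        if v is not None:
            out.append(v == 0)
        else:
            out.append(any(abs(i - j) <= window for j in anchors))
    return out
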