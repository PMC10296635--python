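"""Independent brute-force oracles the implementation is checked against."""

import numpy as np


def oracle_lms(primary, reference, L, mu, normalized, eps=1e-8):
    """Literal textbook LMS/NLMS recursion, one scalar multiply at a time.

    Kept deliberately naive and independent of the implementation:
    explicit python loops, explicit regressor assembly.
    """
    w = [0.0] * L
    errors = []
    weight_rows = []
    for n in range(len(primary)):
        x = []
        for k in range(L):
            x.append(reference[n - k] if n - k >= 0 else 0.0)
        y = sum(w[k] * x[k] for k in range(L))
        e = primary[n] - y
        if normalized:
            denom = eps + sum(xi * xi for xi in x)
            step = mu / denom
        else:
            step = mu
        w = [w[k] + step * e * x[k] for k in range(L)]
        errors.append(e)
        weight_rows.append(list(w))
    return np.array(errors), np.array(weight_rows)
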