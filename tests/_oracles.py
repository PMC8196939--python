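"""Independent brute-force oracles shared by test modules."""

import numpy as np


def brute_force_endemic_I(p, n=200_001):
    """Endemic I-coordinates by dense sign scan + bisection.

    Equilibria satisfy S + I = A/d (sum of the two planar equations), so
    positive equilibria are roots of
    phi(I) = beta*(A/d - I) - (d+v) - c/(b+I) on (0, A/d).  This path is
    independent of the quadratic-formula implementation it checks.
    """
    lvl = p.A / p.d

    def phi(I):
        return p.beta * (lvl - I) - (p.d + p.v) - p.c / (p.b + I)

    I = np.linspace(1e-9, lvl - 1e-9, n)
    vals = phi(I)
    roots = []
    for k in np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        lo, hi = I[k], I[k + 1]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if phi(lo) * phi(mid) <= 0:
                hi = mid
            else:
                lo = mid
        roots.append(0.5 * (lo + hi))
    return roots
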