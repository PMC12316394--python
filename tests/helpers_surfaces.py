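"""Hand-built spline surfaces with known closed-form behaviour."""

import numpy as np

from spotpower.pspline import SplineSurface, make_knots


def constant_surface(c, N, pi_range=(0.0, 1.0), beta_range=(0.0, 3.0), q=6):
    """Surface with every tensor coefficient equal to c (predicts c)."""
    return SplineSurface(
        degree=2,
        knots1=make_knots(*pi_range, q),
        knots2=make_knots(*beta_range, q),
        gamma=np.full(q * q, float(c)),
        lambda1=1.0,
        lambda2=1.0,
        N=N,
        pi_range=pi_range,
        beta_range=beta_range,
    )


def ramp_surface(lo, hi, N, pi_range=(0.0, 1.0), beta_range=(0.0, 3.0), q=6):
    """Surface rising linearly from lo to hi along the pi axis."""
    theta = np.repeat(np.linspace(lo, hi, q), q)
    return SplineSurface(
        degree=2,
        knots1=make_knots(*pi_range, q),
        knots2=make_knots(*beta_range, q),
        gamma=theta,
        lambda1=1.0,
        lambda2=1.0,
        N=N,
        pi_range=pi_range,
        beta_range=beta_range,
    )
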