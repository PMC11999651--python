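"""Fast scalar densities for the numerical-integration oracles.

Plain-math implementations (no scipy distribution objects) so that
adaptive quadrature over products of these is cheap; each is verified
against scipy in test_rng/test_degeneracy via spot checks.
"""

import math

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def norm_pdf(x: float, mu: float, sd: float) -> float:
    z = (x - mu) / sd
    return math.exp(-0.5 * z * z - LOG_SQRT_2PI) / sd


def invgamma_pdf(x: float, a: float, scale: float) -> float:
    if x <= 0:
        return 0.0
    return math.exp(a * math.log(scale) - math.lgamma(a) - (a + 1) * math.log(x) - scale / x)
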