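"""Independent oracle implementations used to cross-check the library.

Everything here is coded from first principles along a different route than
the implementation under test (exact rational arithmetic, brute-force
enumeration) and must stay independent of :mod:`treesel`.
"""

from fractions import Fraction
from itertools import combinations
import math

import numpy as np
import sympy


def brute_force_pi(alleles: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean pairwise per-site difference over copy pairs with both copies
    observed, weighted over accessible sites (>= 2 observed copies)."""
    n, L = alleles.shape
    if weights is None:
        weights = np.ones(L)
    num = 0.0
    den = 0.0
    for j in range(L):
        col = alleles[:, j]
        obs = np.flatnonzero(col >= 0)
        if len(obs) < 2:
            continue
        pairs = list(combinations(obs, 2))
        diff = sum(col[a] != col[b] for a, b in pairs)
        num += weights[j] * diff / len(pairs)
        den += weights[j]
    return num / den if den else float("nan")


def tajimas_d_exact(n: int, S: int, pi_sum: float) -> float:
    """Tajima's D with every constant built in exact rational arithmetic."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_sum - float(S / a1)) / math.sqrt(float(var)))


def fu_li_star_exact(n: int, eta: int, eta_s: int, pi_sum: float) -> tuple[float, float]:
    """Fu & Li D* and F* with coefficients via sympy exact rationals.

    Same corrected coefficient conventions, independently transcribed.
    """
    N = sympy.Integer(n)
    an = sum(sympy.Rational(1, i) for i in range(1, n))
    bn = sum(sympy.Rational(1, i * i) for i in range(1, n))
    an1 = an + sympy.Rational(1, n)

    cn = 2 * (N * an - 2 * (N - 1)) / ((N - 1) * (N - 2))
    dn = cn + sympy.Rational(n - 2, (n - 1) ** 2) + \
        sympy.Rational(2, n - 1) * (sympy.Rational(3, 2) - (2 * an1 - 3) / (N - 2)
                                    - sympy.Rational(1, n))
    vD = ((N / (N - 1)) ** 2 * bn + an**2 * dn
          - 2 * (N * an * (an + 1)) / (N - 1) ** 2) / (an**2 + bn)
    uD = (N / (N - 1)) * (an - N / (N - 1)) - vD
    d_star = ((n / (n - 1)) * eta - float(an) * eta_s) \
        / math.sqrt(float(uD) * eta + float(vD) * eta * eta)

    vF = ((2 * N**3 + 110 * N**2 - 255 * N + 153) / (9 * N**2 * (N - 1))
          + 2 * (N - 1) * an / N**2 - 8 * bn / N) / (an**2 + bn)
    uF = ((4 * N**2 + 19 * N + 3 - 12 * (N + 1) * an1) / (3 * N * (N - 1))) / an - vF
    f_star = (pi_sum - ((n - 1) / n) * eta_s) \
        / math.sqrt(float(uF) * eta + float(vF) * eta * eta)
    return float(d_star), float(f_star)


def binom_cdf_exact(k: int, n: int, p: float) -> float:
    """Binomial CDF by direct pmf summation with math.comb."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i)
               for i in range(0, k + 1))


def binom_quantile_exact(q: float, n: int, p: float) -> int:
    """Smallest integer k with CDF(k; n, p) >= q."""
    for k in range(n + 1):
        if binom_cdf_exact(k, n, p) >= q:
            return k
    return n


def hwe_excess_pvalue_exact(n_het: int, n_minor: int, n_ind: int) -> float:
    """Upper-tail exact conditional Hardy-Weinberg probability of at least
    ``n_het`` heterozygotes, enumerated with exact rationals."""
    n_major = 2 * n_ind - n_minor
    if n_minor == 0 or n_major == 0:
        return 1.0
    probs = {}
    for h in range(n_minor % 2, min(n_minor, n_major) + 1, 2):
        n_aa = (n_minor - h) // 2
        n_bb = n_ind - n_aa - h
        if n_bb < 0:
            continue
        probs[h] = Fraction(
            math.factorial(n_ind) * 2**h,
            math.factorial(n_aa) * math.factorial(h) * math.factorial(n_bb))
    total = sum(probs.values())
    tail = sum(v for h, v in probs.items() if h >= n_het)
    return float(Fraction(tail, total))
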