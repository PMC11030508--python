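"""Independent oracles used by the test suite.

Each function here is deliberately written from first principles (series,
enumeration, closed forms) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import math

import numpy as np


def log_beta(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


def reg_inc_beta(x: float, a: float, b: float, terms: int = 500) -> float:
    """Regularized incomplete beta I_x(a, b) by the standard power series.

    I_x(a,b) = x^a (1-x)^b / (a B(a,b)) · Σ_{n≥0} [B(a+1, n+1)/B(a+b, n+1)] x^{n+1}
    — implemented via the hypergeometric series with symmetry fallback for
    numerical stability when x > (a+1)/(a+b+2).
    """
    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    if x > (a + 1.0) / (a + b + 2.0):
        return 1.0 - reg_inc_beta(1.0 - x, b, a, terms)
    # I_x(a,b) = x^a (1-x)^b / (a·B(a,b)) · 2F1(a+b, 1; a+1; x),
    # 2F1 summed term by term: term_n = term_{n-1} · (a+b+n-1)·x/(a+n)
    front = math.exp(a * math.log(x) + b * math.log1p(-x) - log_beta(a, b)) / a
    total, term = 1.0, 1.0
    for n in range(1, terms):
        term *= (a + b + n - 1.0) * x / (a + n)
        total += term
        if abs(term) < 1e-16 * abs(total):
            break
    return front * total


def f_cdf(f: float, d1: int, d2: int) -> float:
    """F distribution CDF via the incomplete beta series."""
    x = d1 * f / (d1 * f + d2)
    return reg_inc_beta(x, d1 / 2.0, d2 / 2.0)


def f_two_tailed_p(f: float, d1: int, d2: int) -> float:
    c = f_cdf(f, d1, d2)
    return 2.0 * min(c, 1.0 - c)


def binomial_sum_inc_beta(x: float, a: int, b: int) -> float:
    """I_x(a, b) for integer a, b via the binomial-sum identity:

    I_x(a, b) = P(Bin(a+b-1, x) >= a) = Σ_{j=a}^{a+b-1} C(a+b-1, j) x^j (1-x)^{a+b-1-j}
    """
    n = a + b - 1
    return sum(
        math.comb(n, j) * x**j * (1 - x) ** (n - j) for j in range(a, n + 1)
    )


def t_sf(t: float, df: float, n_grid: int = 200001) -> float:
    """Student-t survival function via I_x(df/2, 1/2) identity."""
    x = df / (df + t * t)
    p = 0.5 * reg_inc_beta(x, df / 2.0, 0.5)
    return p if t >= 0 else 1.0 - p


def welch_by_hand(x, y) -> tuple[float, float, float]:
    """Welch statistic, Satterthwaite df, and two-tailed p from raw formulas."""
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df, 2.0 * t_sf(abs(t), df)


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula (vertices as (N, 2))."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def ramanujan_ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def glcm_contrast_enumerated(image: np.ndarray, offset=(0, 1)) -> float:
    """GLCM contrast by brute-force enumeration of symmetric pixel pairs."""
    img = np.asarray(image)
    dr, dc = offset
    pairs = []
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                pairs.append((int(img[r, c]), int(img[r2, c2])))
                pairs.append((int(img[r2, c2]), int(img[r, c])))
    total = len(pairs)
    contrast = sum((i - j) ** 2 for i, j in pairs) / total
    return contrast


def gaussian_autocorr_1e_radius(sigma: float) -> float:
    """1/e radius of the autocorrelation of a Gaussian of width sigma: 2σ."""
    return 2.0 * sigma
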