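"""Independent statistical oracles used by the test suite.

These deliberately avoid scipy.stats test functions: t and F tail
probabilities go through the regularized incomplete beta function, ANOVA
through explicit sums of squares, and the studentized-range tail through
a direct double quadrature.
"""

import numpy as np
from scipy import integrate, special


def t_sf_via_betainc(t, df):
    """P(T > t) from the incomplete-beta representation of the t CDF."""
    x = df / (df + t * t)
    p_half = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return p_half if t >= 0 else 1.0 - p_half


def pooled_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * t_sf_via_betainc(abs(t), na + nb - 2)
    return t, p


def anova_oracle(groups):
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    k, N = len(groups), allv.size
    F = (ssb / (k - 1)) / (ssw / (N - k))
    d1, d2 = k - 1, N - k
    p = special.betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * F))
    return F, p


def studentized_range_sf(q, k, df):
    """P(Q > q) by direct double quadrature (outer: chi over df, inner: z)."""

    def inner(u):
        z = np.linspace(-8.0, 8.0, 2001)
        phi = np.exp(-z * z / 2.0) / np.sqrt(2.0 * np.pi)
        Phi = 0.5 * (1.0 + special.erf(z / np.sqrt(2.0)))
        Phi_shift = 0.5 * (1.0 + special.erf((z - q * u) / np.sqrt(2.0)))
        integrand = k * phi * (Phi - Phi_shift) ** (k - 1)
        return integrate.simpson(integrand, x=z)

    def outer(u):
        # density of u = s/sigma with s^2 ~ sigma^2 chi2_df / df
        logf = (df / 2.0) * np.log(df) + (df - 1) * np.log(u) - df * u * u / 2.0 \
            - special.gammaln(df / 2.0) - (df / 2.0 - 1.0) * np.log(2.0)
        return np.exp(logf) * inner(u)

    cdf, _ = integrate.quad(outer, 1e-9, 10.0, limit=200)
    return 1.0 - cdf


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    n = x.size
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * t_sf_via_betainc(abs(t), n - 2)
    return r, p
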