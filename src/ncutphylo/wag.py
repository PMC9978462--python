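"""Amino-acid substitution models for sequence simulation.

The WAG model (Whelan & Goldman 2001) is embedded as published constants:
190 symmetric exchangeabilities (row-wise upper triangle over the alphabet
``ARNDCQEGHILKMFPSTWYV``) and 20 equilibrium frequencies. The instantaneous
rate matrix is Q_ij = s_ij * pi_j (i != j), diagonal set so rows sum to
zero, scaled so the expected substitution rate at equilibrium is one —
branch lengths are then expected substitutions per (variable) site.

A Poisson (equal-rates, uniform-frequency) model is provided as a fast,
analytically transparent stand-in for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

# fmt: off
WAG_EXCHANGEABILITIES = [
    0.551571, 0.509848, 0.738998, 1.02704, 0.908598, 1.58285, 1.41672,
    0.316954, 0.193335, 0.397915, 0.906265, 0.893496, 0.210494, 1.43855,
    3.37079, 2.12111, 0.113133, 0.240735, 2.00601, 0.635346, 0.147304,
    0.528191, 3.0355, 0.439157, 0.584665, 2.13715, 0.186979, 0.497671,
    5.35142, 0.683162, 0.102711, 0.679489, 1.22419, 0.554413, 1.16392,
    0.381533, 0.251849, 5.42942, 0.265256, 1.54364, 0.947198, 1.12556,
    3.95629, 0.554236, 0.131528, 3.01201, 0.198221, 0.0961621, 0.195081,
    3.97423, 2.03006, 0.0719167, 1.086, 0.196246, 0.0302949, 0.616783,
    6.17416, 0.865584, 0.930676, 0.039437, 0.0848047, 0.479855, 0.103754,
    0.0467304, 0.423984, 1.07176, 0.374866, 0.129767, 0.325711, 0.152335,
    0.0988179, 0.021352, 0.306674, 0.248972, 0.170135, 0.384287, 0.0740339,
    0.390482, 0.39802, 0.109404, 1.40766, 0.512984, 0.71707, 0.543833,
    1.00214, 5.46947, 0.330052, 4.29411, 0.113917, 0.869489, 3.8949,
    1.54526, 0.0999208, 0.933372, 1.02887, 0.857928, 0.215737, 0.22771,
    0.301281, 0.567717, 0.570025, 0.127395, 0.154263, 2.58443, 0.315124,
    0.0811339, 0.682355, 0.704939, 0.822765, 0.156557, 0.196303, 0.588731,
    0.24941, 0.0304501, 0.0613037, 0.373558, 0.1741, 0.049931, 0.24357,
    1.34182, 0.225833, 0.336983, 0.103604, 0.187247, 0.13819, 0.499462,
    0.890432, 0.404141, 0.679371, 0.696198, 0.740169, 0.473307, 0.262569,
    3.87344, 0.118358, 3.17097, 0.323832, 4.25746, 1.05947, 0.0999288,
    0.31944, 1.45816, 0.212483, 0.42017, 7.8213, 0.257555, 4.85402,
    2.11517, 0.415844, 0.344739, 0.326622, 0.665309, 0.398618, 1.80034,
    0.934276, 0.088836, 0.556896, 0.96713, 1.38698, 0.137505, 0.133264,
    0.305434, 1.19063, 0.171329, 0.493905, 1.51612, 0.515706, 0.428437,
    2.05845, 0.161444, 0.545931, 0.171903, 1.52964, 6.45428, 0.649892,
    1.61328, 0.795384, 0.139405, 0.216046, 0.314887, 4.37802, 0.523742,
    0.786993, 0.232739, 0.110864, 0.291148, 1.38823, 2.48539, 0.365369,
    0.31473,
]
WAG_FREQUENCIES = [
    0.086627909, 0.043972004, 0.039089404, 0.057045106, 0.019307802,
    0.036728104, 0.058058906, 0.083251808, 0.024431302, 0.048466005,
    0.086209009, 0.062028606, 0.019502702, 0.038431904, 0.045763105,
    0.069517907, 0.061012706, 0.014385901, 0.035274204, 0.070895607,
]
# fmt: on


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible amino-acid CTMC, rate-normalized to one
    expected substitution per unit time at equilibrium."""

    name: str
    rate_matrix: np.ndarray  # (20, 20), rows sum to zero
    frequencies: np.ndarray  # (20,), sums to one

    @property
    def n_states(self) -> int:
        return len(self.frequencies)


def _build(name: str, exchangeabilities, frequencies) -> SubstitutionModel:
    pi = np.asarray(frequencies, dtype=float)
    pi = pi / pi.sum()
    k = len(pi)
    s = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    s[iu] = exchangeabilities
    s = s + s.T
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float((pi * np.diag(q)).sum())
    return SubstitutionModel(name=name, rate_matrix=q / mu, frequencies=pi)


def wag_model() -> SubstitutionModel:
    return _build("WAG", WAG_EXCHANGEABILITIES, WAG_FREQUENCIES)


def poisson_model() -> SubstitutionModel:
    """Equal exchangeabilities, uniform frequencies: the Jukes–Cantor
    analogue for proteins. Useful as a fast, closed-form test double."""
    k = 20
    n_pairs = k * (k - 1) // 2
    return _build("Poisson", np.ones(n_pairs), np.full(k, 1.0 / k))


def discrete_gamma_rates(shape: float, categories: int) -> np.ndarray:
    """Equal-probability discrete gamma rate categories (category means),
    normalized to mean exactly one."""
    from scipy import stats

    if categories < 1:
        raise ValueError("need at least one category")
    if categories == 1:
        return np.ones(1)
    edges = stats.gamma.ppf(
        np.linspace(0, 1, categories + 1), a=shape, scale=1.0 / shape
    )
    # mean of the gamma within each equal-probability slice
    lower = stats.gamma.cdf(edges[:-1], a=shape + 1, scale=1.0 / shape)
    upper = stats.gamma.cdf(edges[1:], a=shape + 1, scale=1.0 / shape)
    rates = (upper - lower) * categories
    return rates / rates.mean()
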