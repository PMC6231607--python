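"""The blind-respondent null model and its significance thresholds.

Under the null model N a respondent recognizes each other member of the
population independently with probability ``gamma``, sorts every recognized
member into one of ``B`` clusters uniformly at random, and affirms attribute
``a`` with probability ``beta_a``.  For a uniformly random pair of distinct
members, the per-respondent probability of recognizing both and co-clustering
them is

    p = (1/B) * sum_r sum_l  z_r * C(r,l) C(n-r,k-l)/C(n,k) * C(l,2)/C(n,2)

with ``z_r`` the binomial recognition-degree mass, ``l`` ranging over
``max(2, k+r-n) .. min(r, k)``, and the split probability ``q = (B-1) p``.
Over ``m`` sampled respondents the co-cluster count ``X`` and split count
``Y`` of a pair are Binomial(m, p) and Binomial(m, q); the significance
cutoffs are the minimal integers whose strict lower tails reach the
configured confidence level.

All combinatorial terms are evaluated through log-gamma and combined with a
log-sum-exp so paper-scale coefficients such as C(393, 40) never overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .study_io import ReportSet

__all__ = [
    "NullModelParams",
    "PairNullDistributions",
    "estimate_gamma",
    "estimate_beta",
    "estimate_beta_vector",
    "recognition_pmf",
    "copair_probabilities",
    "pair_count_distributions",
    "thresholds",
    "calibrate",
]


@dataclass(frozen=True)
class NullModelParams:
    """The M + 5 free parameters of the null model.

    n: population size; m: number of reports; k: photos shown per report;
    B: number of clusters offered; gamma: recognition probability; beta:
    per-attribute affirmation rates; sig_level: confidence level used for both
    tie thresholds and attribute tests.
    """

    n: int
    m: int
    k: int
    b_clusters: int
    gamma: float
    beta: tuple[float, ...] = ()
    sig_level: float = 0.95

    def __post_init__(self):
        if not (2 <= self.k <= self.n):
            raise ValueError("need 2 <= k <= n")
        if self.m < 1:
            raise ValueError("need m >= 1")
        if self.b_clusters < 1:
            raise ValueError("need B >= 1")
        for name, value in [("gamma", self.gamma), ("sig_level", self.sig_level)]:
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(not (0.0 <= b <= 1.0) for b in self.beta):
            raise ValueError("beta rates must lie in [0, 1]")


@dataclass(frozen=True)
class PairNullDistributions:
    """Null distributions of the pair counts X and Y with their cutoffs."""

    p: float
    q: float
    x_pmf: np.ndarray = field(repr=False)
    y_pmf: np.ndarray = field(repr=False)
    delta_plus: int
    delta_minus: int


class UndefinedEstimateError(ValueError):
    """Raised when an estimator has no data to average over."""


def estimate_gamma(reports: ReportSet) -> float:
    """Moment-match the recognition rate: gamma = sum_i d(s_i) / (m k).

    ``k`` is the configured nominal photos-shown count, so the estimator stays
    well defined when lenient mode allowed varying shown-set sizes.
    """
    if reports.m == 0 or reports.k == 0:
        raise UndefinedEstimateError("gamma undefined without reports")
    total = sum(rep.recognition_degree for rep in reports.reports)
    return total / (reports.m * reports.k)


def estimate_beta(reports: ReportSet, attribute: str) -> float:
    """Fraction of affirmative opinions among all recorded opinions for one attribute."""
    affirm = 0
    count = 0
    for rep in reports.reports:
        for (_member, aid), o in rep.opinions.items():
            if aid == attribute:
                affirm += o
                count += 1
    if count == 0:
        raise UndefinedEstimateError(f"no opinions recorded for attribute {attribute!r}")
    return affirm / count


def estimate_beta_vector(reports: ReportSet) -> tuple[float, ...]:
    """Per-attribute affirmation rates, in catalog order."""
    return tuple(estimate_beta(reports, a) for a in reports.attributes.attributes)


def _log_comb(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def recognition_pmf(params: NullModelParams) -> np.ndarray:
    """z_r over r = 0..n-1: Binomial(n-1, gamma) recognition-degree mass."""
    return binom.pmf(np.arange(params.n), params.n - 1, params.gamma)


def copair_probabilities(params: NullModelParams) -> tuple[float, float]:
    """Per-respondent probabilities (p, q) of co-clustering / splitting a random pair.

    The double sum runs over the recognition degree ``r`` and the number
    ``l`` of recognized members among the ``k`` shown; empty ``l`` ranges
    contribute nothing.  Degenerate ``gamma`` in {0, 1} collapses the ``r``
    sum to a single term.
    """
    n, k, b, g = params.n, params.k, params.b_clusters, params.gamma
    log_terms = []
    if g == 0.0:
        r_values = [0]
    elif g == 1.0:
        r_values = [n - 1]
    else:
        r_values = range(n)
    for r in r_values:
        lo, hi = max(2, k + r - n), min(r, k)
        if hi < lo:
            continue
        ls = np.arange(lo, hi + 1)
        if g in (0.0, 1.0):
            log_z = 0.0
        else:
            log_z = _log_comb(n - 1, r) + r * np.log(g) + (n - r - 1) * np.log1p(-g)
        log_hyper = _log_comb(r, ls) + _log_comb(n - r, k - ls) - _log_comb(n, k)
        log_pair = _log_comb(ls, 2) - _log_comb(n, 2)
        log_terms.append(log_z + log_hyper + log_pair)
    if not log_terms:
        return 0.0, 0.0
    total = float(np.exp(logsumexp(np.concatenate(log_terms))))
    return total / b, total * (b - 1) / b


def thresholds(params: NullModelParams, level: float | None = None) -> tuple[int, int]:
    """Minimum integers whose strict lower tails reach ``level``.

    delta_plus = min{w : P[X < w] >= level}, and analogously delta_minus for
    Y; ``P[X < w]`` is the strict tail ``cdf(w - 1)``, so level 0 yields 0.
    An observed count is significant when it is >= the returned cutoff.
    """
    if level is None:
        level = params.sig_level
    if not (0.0 <= level <= 1.0):
        raise ValueError("level must lie in [0, 1]")
    p, q = copair_probabilities(params)
    return (_min_tail_index(params.m, p, level), _min_tail_index(params.m, q, level))


def _min_tail_index(m: int, rate: float, level: float) -> int:
    for w in range(0, m + 2):
        if binom.cdf(w - 1, m, rate) >= level:
            return w
    return m + 1


def pair_count_distributions(
    params: NullModelParams, level: float | None = None
) -> PairNullDistributions:
    """Binomial(m, p) and Binomial(m, q) pmfs of X and Y, plus the cutoffs."""
    if level is None:
        level = params.sig_level
    p, q = copair_probabilities(params)
    support = np.arange(params.m + 1)
    return PairNullDistributions(
        p=p,
        q=q,
        x_pmf=binom.pmf(support, params.m, p),
        y_pmf=binom.pmf(support, params.m, q),
        delta_plus=_min_tail_index(params.m, p, level),
        delta_minus=_min_tail_index(params.m, q, level),
    )


def calibrate(
    reports: ReportSet,
    *,
    n: int | None = None,
    sig_level: float = 0.95,
) -> NullModelParams:
    """Estimate gamma and the beta vector from data and assemble the null model.

    ``n`` defaults to the roster size; ``m`` is whatever the data contains.
    Attributes with no recorded opinions get beta = 0 with the understanding
    that downstream attribute tests on them are vacuous.
    """
    gamma = estimate_gamma(reports)
    beta = []
    for a in reports.attributes.attributes:
        try:
            beta.append(estimate_beta(reports, a))
        except UndefinedEstimateError:
            beta.append(0.0)
    return NullModelParams(
        n=n if n is not None else reports.n,
        m=reports.m,
        k=reports.k,
        b_clusters=reports.b_clusters,
        gamma=gamma,
        beta=tuple(beta),
        sig_level=sig_level,
    )
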