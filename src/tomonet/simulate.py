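"""Synthetic report generation: null and planted-structure simulators.

The null simulator realizes the blind-respondent model exactly as the
significance machinery assumes it: ``m`` respondents drawn uniformly without
replacement from the roster, each shown a uniform random ``k``-subset of all
``n`` photos (possibly including their own, which carries no entries),
recognizing each shown other with probability ``gamma``, clustering each
recognized member uniformly over ``B`` bins, and affirming attribute ``a``
with probability ``beta_a``.  Because respondents are roster members, a
uniformly random pair is co-clustered by a random respondent with exactly the
null-model probability ``p`` — including the 2/n chance that the respondent
is one of the pair and so cannot place both.

The planted simulator adds known structure for recovery tests: members carry
one of ``K_true`` community labels, an observer routes a recognized member to
the bin indexed by its community with probability ``phi`` (derived from the
target same-community co-clustering rate ``theta_in``) and to a uniform other
bin otherwise; attributes follow community-dependent ground-truth roles with
observer true/false-positive opinion rates.  It is a deliberately simple
perception model whose only job is to create data with the statistical
structure the inference assumes.

Randomness is split per respondent (``default_rng([seed, i])``), so growing
``m`` never reshuffles earlier respondents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_io import AttributeCatalog, Bin, Report, ReportSet, Roster

__all__ = [
    "NullSimConfig",
    "PlantedConfig",
    "simulate_null_reports",
    "simulate_planted_reports",
    "random_signed_network",
]


def random_signed_network(
    n: int, edge_prob: float = 0.4, neg_frac: float = 0.5, seed: int = 0
):
    """Erdos-Renyi signed network for optimizer validation.

    Each pair is an edge with probability ``edge_prob``; an edge is negative
    with probability ``neg_frac``.  Evidence counts are synthetic (one
    supporting report per edge).
    """
    from .ties import PairEvidence, SignedNetwork

    rng = np.random.default_rng(seed)
    members = _members(n)
    edges: dict[tuple[str, str], int] = {}
    evidence: dict[tuple[str, str], PairEvidence] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() >= edge_prob:
                continue
            pair = (members[i], members[j])
            sign = -1 if rng.random() < neg_frac else +1
            edges[pair] = sign
            evidence[pair] = PairEvidence(
                pair=pair,
                n_corecognized=1,
                x_obs=1 if sign > 0 else 0,
                y_obs=0 if sign > 0 else 1,
            )
    return SignedNetwork(
        nodes=frozenset(members), edges=edges, contested=frozenset(), evidence=evidence
    )


@dataclass(frozen=True)
class NullSimConfig:
    """Parameters of a blind-respondent simulation."""

    n: int
    m: int
    k: int
    b_clusters: int
    gamma: float
    beta: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.k <= self.n):
            raise ValueError("need 2 <= k <= n")
        if not (1 <= self.m <= self.n):
            raise ValueError("need 1 <= m <= n (respondents are roster members)")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if any(not (0.0 <= b <= 1.0) for b in self.beta):
            raise ValueError("beta rates must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedConfig:
    """Parameters of a community/role-structured simulation.

    ``theta_in``/``theta_out``: target probabilities that an observer
    co-clusters a recognized pair from the same / different true communities.
    ``role_prob[c][a]``: probability that a member of community ``c`` truly
    holds attribute ``a``.  ``opinion_tp``/``opinion_fp``: P(affirm | holder)
    and P(affirm | non-holder).  ``close_prob``: probability a recognized
    member is instead binned CLOSE (and so drops out of pair tallies).
    """

    n: int
    m: int
    k: int
    b_clusters: int
    community_sizes: tuple[int, ...]
    gamma: float = 0.75
    theta_in: float = 0.9
    theta_out: float = 0.1
    role_prob: tuple[tuple[float, ...], ...] = ()
    opinion_tp: float = 0.85
    opinion_fp: float = 0.05
    close_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if sum(self.community_sizes) != self.n:
            raise ValueError("community sizes must sum to n")
        if len(self.community_sizes) > self.b_clusters:
            raise ValueError("more true communities than bins: K_true must be <= B")
        if not (2 <= self.k <= self.n and 1 <= self.m <= self.n):
            raise ValueError("invalid k or m")
        probs = [self.gamma, self.theta_in, self.theta_out, self.opinion_tp,
                 self.opinion_fp, self.close_prob]
        probs += [p for row in self.role_prob for p in row]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    @property
    def k_true(self) -> int:
        return len(self.community_sizes)


def _members(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"P{i:0{width}d}" for i in range(n))


def _attr_ids(m_attrs: int) -> tuple[str, ...]:
    return tuple(f"A{j + 1}" for j in range(m_attrs))


def simulate_null_reports(config: NullSimConfig) -> ReportSet:
    """Draw a ReportSet from the blind-respondent null model."""
    members = _members(config.n)
    attrs = _attr_ids(len(config.beta))
    roster = Roster(members=members)
    catalog = AttributeCatalog(attributes=attrs if attrs else ("A1",))
    master = np.random.default_rng(config.seed)
    respondents = master.permutation(config.n)[: config.m]
    beta = np.asarray(config.beta, dtype=float)
    reports = []
    for i, ridx in enumerate(respondents):
        rng = np.random.default_rng([config.seed, i])
        shown_idx = rng.choice(config.n, size=config.k, replace=False)
        rid = members[ridx]
        bins: dict[str, Bin] = {}
        clusters: dict[str, int] = {}
        opinions: dict[tuple[str, str], int] = {}
        for vidx in shown_idx:
            if vidx == ridx:
                continue  # own photo carries no entries
            v = members[vidx]
            if rng.random() < config.gamma:
                bins[v] = Bin.RECOGNIZED
                clusters[v] = int(rng.integers(1, config.b_clusters + 1))
                if len(beta):
                    affirm = rng.random(len(beta)) < beta
                    for j, a in enumerate(attrs):
                        opinions[(v, a)] = int(affirm[j])
            else:
                bins[v] = Bin.UNKNOWN
        reports.append(
            Report(
                respondent_id=rid,
                shown=tuple(members[j] for j in shown_idx),
                bin=bins,
                cluster=clusters,
                opinions=opinions,
            )
        )
    return ReportSet(
        roster=roster,
        attributes=catalog,
        reports=reports,
        k=config.k,
        b_clusters=config.b_clusters,
    )


def _own_bin_probability(theta_in: float, b_clusters: int) -> float:
    """Solve phi so that two same-community members co-cluster w.p. theta_in.

    Both land in the community's own bin (phi^2) or both stray to the same
    other bin ((1-phi)^2 / (B-1)):

        (1 + 1/(B-1)) phi^2 - (2/(B-1)) phi + 1/(B-1) - theta_in = 0
    """
    if b_clusters == 1:
        return 1.0
    inv = 1.0 / (b_clusters - 1)
    a, b, c = 1.0 + inv, -2.0 * inv, inv - theta_in
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError(f"theta_in={theta_in} unreachable with B={b_clusters}")
    return (-b + math.sqrt(disc)) / (2 * a)


@dataclass
class PlantedTruth:
    """Ground truth returned beside a planted ReportSet."""

    communities: dict[str, int]  # member -> community index 1..K_true
    q_matrix: pd.DataFrame = field(repr=False)  # members x attributes of +-1


def simulate_planted_reports(config: PlantedConfig) -> tuple[ReportSet, PlantedTruth]:
    """Draw a ReportSet with planted communities and attribute roles.

    When ``theta_in == theta_out`` there is no community contrast and
    clustering falls back to uniform bins — reproducing the null model's
    pair statistics exactly.
    """
    members = _members(config.n)
    m_attrs = len(config.role_prob[0]) if config.role_prob else 0
    attrs = _attr_ids(m_attrs)
    roster = Roster(members=members)
    catalog = AttributeCatalog(attributes=attrs if attrs else ("A1",))

    comm = np.repeat(np.arange(1, config.k_true + 1), config.community_sizes)
    master = np.random.default_rng(config.seed)
    master.shuffle(comm)

    # ground-truth roles
    q = np.full((config.n, m_attrs), -1, dtype=int)
    if m_attrs:
        role = np.asarray(config.role_prob, dtype=float)  # (K_true, M)
        draws = master.random((config.n, m_attrs))
        q[draws < role[comm - 1]] = 1

    uniform = config.theta_in == config.theta_out
    phi = None if uniform else _own_bin_probability(config.theta_in, config.b_clusters)
    if phi is not None:
        bb = config.b_clusters
        cross = 2 * phi * (1 - phi) / (bb - 1) + (1 - phi) ** 2 * (bb - 2) / (bb - 1) ** 2
        if cross > config.theta_out + 1e-9:
            raise ValueError(
                f"theta_in={config.theta_in} implies cross-community co-clustering "
                f"{cross:.3f} > theta_out={config.theta_out}"
            )

    respondents = master.permutation(config.n)[: config.m]
    reports = []
    for i, ridx in enumerate(respondents):
        rng = np.random.default_rng([config.seed, i])
        shown_idx = rng.choice(config.n, size=config.k, replace=False)
        rid = members[ridx]
        bins: dict[str, Bin] = {}
        clusters: dict[str, int] = {}
        opinions: dict[tuple[str, str], int] = {}
        for vidx in shown_idx:
            if vidx == ridx:
                continue
            v = members[vidx]
            if rng.random() >= config.gamma:
                bins[v] = Bin.UNKNOWN
                continue
            if rng.random() < config.close_prob:
                bins[v] = Bin.CLOSE
                continue
            bins[v] = Bin.RECOGNIZED
            if uniform:
                c = int(rng.integers(1, config.b_clusters + 1))
            else:
                own = int(comm[vidx])
                if rng.random() < phi:
                    c = own
                else:
                    others = [b for b in range(1, config.b_clusters + 1) if b != own]
                    c = int(others[rng.integers(0, len(others))])
            clusters[v] = c
            for j, a in enumerate(attrs):
                rate = config.opinion_tp if q[vidx, j] == 1 else config.opinion_fp
                opinions[(v, a)] = int(rng.random() < rate)
        reports.append(
            Report(
                respondent_id=rid,
                shown=tuple(members[j] for j in shown_idx),
                bin=bins,
                cluster=clusters,
                opinions=opinions,
            )
        )
    report_set = ReportSet(
        roster=roster,
        attributes=catalog,
        reports=reports,
        k=config.k,
        b_clusters=config.b_clusters,
    )
    truth = PlantedTruth(
        communities={members[i]: int(comm[i]) for i in range(config.n)},
        q_matrix=pd.DataFrame(q, index=members, columns=attrs),
    )
    return report_set, truth
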