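"""Perceived-attribute ascription from third-party opinions.

For member ``j``, the observer set ``O_j`` holds the respondents who placed
``j`` in their RECOGNIZED bin.  Under the null model the affirmative-opinion
count ``Z`` for attribute ``a`` is Binomial(|O_j|, beta_a).  The observed
count ``f`` is compared to its null expectation ``beta_a * |O_j|``: if above
it, an exact right-tailed binomial test; if below, a left-tailed test; a
significant tail (p <= 1 - level) yields +1 ("perceived to have") or -1
("perceived to not have"), anything else 0 ("inconclusive").  No normal
approximation is used — the exact tails stay well defined at small
observer counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .study_io import Bin, ReportSet

__all__ = ["AttributeEstimate", "observer_sets", "ascribe_attribute", "ascribe_all"]


@dataclass
class AttributeEstimate:
    """Ascribed perception matrix with its supporting counts.

    ``q_tilde``: members x attributes frame of {-1, 0, +1}; ``f``: affirmation
    counts; ``o_size``: opinion counts per (member, attribute); ``tail_prob``:
    the exact tail probability of each decision (NaN where no test ran).
    """

    q_tilde: pd.DataFrame
    f: pd.DataFrame
    o_size: pd.DataFrame
    tail_prob: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Per-attribute counts of have / not-have / inconclusive members."""
        rows = []
        for a in self.q_tilde.columns:
            col = self.q_tilde[a]
            rows.append(
                {
                    "attribute": a,
                    "have": int((col == 1).sum()),
                    "not_have": int((col == -1).sum()),
                    "inconclusive": int((col == 0).sum()),
                }
            )
        return pd.DataFrame(rows)


def observer_sets(reports: ReportSet) -> dict[str, set[str]]:
    """O_j: the respondents who placed member j in their RECOGNIZED bin."""
    out: dict[str, set[str]] = {v: set() for v in reports.roster.members}
    for rep in reports.reports:
        for v, b in rep.bin.items():
            if b is Bin.RECOGNIZED:
                out[v].add(rep.respondent_id)
    return out


def ascribe_attribute(
    f: int, o_size: int, beta_a: float, level: float = 0.95
) -> tuple[int, float]:
    """Exact one-sided binomial decision for one (member, attribute) cell.

    Returns ``(decision, tail_probability)`` with decision in {-1, 0, +1}.
    ``f`` exactly at the null expectation (including the no-observer case)
    is inconclusive without running a test.
    """
    if not (0.0 <= beta_a <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    if not (0 <= f <= o_size):
        raise ValueError("need 0 <= f <= o_size")
    expectation = beta_a * o_size
    if o_size == 0 or f == expectation:
        return 0, float("nan")
    alpha = 1.0 - level
    if f > expectation:
        tail = float(binom.sf(f - 1, o_size, beta_a))  # P[Z >= f]
        return (+1 if tail <= alpha else 0), tail
    tail = float(binom.cdf(f, o_size, beta_a))  # P[Z <= f]
    return (-1 if tail <= alpha else 0), tail


def ascribe_all(
    reports: ReportSet,
    beta: tuple[float, ...] | None = None,
    level: float = 0.95,
) -> AttributeEstimate:
    """Ascribe the full members x attributes perception matrix.

    ``beta`` defaults to the rates estimated from the reports themselves
    (globally, pooling all opinions per attribute); an externally supplied
    vector supports sensitivity analysis.  Opinions are counted only where
    recorded, so ``o_size`` can be smaller than ``|O_j|`` if some observers
    skipped the attribute question.
    """
    from .null_model import UndefinedEstimateError, estimate_beta

    attrs = list(reports.attributes.attributes)
    members = list(reports.roster.members)
    if beta is None:
        vals = []
        for a in attrs:
            try:
                vals.append(estimate_beta(reports, a))
            except UndefinedEstimateError:
                vals.append(0.0)
        beta = tuple(vals)
    if len(beta) != len(attrs):
        raise ValueError("beta vector length must match the attribute catalog")

    midx = {v: i for i, v in enumerate(members)}
    aidx = {a: i for i, a in enumerate(attrs)}
    f = np.zeros((len(members), len(attrs)), dtype=int)
    o = np.zeros_like(f)
    for rep in reports.reports:
        for (v, a), opinion in rep.opinions.items():
            f[midx[v], aidx[a]] += opinion
            o[midx[v], aidx[a]] += 1

    q = np.zeros_like(f)
    tail = np.full(f.shape, np.nan)
    for j, a in enumerate(attrs):
        for i in range(len(members)):
            q[i, j], tail[i, j] = ascribe_attribute(
                int(f[i, j]), int(o[i, j]), beta[j], level
            )
    return AttributeEstimate(
        q_tilde=pd.DataFrame(q, index=members, columns=attrs),
        f=pd.DataFrame(f, index=members, columns=attrs),
        o_size=pd.DataFrame(o, index=members, columns=attrs),
        tail_prob=pd.DataFrame(tail, index=members, columns=attrs),
    )
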