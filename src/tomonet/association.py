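"""Class-membership vs perceived-attribute association.

Each member's ascribed attribute status (-1 / 0 / +1) is regressed on
balance-class membership with a multinomial logit: classes are dummy coded
against a reference class (by default the largest), and the "inconclusive"
outcome 0 is the reference outcome, so the fitted coefficients are log
odds-ratios of being perceived to not-have (-1) or have (+1) the attribute
relative to inconclusive, for each class relative to the reference class.

Fitting is plain maximum likelihood through statsmodels.  Quasi-separation
(an empty class x outcome cell) is flagged rather than penalized away — with
sparse cells the MLE drifts to infinity and the reported standard errors
become enormous; the flag tells the reader which rows to distrust.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .attributes import AttributeEstimate
from .balance import SignedPartition

logger = logging.getLogger(__name__)

__all__ = ["AssociationModel", "build_design", "fit_multinomial", "associate_attribute"]

_OUTCOME_ORDER = (0, -1, 1)  # reference outcome first


@dataclass
class AssociationModel:
    """Fitted multinomial logit of outcome {-1,0,+1} on class dummies.

    ``coefficients``/``std_errors``: frames indexed by predictor (const +
    class dummies) with one column per non-reference outcome (-1 and +1).
    """

    attribute: str
    reference_class: int
    coefficients: pd.DataFrame
    std_errors: pd.DataFrame
    aic: float
    converged: bool
    separation_cells: list[tuple[int, int]]

    @property
    def quasi_separated(self) -> bool:
        return bool(self.separation_cells)

    def tidy(self) -> pd.DataFrame:
        rows = []
        for outcome in self.coefficients.columns:
            for pred in self.coefficients.index:
                rows.append(
                    {
                        "attribute": self.attribute,
                        "outcome": outcome,
                        "predictor": pred,
                        "coef": self.coefficients.loc[pred, outcome],
                        "se": self.std_errors.loc[pred, outcome],
                    }
                )
        return pd.DataFrame(rows)


def build_design(
    partition: SignedPartition,
    estimates: AttributeEstimate,
    attribute: str,
    reference_class: int | None = None,
) -> pd.DataFrame:
    """One row per assigned node: outcome plus K-1 class indicator columns.

    ``reference_class`` defaults to the largest class.  Nodes without an
    attribute estimate are excluded with a logged count.
    """
    if attribute not in estimates.q_tilde.columns:
        raise KeyError(f"no estimate for attribute {attribute!r}")
    if reference_class is None:
        sizes = partition.class_sizes()
        reference_class = int(np.argmax(sizes)) + 1
    if not (1 <= reference_class <= partition.n_classes):
        raise ValueError(f"reference class {reference_class} outside 1..{partition.n_classes}")
    rows = []
    dropped = 0
    estimated = set(estimates.q_tilde.index)
    for node, cls in sorted(partition.assignment.items()):
        if node not in estimated:
            dropped += 1
            continue
        rows.append((node, int(estimates.q_tilde.loc[node, attribute]), cls))
    if dropped:
        logger.warning("%d node(s) lacked an estimate for %r and were excluded",
                       dropped, attribute)
    df = pd.DataFrame(rows, columns=["node", "outcome", "cls"]).set_index("node")
    for c in range(1, partition.n_classes + 1):
        if c == reference_class:
            continue
        df[f"class_{c}"] = (df["cls"] == c).astype(int)
    df.attrs["reference_class"] = reference_class
    if not any(df["cls"] != reference_class):
        df.attrs["degenerate"] = True
        logger.warning("all nodes fall in the reference class: all-zero design")
    return df.drop(columns="cls")


def fit_multinomial(
    design: pd.DataFrame, attribute: str = "", maxiter: int = 200
) -> AssociationModel:
    """Fit the multinomial logit with outcome 0 as the reference level."""
    outcomes = design["outcome"]
    levels = [lv for lv in _OUTCOME_ORDER if (outcomes == lv).any()]
    if len(levels) < 2:
        raise ValueError("need at least 2 outcome levels to fit")
    codes = outcomes.map({lv: i for i, lv in enumerate(levels)})
    exog_cols = [c for c in design.columns if c != "outcome"]
    exog = sm.add_constant(design[exog_cols].astype(float), has_constant="add")

    # empty class x outcome cells push the MLE to infinity: flag them
    separation: list[tuple[int, int]] = []
    for col in exog_cols:
        for lv in levels:
            if not ((design[col] == 1) & (outcomes == lv)).any() and (design[col] == 1).any():
                separation.append((int(col.split("_")[1]), lv))

    model = sm.MNLogit(codes.to_numpy(), exog.to_numpy())
    with np.errstate(all="ignore"):
        fit = model.fit(disp=False, maxiter=maxiter, method="newton")
    converged = bool(fit.mle_retvals.get("converged", False))
    out_cols = levels[1:]  # non-reference outcomes, in (0, -1, 1) order
    coefs = pd.DataFrame(fit.params, index=exog.columns, columns=out_cols)
    ses = pd.DataFrame(fit.bse, index=exog.columns, columns=out_cols)
    return AssociationModel(
        attribute=attribute,
        reference_class=design.attrs.get("reference_class", 0),
        coefficients=coefs,
        std_errors=ses,
        aic=float(fit.aic),
        converged=converged,
        separation_cells=separation,
    )


def associate_attribute(
    partition: SignedPartition,
    estimates: AttributeEstimate,
    attribute: str,
    reference_class: int | None = None,
) -> AssociationModel:
    """Build the design and fit the multinomial model for one attribute."""
    design = build_design(partition, estimates, attribute, reference_class)
    return fit_multinomial(design, attribute=attribute)
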