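"""Biological labeling of fitted mixture components.

Once the mixture has separated the combined population into component
populations, two rule families decide what the components mean:

1. **Regular vs outlier** — if one component dominates the other in weight
   and neither body size (Mann–Whitney U on length) nor sex ratio
   (chi-squared) differs significantly between the hard-assigned groups,
   the dominant component represents the regular experimental results and
   the minor one collects outlier observations.
2. **Large-insect vs small-insect** — otherwise, if body size differs
   significantly, the component whose members are smaller on average is
   the small-insect population.

If neither rule fires the components stay unlabeled. All test statistics
and p-values are kept as evidence alongside the labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import Dataset
from .weibull_mix import MixtureModel, e_step

logger = logging.getLogger(__name__)

REGULAR = "regular"
OUTLIER = "outlier"
LARGE = "large_insect"
SMALL = "small_insect"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class RuleEvidence:
    """Outcome of one decision rule's statistical test."""

    name: str
    statistic: float
    p_value: float
    fired: bool


@dataclass
class LabeledModel:
    """A mixture model plus per-component biological labels and evidence."""

    model: MixtureModel
    labels: list[str]
    evidence: list[RuleEvidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != self.model.n_components:
            raise ValueError("exactly one label per component required")


def hard_assign(data: Dataset, model: MixtureModel) -> np.ndarray:
    """Maximum-responsibility component index per record (ties to lower index)."""
    resp = e_step(data, model)
    return np.argmax(resp, axis=1)


def size_test(
    data: Dataset, assignment: np.ndarray, a: int = 0, b: int = 1
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U on body length between two assigned groups.

    Records with missing length are dropped pairwise. Uses the exact null
    distribution when the combined sample is small (n <= 20), otherwise the
    normal approximation with tie correction.
    """
    lengths = data.length
    la = lengths[(assignment == a) & ~np.isnan(lengths)]
    lb = lengths[(assignment == b) & ~np.isnan(lengths)]
    if len(la) == 0 or len(lb) == 0:
        raise ValueError("both groups need at least one record with length data")
    method = "exact" if len(la) + len(lb) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(la, lb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def sex_test(
    data: Dataset, assignment: np.ndarray, a: int = 0, b: int = 1
) -> tuple[float, float]:
    """Chi-squared test of sex ratio between two assigned groups.

    2x2 table of known-sex counts, no continuity correction.
    """
    sex = data.sex
    table = np.zeros((2, 2))
    for col, g in enumerate((a, b)):
        in_g = assignment == g
        table[0, col] = np.sum(in_g & (sex == "M"))
        table[1, col] = np.sum(in_g & (sex == "F"))
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(
            "zero row/column in the sex table; consider Fisher's exact test"
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def chi2_from_table(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) for a printed 2x2 table."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table, dtype=float), correction=False)
    return float(chi2), float(p)


def label_components(
    data: Dataset,
    model: MixtureModel,
    alpha: float = 0.05,
    dominance_ratio: float = 3.0,
) -> LabeledModel:
    """Apply the labeling rules to a one- or two-component model.

    Parameters
    ----------
    alpha
        Significance level for the size and sex tests.
    dominance_ratio
        Minimum weight ratio (max/min) for one component to count as
        "substantially larger" than the other.
    """
    L = model.n_components
    if L == 1:
        return LabeledModel(model, [REGULAR])
    if L > 2:
        warnings.warn("labeling rules are defined for at most 2 components", stacklevel=2)
        return LabeledModel(model, [UNLABELED] * L)

    assignment = hard_assign(data, model)
    evidence: list[RuleEvidence] = []

    try:
        u_stat, u_p = size_test(data, assignment, 0, 1)
        have_size = True
    except ValueError:
        warnings.warn("missing size data disables the size-based rules", stacklevel=2)
        have_size = False
        u_stat, u_p = float("nan"), float("nan")
    try:
        chi2_stat, chi2_p = sex_test(data, assignment, 0, 1)
        have_sex = True
    except ValueError:
        have_sex = False
        chi2_stat, chi2_p = float("nan"), float("nan")

    w = model.weights
    ratio = float(w.max() / w.min())
    dominant = ratio >= dominance_ratio

    # Rule (i): one dominant component, no size or sex differences -> outlier split
    rule_i = (
        dominant
        and have_size
        and u_p > alpha
        and (not have_sex or chi2_p > alpha)
    )
    evidence.append(RuleEvidence("weight_dominance", ratio, float("nan"), dominant))
    evidence.append(RuleEvidence("size_mannwhitney_u", u_stat, u_p, rule_i))
    if have_sex:
        evidence.append(RuleEvidence("sex_chi2", chi2_stat, chi2_p, rule_i))

    if rule_i:
        labels = [REGULAR if w[j] == w.max() else OUTLIER for j in range(2)]
        return LabeledModel(model, labels, evidence)

    # Rule (ii): significant size difference -> large/small split
    if have_size and u_p <= alpha:
        lengths = data.length
        means = [
            np.nanmean(lengths[assignment == j]) if np.any(assignment == j) else np.nan
            for j in range(2)
        ]
        small = int(np.nanargmin(means))
        labels = [SMALL if j == small else LARGE for j in range(2)]
        evidence.append(RuleEvidence("size_split", float(means[small]), u_p, True))
        # informational only: weighted midpoint of the component mean lengths
        midpoint = float(np.nansum([w[j] * means[j] for j in range(2)]))
        logger.info("weighted midpoint of component mean lengths: %.2f mm", midpoint)
        return LabeledModel(model, labels, evidence)

    return LabeledModel(model, [UNLABELED, UNLABELED], evidence)
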