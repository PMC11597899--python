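"""Rule-based light-sensitivity classification.

A child is labelled hypo-sensitive (drawn to intense light), hyper-sensitive
(averse to bright light), or normal, from the mined supports:

* CCM: compare the HI vs LI selection supports and the HI vs LI total dwell
  durations.  Hypo-sensitive requires both percentage differences to reach
  the threshold **and** both quantities to point toward HI; hyper-sensitive
  is the LI mirror; everything else — including mixed directions — is normal.
* SCM: compare positive-response supports (HI_P vs LI_P) and
  negative-response supports (HI_N vs LI_N).  Hypo-sensitive requires both
  differences to reach the threshold with more positive and fewer negative
  responses under HI; hyper-sensitive is the mirror; the residual is normal.

The difference metric is the symmetric percentage difference
``|A - B| / ((A + B) / 2) * 100``, bounded in [0, 200] and invariant to a
common rescaling of A and B — which is why it is immaterial whether SCM
differences are taken on supports or raw counts.  The decision threshold
defaults to 40 (percent), compared with ``>=``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Optional, Union

from .mining import CCMSummary, SCMSummary

__all__ = [
    "SensitivityLabel",
    "ClassificationDetail",
    "DEFAULT_THRESHOLD",
    "percentage_difference",
    "classify_ccm",
    "classify_scm",
    "normalize_label",
]

DEFAULT_THRESHOLD = 40.0


class SensitivityLabel(str, Enum):
    HYPO = "hypo-sensitive"
    HYPER = "hyper-sensitive"
    NORMAL = "normal"

    @property
    def display(self) -> str:
        """Report rendering: 'Hypo-sensitive' / 'Hyper-sensitive' / 'Normal'."""
        return self.value.capitalize()


def normalize_label(label: Union[SensitivityLabel, str]) -> SensitivityLabel:
    """Parse a label leniently: case-, hyphen- and whitespace-insensitive.

    Printed reports mix casings ('Hypo-Sensitive', 'normal', ...); audits
    must treat them as equal.
    """
    if isinstance(label, SensitivityLabel):
        return label
    canon = str(label).strip().lower().replace("_", "-").replace(" ", "-")
    try:
        return SensitivityLabel(canon)
    except ValueError:
        raise ValueError(f"unknown sensitivity label: {label!r}") from None


def percentage_difference(a, b):
    """Symmetric percentage difference of two non-negative quantities.

    ``|a - b| / ((a + b) / 2) * 100``; by convention 0 when both inputs are 0
    (the limit of equal values), so an entirely absent response class never
    registers as a difference.  Exact when given ints/Fractions.

    Raises
    ------
    ValueError
        On a negative input.
    """
    if a < 0 or b < 0:
        raise ValueError(f"inputs must be non-negative, got ({a}, {b})")
    if a == b:
        return a - a  # 0 of the operand type
    return abs(a - b) / ((a + b) / Fraction(2)) * 100


@dataclass(frozen=True)
class ClassificationDetail:
    """A label together with the percentage differences that produced it.

    CCM details carry ``hls_diff`` (HI vs LI selection support) and
    ``hld_diff`` (HI vs LI total dwell duration); SCM details carry
    ``pr_diff`` (positive-response supports) and ``nr_diff``
    (negative-response supports).  All differences are in [0, 200].
    """

    label: SensitivityLabel
    threshold: float = DEFAULT_THRESHOLD
    hls_diff: Optional[float] = None
    hld_diff: Optional[float] = None
    pr_diff: Optional[float] = None
    nr_diff: Optional[float] = None

    def to_dict(self) -> dict:
        out = {"label": self.label.display, "threshold": self.threshold}
        for key in ("hls_diff", "hld_diff", "pr_diff", "nr_diff"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        return out


def classify_ccm(summary: CCMSummary, threshold: float = DEFAULT_THRESHOLD) -> ClassificationDetail:
    """Classify from CCM preference supports and dwell durations.

    Hypo-sensitive: both differences >= threshold with HI dominant in both
    support and duration.  Hyper-sensitive: both >= threshold with LI
    dominant in both.  Otherwise normal (balanced, sub-threshold, or mixed
    directions).
    """
    hls = percentage_difference(summary.support_hi, summary.support_li)
    hld = percentage_difference(summary.total_hi_duration_s, summary.total_li_duration_s)
    both = hls >= threshold and hld >= threshold
    if (
        both
        and summary.support_hi > summary.support_li
        and summary.total_hi_duration_s > summary.total_li_duration_s
    ):
        label = SensitivityLabel.HYPO
    elif (
        both
        and summary.support_li > summary.support_hi
        and summary.total_li_duration_s > summary.total_hi_duration_s
    ):
        label = SensitivityLabel.HYPER
    else:
        label = SensitivityLabel.NORMAL
    return ClassificationDetail(
        label=label, threshold=threshold, hls_diff=float(hls), hld_diff=float(hld)
    )


def classify_scm(summary: SCMSummary, threshold: float = DEFAULT_THRESHOLD) -> ClassificationDetail:
    """Classify from SCM (illumination, response) supports.

    Hypo-sensitive: positive responses concentrate under HI and negative
    responses under LI, both differences >= threshold.  Hyper-sensitive is
    the HI<->LI mirror.  Balanced responses are normal (the residual class).
    """
    pr = percentage_difference(summary.support_hi_p, summary.support_li_p)
    nr = percentage_difference(summary.support_hi_n, summary.support_li_n)
    both = pr >= threshold and nr >= threshold
    if (
        both
        and summary.support_hi_p > summary.support_li_p
        and summary.support_hi_n < summary.support_li_n
    ):
        label = SensitivityLabel.HYPO
    elif (
        both
        and summary.support_li_p > summary.support_hi_p
        and summary.support_li_n < summary.support_hi_n
    ):
        label = SensitivityLabel.HYPER
    else:
        label = SensitivityLabel.NORMAL
    return ClassificationDetail(
        label=label, threshold=threshold, pr_diff=float(pr), nr_diff=float(nr)
    )
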