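"""Support mining over interaction records.

Support is used in the Apriori sense: the proportion of logged transactions
(records) that contain a given item or item pair.  Only single items
(illumination classes, colors) and the four fixed (illumination, response)
pairs are mined — there is no candidate-generation lattice, because the
classification rules downstream consume exactly these supports.

Counts are kept as integers and supports as exact :class:`~fractions.Fraction`
values so that report percentages and agreement audits are reproducible
bit-for-bit; floats appear only in serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Union

import pandas as pd

from .records import CCMRecord, ChildLog, Illumination, Mode, SCMRecord, Valence

__all__ = [
    "CCMSummary",
    "SCMSummary",
    "item_supports",
    "ccm_summary",
    "scm_summary",
    "ccm_session_summaries",
    "scm_session_summaries",
    "ccm_incidence",
    "scm_incidence",
]


def item_supports(transactions: pd.DataFrame) -> dict[str, Fraction]:
    """Per-item supports from a binary incidence table.

    ``transactions`` has one row per transaction and one 0/1 column per item.
    The support of an item is its column sum divided by the row count.

    Returns a mapping item -> exact Fraction in [0, 1].

    Raises
    ------
    ValueError
        If the table has zero rows (support undefined) or non-binary cells.
    """
    n = len(transactions)
    if n == 0:
        raise ValueError("support undefined: incidence table has zero transactions")
    if not transactions.isin([0, 1]).all().all():
        raise ValueError("incidence table cells must be 0 or 1")
    return {
        str(item): Fraction(int(transactions[item].sum()), n)
        for item in transactions.columns
    }


@dataclass(frozen=True)
class CCMSummary:
    """Mined preference summary of a child's pooled CCM records.

    Holds the HI/LI record counts and total dwell durations; supports are
    derived as exact fractions of the record count.
    """

    count_hi: int
    count_li: int
    total_hi_duration_s: int
    total_li_duration_s: int

    def __post_init__(self) -> None:
        if min(self.count_hi, self.count_li) < 0:
            raise ValueError("counts must be non-negative")
        if min(self.total_hi_duration_s, self.total_li_duration_s) < 0:
            raise ValueError("durations must be non-negative")
        if self.n_records == 0:
            raise ValueError("summary needs at least one record")

    @property
    def n_records(self) -> int:
        return self.count_hi + self.count_li

    @property
    def support_hi(self) -> Fraction:
        return Fraction(self.count_hi, self.n_records)

    @property
    def support_li(self) -> Fraction:
        return Fraction(self.count_li, self.n_records)

    def to_dict(self) -> dict:
        return {
            "support_hi": float(self.support_hi),
            "support_li": float(self.support_li),
            "total_hi_duration_s": self.total_hi_duration_s,
            "total_li_duration_s": self.total_li_duration_s,
            "n_records": self.n_records,
        }


@dataclass(frozen=True)
class SCMSummary:
    """Mined (illumination, response) pair supports of pooled SCM records."""

    count_hi_p: int
    count_hi_n: int
    count_li_p: int
    count_li_n: int

    def __post_init__(self) -> None:
        if min(self.count_hi_p, self.count_hi_n, self.count_li_p, self.count_li_n) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_records == 0:
            raise ValueError("summary needs at least one record")

    @property
    def n_records(self) -> int:
        return self.count_hi_p + self.count_hi_n + self.count_li_p + self.count_li_n

    @property
    def support_hi_p(self) -> Fraction:
        return Fraction(self.count_hi_p, self.n_records)

    @property
    def support_hi_n(self) -> Fraction:
        return Fraction(self.count_hi_n, self.n_records)

    @property
    def support_li_p(self) -> Fraction:
        return Fraction(self.count_li_p, self.n_records)

    @property
    def support_li_n(self) -> Fraction:
        return Fraction(self.count_li_n, self.n_records)

    def to_dict(self) -> dict:
        return {
            "support_hi_p": float(self.support_hi_p),
            "support_hi_n": float(self.support_hi_n),
            "support_li_p": float(self.support_li_p),
            "support_li_n": float(self.support_li_n),
            "n_records": self.n_records,
        }


def _ccm_records(source: Union[ChildLog, Iterable[CCMRecord]]) -> list[CCMRecord]:
    if isinstance(source, ChildLog):
        if Mode(source.mode) is not Mode.CCM:
            raise ValueError("expected a CCM log")
        return list(source.records)
    return list(source)


def _scm_records(source: Union[ChildLog, Iterable[SCMRecord]]) -> list[SCMRecord]:
    if isinstance(source, ChildLog):
        if Mode(source.mode) is not Mode.SCM:
            raise ValueError("expected an SCM log")
        return list(source.records)
    return list(source)


def ccm_summary(log: Union[ChildLog, Iterable[CCMRecord]]) -> CCMSummary:
    """Count HI/LI selections and sum dwell durations over all sessions.

    Sessions are pooled (concatenated) before counting, so one summary — and
    hence one classification — is produced per child.

    Raises
    ------
    ValueError
        If the log holds no records.
    """
    records = _ccm_records(log)
    if not records:
        raise ValueError("cannot summarize an empty CCM log")
    count_hi = count_li = dur_hi = dur_li = 0
    for rec in records:
        if rec.illumination is Illumination.HIGH:
            count_hi += 1
            dur_hi += rec.duration_s
        else:
            count_li += 1
            dur_li += rec.duration_s
    return CCMSummary(count_hi, count_li, dur_hi, dur_li)


def scm_summary(log: Union[ChildLog, Iterable[SCMRecord]]) -> SCMSummary:
    """Count the four (illumination, response) combinations over all sessions.

    Raises
    ------
    ValueError
        If the log holds no records.
    """
    records = _scm_records(log)
    if not records:
        raise ValueError("cannot summarize an empty SCM log")
    counts = {(i, v): 0 for i in Illumination for v in Valence}
    for rec in records:
        counts[(rec.illumination, rec.response)] += 1
    return SCMSummary(
        count_hi_p=counts[(Illumination.HIGH, Valence.POSITIVE)],
        count_hi_n=counts[(Illumination.HIGH, Valence.NEGATIVE)],
        count_li_p=counts[(Illumination.LOW, Valence.POSITIVE)],
        count_li_n=counts[(Illumination.LOW, Valence.NEGATIVE)],
    )


def ccm_session_summaries(log: ChildLog) -> list[CCMSummary]:
    """Per-session CCM summaries, for diagnostics; empty sessions are skipped."""
    return [ccm_summary(list(s)) for s in log.sessions if s]


def scm_session_summaries(log: ChildLog) -> list[SCMSummary]:
    """Per-session SCM summaries, for diagnostics; empty sessions are skipped."""
    return [scm_summary(list(s)) for s in log.sessions if s]


def ccm_incidence(log: Union[ChildLog, Iterable[CCMRecord]]) -> pd.DataFrame:
    """Binary incidence table of a CCM log: one row per record.

    Columns are the two illumination classes (HI, LI) and the five color
    codes, so :func:`item_supports` reproduces the summary supports and adds
    descriptive per-color supports (colors do not enter classification).
    """
    records = _ccm_records(log)
    rows = [
        {
            "HI": int(r.illumination is Illumination.HIGH),
            "LI": int(r.illumination is Illumination.LOW),
            "R": int(r.color.value == "R"),
            "G": int(r.color.value == "G"),
            "B": int(r.color.value == "B"),
            "Y": int(r.color.value == "Y"),
            "W": int(r.color.value == "W"),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["HI", "LI", "R", "G", "B", "Y", "W"])


def scm_incidence(log: Union[ChildLog, Iterable[SCMRecord]]) -> pd.DataFrame:
    """Binary incidence table of an SCM log.

    Single items (illumination classes, colors, responses) plus the four
    (illumination, response) pair items HI_P, HI_N, LI_P, LI_N, so
    :func:`item_supports` reproduces the pair supports of
    :func:`scm_summary`.
    """
    records = _scm_records(log)
    rows = []
    for r in records:
        hi = r.illumination is Illumination.HIGH
        pos = r.response is Valence.POSITIVE
        rows.append(
            {
                "HI": int(hi),
                "LI": int(not hi),
                "R": int(r.color.value == "R"),
                "G": int(r.color.value == "G"),
                "B": int(r.color.value == "B"),
                "Y": int(r.color.value == "Y"),
                "W": int(r.color.value == "W"),
                "P": int(pos),
                "N": int(not pos),
                "HI_P": int(hi and pos),
                "HI_N": int(hi and not pos),
                "LI_P": int(not hi and pos),
                "LI_N": int(not hi and not pos),
            }
        )
    cols = ["HI", "LI", "R", "G", "B", "Y", "W", "P", "N", "HI_P", "HI_N", "LI_P", "LI_N"]
    return pd.DataFrame(rows, columns=cols)
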