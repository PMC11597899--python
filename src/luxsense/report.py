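"""Per-child classification reports and practitioner-agreement audits.

The two report tables mirror the layout clinicians see on the assessment
console: one CCM row per child (HI/LI selection supports as percentages,
total dwell seconds, label) and one SCM row per child (the four
illumination x response supports as percentages, label).  Percentages are
computed on exact rational supports and rendered to one decimal place only
when writing CSV/text; agreement audits compare normalized labels, never
rounded renderings.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Tuple, Union

import pandas as pd

from .classify import (
    DEFAULT_THRESHOLD,
    SensitivityLabel,
    classify_ccm,
    classify_scm,
    normalize_label,
)
from .mining import CCMSummary, SCMSummary

__all__ = [
    "CCM_REPORT_COLUMNS",
    "SCM_REPORT_COLUMNS",
    "AgreementAudit",
    "Mismatch",
    "make_ccm_report",
    "make_scm_report",
    "agreement_audit",
    "format_report_text",
    "write_report_csv",
    "read_labels_csv",
    "write_labels_csv",
]

CCM_REPORT_COLUMNS = ["child_id", "hi_s_pct", "li_s_pct", "hi_d_s", "li_d_s", "classification"]
SCM_REPORT_COLUMNS = [
    "child_id",
    "li_prs_pct",
    "li_nrs_pct",
    "hi_prs_pct",
    "hi_nrs_pct",
    "classification",
]


def _check_unique(ids: list[str]) -> None:
    seen: set[str] = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise ValueError(f"duplicate child_id(s): {dups}")


def make_ccm_report(
    cohort: Iterable[Tuple[str, CCMSummary]], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """One CCM report row per child, sorted by child_id.

    Columns: ``child_id, hi_s_pct, li_s_pct, hi_d_s, li_d_s, classification``.

    Raises
    ------
    ValueError
        On duplicate child ids.
    """
    cohort = list(cohort)
    _check_unique([cid for cid, _ in cohort])
    rows = []
    for child_id, summary in sorted(cohort, key=lambda kv: kv[0]):
        detail = classify_ccm(summary, threshold=threshold)
        rows.append(
            {
                "child_id": child_id,
                "hi_s_pct": float(summary.support_hi * 100),
                "li_s_pct": float(summary.support_li * 100),
                "hi_d_s": summary.total_hi_duration_s,
                "li_d_s": summary.total_li_duration_s,
                "classification": detail.label.display,
            }
        )
    return pd.DataFrame(rows, columns=CCM_REPORT_COLUMNS)


def make_scm_report(
    cohort: Iterable[Tuple[str, SCMSummary]], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """One SCM report row per child, sorted by child_id.

    Columns: ``child_id, li_prs_pct, li_nrs_pct, hi_prs_pct, hi_nrs_pct,
    classification``.
    """
    cohort = list(cohort)
    _check_unique([cid for cid, _ in cohort])
    rows = []
    for child_id, summary in sorted(cohort, key=lambda kv: kv[0]):
        detail = classify_scm(summary, threshold=threshold)
        rows.append(
            {
                "child_id": child_id,
                "li_prs_pct": float(summary.support_li_p * 100),
                "li_nrs_pct": float(summary.support_li_n * 100),
                "hi_prs_pct": float(summary.support_hi_p * 100),
                "hi_nrs_pct": float(summary.support_hi_n * 100),
                "classification": detail.label.display,
            }
        )
    return pd.DataFrame(rows, columns=SCM_REPORT_COLUMNS)


@dataclass(frozen=True)
class Mismatch:
    child_id: str
    practitioner: str
    system: str


@dataclass(frozen=True)
class AgreementAudit:
    """Outcome of comparing system labels against practitioner labels."""

    n_children: int
    n_agree: int
    mismatches: tuple[Mismatch, ...] = field(default_factory=tuple)

    @property
    def agreement_pct(self) -> float:
        return self.n_agree / self.n_children * 100

    def to_dict(self) -> dict:
        return {
            "n_children": self.n_children,
            "n_agree": self.n_agree,
            "agreement_pct": self.agreement_pct,
            "mismatches": [
                {"child_id": m.child_id, "practitioner": m.practitioner, "system": m.system}
                for m in self.mismatches
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


LabelLike = Union[SensitivityLabel, str]


def agreement_audit(
    system_labels: Mapping[str, LabelLike], practitioner_labels: Mapping[str, LabelLike]
) -> AgreementAudit:
    """Compare per-child system labels with practitioner labels.

    Labels are compared after normalization (case-, hyphen- and
    whitespace-insensitive).  Mismatches are listed in child_id order with
    the labels as given, practitioner first.

    Raises
    ------
    ValueError
        If the two mappings do not cover the same children, naming the ids
        missing on each side.
    """
    sys_ids, prac_ids = set(system_labels), set(practitioner_labels)
    if sys_ids != prac_ids:
        parts = []
        if prac_ids - sys_ids:
            parts.append(f"missing from system labels: {sorted(prac_ids - sys_ids)}")
        if sys_ids - prac_ids:
            parts.append(f"missing from practitioner labels: {sorted(sys_ids - prac_ids)}")
        raise ValueError("child id sets differ; " + "; ".join(parts))
    if not sys_ids:
        raise ValueError("no children to audit")
    mismatches = []
    n_agree = 0
    for child_id in sorted(sys_ids):
        sys_label = system_labels[child_id]
        prac_label = practitioner_labels[child_id]
        if normalize_label(sys_label) == normalize_label(prac_label):
            n_agree += 1
        else:
            mismatches.append(Mismatch(child_id, str(prac_label), str(sys_label)))
    return AgreementAudit(
        n_children=len(sys_ids), n_agree=n_agree, mismatches=tuple(mismatches)
    )


def format_report_text(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering with percentages to one decimal place."""
    return report.to_string(index=False, float_format=lambda v: f"{v:.1f}")


def write_report_csv(report: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a report table as CSV, percentages to one decimal place."""
    report.to_csv(path, index=False, float_format="%.1f")


def read_labels_csv(path: Union[str, Path]) -> dict[str, str]:
    """Read a ``child_id,label`` CSV into an id -> label mapping.

    Labels are returned as written (audits normalize on comparison).
    """
    labels: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"child_id", "label"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns child_id,label")
        for row in reader:
            cid = row["child_id"].strip()
            if cid in labels:
                raise ValueError(f"{path}: duplicate child_id {cid!r}")
            normalize_label(row["label"])  # validate early
            labels[cid] = row["label"].strip()
    if not labels:
        raise ValueError(f"{path}: no label rows")
    return labels


def write_labels_csv(labels: Mapping[str, LabelLike], path: Union[str, Path]) -> None:
    """Write an id -> label mapping as a ``child_id,label`` CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["child_id", "label"])
        for cid in sorted(labels):
            label = labels[cid]
            writer.writerow([cid, normalize_label(label).display])
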