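"""Bundled reference data: the 20-child evaluation cohort label tables.

The package ships the published field-evaluation classification tables —
practitioner assessment, child-control-mode (CCM) system output, and
system-control-mode (SCM) system output for twenty children — as
``child_id,label`` CSVs with their original mixed casing preserved.  These
are the only real (non-synthetic) data in the package; the raw interaction
logs behind them were never deposited, so the tables are the reproducible
surface for agreement audits.
"""

from __future__ import annotations

import csv
from importlib import resources

__all__ = [
    "load_practitioner_labels",
    "load_ccm_labels",
    "load_scm_labels",
    "evaluation_cohort_composition",
]


def _load(name: str) -> dict[str, str]:
    ref = resources.files("luxsense.data").joinpath(name)
    with ref.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        return {row["child_id"]: row["label"] for row in reader}


def load_practitioner_labels() -> dict[str, str]:
    """Practitioner sensitivity labels for the evaluation cohort (n=20)."""
    return _load("evaluation_practitioner_labels.csv")


def load_ccm_labels() -> dict[str, str]:
    """CCM pipeline labels for the evaluation cohort (n=20)."""
    return _load("evaluation_ccm_labels.csv")


def load_scm_labels() -> dict[str, str]:
    """SCM pipeline labels for the evaluation cohort (n=20)."""
    return _load("evaluation_scm_labels.csv")


def evaluation_cohort_composition() -> dict[str, int]:
    """Practitioner label counts of the evaluation cohort (9/5/6)."""
    from .classify import normalize_label

    counts: dict[str, int] = {}
    for label in load_practitioner_labels().values():
        key = normalize_label(label).value
        counts[key] = counts.get(key, 0) + 1
    return counts
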