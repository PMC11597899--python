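"""Synthetic session generator standing in for the physical device.

No interaction logs from the field study were deposited, so this module
emulates the assessment protocol end-to-end: five colors, nine illumination
levels binarized at 100 lux, 180-second sessions, three sessions per mode
per child, system-mode stimuli changing every 5 s.  Child behavior is
parameterized by a :class:`ChildProfile` whose probabilities encode the
qualitative premises behind the classification rules — hypo-sensitive
children seek bright stimuli and dwell on them longer, hyper-sensitive
children avoid them and respond negatively, normal children are balanced.

Everything is deterministic given a seed: per-child random streams are
derived from the master seed and a stable hash of the child id, so cohorts
are reproducible and independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from math import floor
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .classify import (
    DEFAULT_THRESHOLD,
    SensitivityLabel,
    classify_ccm,
    classify_scm,
    normalize_label,
)
from .mining import ccm_summary, scm_summary
from .records import (
    CCMRecord,
    ChildLog,
    Color,
    Illumination,
    Mode,
    SCMRecord,
    Valence,
    binarize_illumination,
)
from .report import agreement_audit

__all__ = [
    "ChildProfile",
    "ProtocolConfig",
    "RecoveryReport",
    "DEFAULT_LEVEL_LUX",
    "DEFAULT_CLASS_MIX",
    "default_profiles",
    "scale_contrast",
    "simulate_ccm",
    "simulate_scm",
    "simulate_cohort",
    "recovery_experiment",
    "protocol_from_dict",
    "profiles_from_dict",
]

#: Illuminance (lux at 1 m) assigned to the nine device levels.  The exact
#: per-level photometry is hardware-dependent; the defaults place L1-L4 below
#: the 100-lux LI/HI boundary and L5-L9 above it, and are configurable.
DEFAULT_LEVEL_LUX: dict[str, float] = {
    "L1": 20.0,
    "L2": 40.0,
    "L3": 60.0,
    "L4": 80.0,
    "L5": 110.0,
    "L6": 140.0,
    "L7": 180.0,
    "L8": 230.0,
    "L9": 290.0,
}

#: Class mix of the field-evaluation cohort (9 hypo, 5 hyper, 6 normal of 20).
DEFAULT_CLASS_MIX: dict[SensitivityLabel, float] = {
    SensitivityLabel.HYPO: 9 / 20,
    SensitivityLabel.HYPER: 5 / 20,
    SensitivityLabel.NORMAL: 6 / 20,
}

_LEVEL_NAMES = tuple(f"L{i}" for i in range(1, 10))


@dataclass(frozen=True)
class ProtocolConfig:
    """Session protocol parameters of the assessment device."""

    session_length_s: int = 180
    n_sessions_per_mode: int = 3
    scm_interval_s: int = 5
    colors: Tuple[Color, ...] = tuple(Color)
    level_lux_at_1m: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_LUX)
    )

    def __post_init__(self) -> None:
        if self.session_length_s < 1 or self.n_sessions_per_mode < 1:
            raise ValueError("session length and session count must be positive")
        if self.scm_interval_s < 1 or self.session_length_s % self.scm_interval_s:
            raise ValueError(
                "session_length_s must be a positive multiple of scm_interval_s"
            )
        if set(self.level_lux_at_1m) != set(_LEVEL_NAMES):
            raise ValueError(f"level_lux_at_1m must cover exactly {list(_LEVEL_NAMES)}")
        if not self.colors:
            raise ValueError("at least one color is required")

    def levels_of(self, cls: Illumination) -> tuple[str, ...]:
        """Device levels whose 1-m illuminance binarizes to ``cls``."""
        return tuple(
            name
            for name in _LEVEL_NAMES
            if binarize_illumination(self.level_lux_at_1m[name]) is cls
        )

    @property
    def scm_records_per_session(self) -> int:
        return self.session_length_s // self.scm_interval_s


@dataclass(frozen=True)
class ChildProfile:
    """Behavioral parameterization of one simulated child.

    ``p_hi_select`` is the probability that a child-mode selection is a
    high-illumination stimulus; ``dwell_*_mean_s`` are mean dwell times per
    selection; ``p_pos_given_*`` are probabilities of a positive emotional
    response to HI/LI stimuli in system mode.
    """

    child_id: str
    true_class: SensitivityLabel
    p_hi_select: float
    dwell_hi_mean_s: float
    dwell_li_mean_s: float
    p_pos_given_hi: float
    p_pos_given_li: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_hi_select", "p_pos_given_hi", "p_pos_given_li"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if min(self.dwell_hi_mean_s, self.dwell_li_mean_s) < 1:
            raise ValueError("dwell means must be >= 1 second")


def default_profiles() -> dict[SensitivityLabel, ChildProfile]:
    """Per-class profile templates with strong behavioral contrast.

    The hypo template concentrates selections, dwell and positive responses
    on high illumination; the hyper template is its exact HI<->LI mirror;
    the normal template is balanced (expected percentage differences of 0).
    """
    hypo = ChildProfile(
        child_id="",
        true_class=SensitivityLabel.HYPO,
        p_hi_select=0.85,
        dwell_hi_mean_s=25.0,
        dwell_li_mean_s=10.0,
        p_pos_given_hi=0.8,
        p_pos_given_li=0.2,
    )
    hyper = ChildProfile(
        child_id="",
        true_class=SensitivityLabel.HYPER,
        p_hi_select=0.15,
        dwell_hi_mean_s=10.0,
        dwell_li_mean_s=25.0,
        p_pos_given_hi=0.2,
        p_pos_given_li=0.8,
    )
    normal = ChildProfile(
        child_id="",
        true_class=SensitivityLabel.NORMAL,
        p_hi_select=0.5,
        dwell_hi_mean_s=15.0,
        dwell_li_mean_s=15.0,
        p_pos_given_hi=0.5,
        p_pos_given_li=0.5,
    )
    return {p.true_class: p for p in (hypo, hyper, normal)}


_BALANCED = dict(
    p_hi_select=0.5,
    dwell_hi_mean_s=15.0,
    dwell_li_mean_s=15.0,
    p_pos_given_hi=0.5,
    p_pos_given_li=0.5,
)


def scale_contrast(profile: ChildProfile, contrast: float) -> ChildProfile:
    """Interpolate a profile toward perfectly balanced behavior.

    ``contrast=1`` returns the profile unchanged; ``contrast=0`` collapses
    every parameter onto the balanced (normal) template.  Used to study how
    classification accuracy degrades as behavioral signal shrinks.
    """
    if not 0 <= contrast <= 1:
        raise ValueError(f"contrast must be in [0, 1], got {contrast}")
    updates = {
        name: base + contrast * (getattr(profile, name) - base)
        for name, base in _BALANCED.items()
    }
    return replace(profile, **updates)


def _rng(profile: ChildProfile, mode: Mode) -> np.random.Generator:
    # stable per-child, per-mode stream: master seed + CRC of the id + mode tag
    tag = 1 if mode is Mode.CCM else 2
    entropy = [int(profile.seed), zlib.crc32(profile.child_id.encode("utf-8")), tag]
    return np.random.default_rng(np.random.SeedSequence(entropy))


_CCM_BASE = datetime(2024, 7, 23, 10, 0, 0)
_SCM_BASE = datetime(2024, 7, 23, 14, 0, 0)


def simulate_ccm(profile: ChildProfile, config: Optional[ProtocolConfig] = None) -> ChildLog:
    """Generate a child-control-mode log.

    Each session is filled end-to-end with selections: illumination class is
    Bernoulli(``p_hi_select``), color uniform, dwell geometric on whole
    seconds with the class's mean, truncated at the session boundary so the
    per-session dwell total never exceeds the session length.
    """
    config = config or ProtocolConfig()
    rng = _rng(profile, Mode.CCM)
    colors = tuple(config.colors)
    sessions = []
    for s in range(config.n_sessions_per_mode):
        t = _CCM_BASE + timedelta(hours=s)
        remaining = config.session_length_s
        session = []
        while remaining > 0:
            hi = rng.random() < profile.p_hi_select
            mean = profile.dwell_hi_mean_s if hi else profile.dwell_li_mean_s
            dwell = int(rng.geometric(1.0 / mean))
            dwell = min(dwell, remaining)
            session.append(
                CCMRecord(
                    timestamp=t,
                    color=colors[int(rng.integers(len(colors)))],
                    illumination=Illumination.HIGH if hi else Illumination.LOW,
                    duration_s=dwell,
                )
            )
            t += timedelta(seconds=dwell)
            remaining -= dwell
        sessions.append(tuple(session))
    return ChildLog(child_id=profile.child_id, mode=Mode.CCM, sessions=tuple(sessions))


def simulate_scm(profile: ChildProfile, config: Optional[ProtocolConfig] = None) -> ChildLog:
    """Generate a system-control-mode log.

    Stimuli change at fixed intervals; each session emits exactly
    ``session_length_s / scm_interval_s`` records (36 under the default
    protocol).  The schedule alternates deterministically between the LI and
    HI level sub-grids, cycling levels-then-colors within each, so HI and LI
    exposure counts are exactly balanced.  The response to each stimulus is
    Bernoulli(``p_pos_given_hi`` or ``p_pos_given_li``) mapped to P/N.
    """
    config = config or ProtocolConfig()
    rng = _rng(profile, Mode.SCM)
    colors = tuple(config.colors)
    li_levels = config.levels_of(Illumination.LOW)
    hi_levels = config.levels_of(Illumination.HIGH)
    if not li_levels or not hi_levels:
        raise ValueError("level_lux_at_1m must provide both LI and HI levels")
    counters = {Illumination.LOW: 0, Illumination.HIGH: 0}
    sessions = []
    step = 0
    for s in range(config.n_sessions_per_mode):
        start = _SCM_BASE + timedelta(hours=s)
        session = []
        for i in range(config.scm_records_per_session):
            cls = Illumination.LOW if step % 2 == 0 else Illumination.HIGH
            levels = li_levels if cls is Illumination.LOW else hi_levels
            k = counters[cls]
            counters[cls] += 1
            # level cycles fastest, color advances once per full level cycle
            _level = levels[k % len(levels)]  # logged only as its LI/HI class
            color = colors[(k // len(levels)) % len(colors)]
            p_pos = (
                profile.p_pos_given_hi
                if cls is Illumination.HIGH
                else profile.p_pos_given_li
            )
            response = Valence.POSITIVE if rng.random() < p_pos else Valence.NEGATIVE
            session.append(
                SCMRecord(
                    timestamp=start + timedelta(seconds=i * config.scm_interval_s),
                    color=color,
                    illumination=cls,
                    response=response,
                )
            )
            step += 1
        sessions.append(tuple(session))
    return ChildLog(child_id=profile.child_id, mode=Mode.SCM, sessions=tuple(sessions))


def _mix_counts(
    n_children: int, class_mix: Mapping[SensitivityLabel, float]
) -> list[tuple[SensitivityLabel, int]]:
    order = [SensitivityLabel.HYPO, SensitivityLabel.HYPER, SensitivityLabel.NORMAL]
    mix = {normalize_label(k): float(v) for k, v in class_mix.items()}
    unknown = set(mix) - set(order)
    if unknown:
        raise ValueError(f"unknown labels in class mix: {sorted(l.value for l in unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class mix proportions must sum to 1, got {total}")
    quotas = [(label, n_children * mix.get(label, 0.0)) for label in order]
    counts = {label: floor(q) for label, q in quotas}
    leftover = n_children - sum(counts.values())
    by_frac = sorted(quotas, key=lambda lq: (-(lq[1] - floor(lq[1])), order.index(lq[0])))
    for label, _ in by_frac[:leftover]:
        counts[label] += 1
    return [(label, counts[label]) for label in order]


def simulate_cohort(
    n_children: int,
    class_mix: Optional[Mapping[SensitivityLabel, float]] = None,
    config: Optional[ProtocolConfig] = None,
    seed: int = 0,
    contrast: float = 1.0,
    profiles: Optional[Mapping[SensitivityLabel, ChildProfile]] = None,
) -> tuple[dict[str, tuple[ChildLog, ChildLog]], dict[str, SensitivityLabel]]:
    """Simulate paired CCM+SCM logs for a cohort of children.

    Children get zero-padded ids ("001", "002", ...).  True classes are
    assigned deterministically from ``class_mix`` (largest-remainder
    apportionment; default: the field cohort's 9:5:6 hypo:hyper:normal).

    Returns ``(logs, truth)`` where ``logs[child_id] = (ccm_log, scm_log)``
    and ``truth[child_id]`` is the child's true sensitivity class.
    """
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    config = config or ProtocolConfig()
    templates = dict(profiles or default_profiles())
    label_seq: list[SensitivityLabel] = []
    for label, count in _mix_counts(n_children, class_mix or DEFAULT_CLASS_MIX):
        label_seq.extend([label] * count)
    logs: dict[str, tuple[ChildLog, ChildLog]] = {}
    truth: dict[str, SensitivityLabel] = {}
    for i, label in enumerate(label_seq, start=1):
        child_id = f"{i:03d}"
        profile = replace(templates[label], child_id=child_id, seed=seed)
        profile = scale_contrast(profile, contrast)
        logs[child_id] = (simulate_ccm(profile, config), simulate_scm(profile, config))
        truth[child_id] = label
    return logs, truth


@dataclass(frozen=True)
class RecoveryReport:
    """Classification accuracy on simulated cohorts with known truth."""

    n_children: int
    n_replicates: int
    contrast: float
    ccm_accuracy_pct: tuple[float, ...]
    scm_accuracy_pct: tuple[float, ...]

    @property
    def mean_ccm_accuracy_pct(self) -> float:
        return float(np.mean(self.ccm_accuracy_pct))

    @property
    def mean_scm_accuracy_pct(self) -> float:
        return float(np.mean(self.scm_accuracy_pct))

    @property
    def sd_ccm_accuracy_pct(self) -> float:
        return float(np.std(self.ccm_accuracy_pct, ddof=1)) if self.n_replicates > 1 else 0.0

    @property
    def sd_scm_accuracy_pct(self) -> float:
        return float(np.std(self.scm_accuracy_pct, ddof=1)) if self.n_replicates > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "n_children": self.n_children,
            "n_replicates": self.n_replicates,
            "contrast": self.contrast,
            "mean_ccm_accuracy_pct": self.mean_ccm_accuracy_pct,
            "mean_scm_accuracy_pct": self.mean_scm_accuracy_pct,
            "sd_ccm_accuracy_pct": self.sd_ccm_accuracy_pct,
            "sd_scm_accuracy_pct": self.sd_scm_accuracy_pct,
            "ccm_accuracy_pct": list(self.ccm_accuracy_pct),
            "scm_accuracy_pct": list(self.scm_accuracy_pct),
        }


def recovery_experiment(
    n_children: int = 20,
    class_mix: Optional[Mapping[SensitivityLabel, float]] = None,
    config: Optional[ProtocolConfig] = None,
    n_replicates: int = 50,
    seed: int = 0,
    contrast: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
    profiles: Optional[Mapping[SensitivityLabel, ChildProfile]] = None,
) -> RecoveryReport:
    """Measure how well the pipeline recovers true classes from simulations.

    Per replicate: simulate a cohort, mine both modes, classify, and audit
    the system labels against the known truth.  Reports per-replicate and
    mean CCM/SCM accuracy (agreement with truth, percent).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rep_seeds = np.random.default_rng(seed).integers(2**31, size=n_replicates)
    ccm_acc, scm_acc = [], []
    for rep_seed in rep_seeds:
        logs, truth = simulate_cohort(
            n_children,
            class_mix=class_mix,
            config=config,
            seed=int(rep_seed),
            contrast=contrast,
            profiles=profiles,
        )
        ccm_labels = {
            cid: classify_ccm(ccm_summary(ccm), threshold=threshold).label
            for cid, (ccm, _) in logs.items()
        }
        scm_labels = {
            cid: classify_scm(scm_summary(scm), threshold=threshold).label
            for cid, (_, scm) in logs.items()
        }
        ccm_acc.append(agreement_audit(ccm_labels, truth).agreement_pct)
        scm_acc.append(agreement_audit(scm_labels, truth).agreement_pct)
    return RecoveryReport(
        n_children=n_children,
        n_replicates=n_replicates,
        contrast=contrast,
        ccm_accuracy_pct=tuple(ccm_acc),
        scm_accuracy_pct=tuple(scm_acc),
    )


def protocol_from_dict(data: Mapping) -> ProtocolConfig:
    """Build a :class:`ProtocolConfig` from a plain mapping (YAML-friendly)."""
    kwargs = dict(data)
    if "colors" in kwargs:
        kwargs["colors"] = tuple(Color(c) for c in kwargs["colors"])
    if "level_lux_at_1m" in kwargs:
        kwargs["level_lux_at_1m"] = {
            str(k): float(v) for k, v in kwargs["level_lux_at_1m"].items()
        }
    return ProtocolConfig(**kwargs)


def profiles_from_dict(data: Mapping) -> dict[SensitivityLabel, ChildProfile]:
    """Merge per-class profile overrides into the default templates.

    ``data`` maps class names ("hypo-sensitive", ...) to field overrides,
    e.g. ``{"hypo-sensitive": {"p_hi_select": 0.9}}``.
    """
    templates = default_profiles()
    for key, overrides in data.items():
        label = normalize_label(key)
        templates[label] = replace(templates[label], **dict(overrides))
    return templates
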