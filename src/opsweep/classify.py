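"""Skeletal classification: sagittal by ANB bands, vertical by a 2-of-3 quorum.

Sagittal: Class I for 1 <= ANB <= 5 degrees (boundaries inclusive, as
printed), Class II above, Class III below.

Vertical: each growth pattern is defined by a criterion triple over SN-MP,
FH-MP (FMA) and FHR, and a patient belongs to the pattern whose criteria
they meet at least ``quorum`` (default 2) times:

=============  ==========  ==========  ===========
pattern        SN-MP       FH-MP       FHR
=============  ==========  ==========  ===========
hypodivergent  < 24        < 22        > 65
normodivergent 24..36      22..30      62..65
hyperdivergent > 36        > 30        < 62
=============  ==========  ==========  ===========

The FHR bands are oriented so that a short (hypodivergent) face has the
*higher* posterior/anterior ratio, consistent with the reference cohort's
per-pattern FHR means (~70 / ~64.5 / ~60) and the normative 62-65% band of
the normodivergent pattern.

Ties at quorum (possible only on band boundaries) prefer normodivergent,
then the pattern containing the SN-MP value.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tables
from .data import Cohort, SkeletalClass
from .exceptions import ValidationError

__all__ = [
    "ClassificationRuleSet", "classify_sagittal", "classify_vertical",
    "classify_record", "classify_cohort", "DEFAULT_RULES",
]


@dataclass(frozen=True)
class ClassificationRuleSet:
    """Threshold set for the 3x3 classification; YAML-serializable."""

    anb_class_i: tuple[float, float] = (1.0, 5.0)  # inclusive band
    sn_mp_nor: tuple[float, float] = (24.0, 36.0)  # inclusive band
    fh_mp_nor: tuple[float, float] = (22.0, 30.0)  # inclusive band
    fhr_nor: tuple[float, float] = (62.0, 65.0)    # inclusive band
    quorum: int = 2

    def __post_init__(self):
        for name in ("anb_class_i", "sn_mp_nor", "fh_mp_nor", "fhr_nor"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"band {name} must satisfy lo < hi")
        if self.quorum not in (2, 3):
            raise ValidationError("quorum must be 2 or 3")

    # -- per-indicator band membership (bands partition the real line) -----
    def sn_mp_band(self, v: float) -> str:
        lo, hi = self.sn_mp_nor
        return "hypo" if v < lo else ("nor" if v <= hi else "hyper")

    def fh_mp_band(self, v: float) -> str:
        lo, hi = self.fh_mp_nor
        return "hypo" if v < lo else ("nor" if v <= hi else "hyper")

    def fhr_band(self, v: float) -> str:
        lo, hi = self.fhr_nor
        # inverted orientation: high FHR = short face = hypodivergent
        return "hyper" if v < lo else ("nor" if v <= hi else "hypo")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassificationRuleSet":
        d = yaml.safe_load(Path(path).read_text())
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**d)


DEFAULT_RULES = ClassificationRuleSet()


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not np.isfinite(v):
            raise ValidationError(f"{name} must be finite, got {v!r}")


def classify_sagittal(anb: float,
                      rules: ClassificationRuleSet = DEFAULT_RULES) -> str:
    """Class I/II/III from the ANB angle (total function of finite input)."""
    _require_finite(ANB=anb)
    lo, hi = rules.anb_class_i
    if anb < lo:
        return "III"
    if anb > hi:
        return "II"
    return "I"


def classify_vertical(sn_mp: float, fh_mp: float, fhr: float,
                      rules: ClassificationRuleSet = DEFAULT_RULES) -> str:
    """Vertical pattern by quorum counting; 'unclassified' if no quorum."""
    _require_finite(SN_MP=sn_mp, FH_MP=fh_mp, FHR=fhr)
    counts = {v: 0 for v in tables.VERTICAL}
    counts[rules.sn_mp_band(sn_mp)] += 1
    counts[rules.fh_mp_band(fh_mp)] += 1
    counts[rules.fhr_band(fhr)] += 1
    winners = [v for v in tables.VERTICAL if counts[v] >= rules.quorum]
    if not winners:
        return "unclassified"
    if len(winners) == 1:
        return winners[0]
    # boundary tie: prefer normodivergent, else the SN-MP band
    if "nor" in winners:
        return "nor"
    sn_band = rules.sn_mp_band(sn_mp)
    return sn_band if sn_band in winners else winners[0]


def classify_record(record, rules: ClassificationRuleSet = DEFAULT_RULES) -> SkeletalClass:
    return SkeletalClass(
        classify_sagittal(record.ANB, rules),
        classify_vertical(record.SN_MP, record.FH_MP, record.FHR, rules),
    )


def classify_cohort(cohort: Cohort,
                    rules: ClassificationRuleSet = DEFAULT_RULES) -> dict:
    """Label every record; returns labels, a contingency table and, when
    generator truth labels are present, the agreement rate."""
    labels = [classify_record(r, rules) for r in cohort]
    verticals = list(tables.VERTICAL) + ["unclassified"]
    table = pd.DataFrame(0, index=list(tables.SAGITTAL), columns=verticals)
    for lab in labels:
        table.loc[lab.sagittal, lab.vertical] += 1
    agreement = None
    if cohort.labels is not None and len(cohort) > 0:
        hits = sum(a.cell == b.cell for a, b in zip(labels, cohort.labels))
        agreement = hits / len(cohort)
    return {"labels": labels, "table": table, "agreement": agreement}
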