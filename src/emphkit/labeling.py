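"""Dual-criterion weak emphysema labeling and cohort utilities.

A scan is labeled emphysema-positive when BOTH hold:

* %LAA-950 >= 6% (inclusive), and
* mean lung attenuation < -850 HU (strict).

The HU constraint guards against high-LAA false positives driven by deep
inspiration or noise: a scan can show substantial low-attenuation area
yet have a mean lung density too high to be plausible emphysema. A
severity flag marks scans at or above the 14% cut-off.

These rules produce *weak* labels for model training — they are
quantitative proxies, not radiologist reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .qct import QCTMarkers


@dataclass
class LabelCriteria:
    """Thresholds of the dual-criterion rule.

    laa_threshold_pct : inclusive %LAA-950 cut-off for positivity.
    mean_hu_threshold : strict upper bound on mean lung HU for positivity.
    severe_threshold_pct : inclusive %LAA-950 cut-off for the severity flag.
    """

    laa_threshold_pct: float = 6.0
    mean_hu_threshold: float = -850.0
    severe_threshold_pct: float = 14.0

    def __post_init__(self) -> None:
        if not 0 < self.laa_threshold_pct < self.severe_threshold_pct <= 100:
            raise ValueError(
                "need 0 < laa_threshold_pct < severe_threshold_pct <= 100"
            )


@dataclass
class ScanLabel:
    """Weak label with its criterion breakdown."""

    patient_id: str
    label: int
    laa_pass: bool
    hu_pass: bool
    severe: bool

    def __post_init__(self) -> None:
        if self.label != int(self.laa_pass and self.hu_pass):
            raise ValueError("label must equal (laa_pass AND hu_pass)")
        if self.severe and not self.laa_pass:
            raise ValueError("severe implies laa_pass")


def assign_label(
    markers: QCTMarkers, criteria: LabelCriteria | None = None
) -> ScanLabel:
    """Apply the dual-criterion rule to one scan's markers."""
    criteria = criteria or LabelCriteria()
    laa_pass = markers.laa950_pct >= criteria.laa_threshold_pct
    hu_pass = markers.mean_hu < criteria.mean_hu_threshold
    return ScanLabel(
        patient_id=markers.patient_id,
        label=int(laa_pass and hu_pass),
        laa_pass=laa_pass,
        hu_pass=hu_pass,
        severe=severity_flag(markers, criteria),
    )


def severity_flag(
    markers: QCTMarkers, criteria: LabelCriteria | None = None
) -> bool:
    """True when %LAA-950 reaches the severe cut-off (inclusive)."""
    criteria = criteria or LabelCriteria()
    return bool(markers.laa950_pct >= criteria.severe_threshold_pct)


def summarize_cohort(markers_list: Sequence[QCTMarkers]) -> pd.Series:
    """Descriptive statistics of %LAA-950 across a cohort.

    Standard deviation uses the n-1 denominator; quartiles use linear
    interpolation (same convention as Perc15). A singleton cohort reports
    sd 0.0 with ``sd_defined`` False.
    """
    if not markers_list:
        raise DegenerateDataError("empty cohort")
    laa = np.array([m.laa950_pct for m in markers_list], dtype=float)
    n = laa.size
    sd_defined = n > 1
    return pd.Series(
        {
            "count": float(n),
            "mean": float(laa.mean()),
            "sd": float(laa.std(ddof=1)) if sd_defined else 0.0,
            "sd_defined": sd_defined,
            "min": float(laa.min()),
            "p25": float(np.percentile(laa, 25)),
            "median": float(np.percentile(laa, 50)),
            "p75": float(np.percentile(laa, 75)),
            "max": float(laa.max()),
        }
    )


def build_balanced_subset(
    labels: Iterable[ScanLabel], seed: int
) -> list[str]:
    """Every positive plus an equal number of randomly chosen negatives.

    The majority (negative) class is downsampled without replacement;
    positives are never resampled. Exploration-only artifact — final
    evaluation always runs on the natural class balance.
    """
    labels = list(labels)
    pos = [l.patient_id for l in labels if l.label == 1]
    neg = [l.patient_id for l in labels if l.label == 0]
    if not pos:
        raise DegenerateDataError("cannot balance: no positives")
    if len(neg) < len(pos):
        raise DegenerateDataError("cannot balance: fewer negatives than positives")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(neg), size=len(pos), replace=False)
    return pos + [neg[i] for i in sorted(chosen)]


def labels_to_frame(labels: Iterable[ScanLabel]) -> pd.DataFrame:
    """Label manifest with the criterion breakdown and severity flag."""
    return pd.DataFrame(
        [
            {
                "patient_id": l.patient_id,
                "label": l.label,
                "laa_pass": l.laa_pass,
                "hu_pass": l.hu_pass,
                "severe": l.severe,
            }
            for l in labels
        ]
    )
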