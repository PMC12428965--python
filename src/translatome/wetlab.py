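"""Closed-form wet-lab calculations: relative electrolyte leakage and
delta-delta-Ct qPCR quantification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import math


@dataclass
class LeakageMeasurement:
    """Conductivities in uS/cm: the tested extract (before or after
    freezing, as labelled by the caller) and the same sample after boiling."""

    conductivity_sample: float
    conductivity_boiled: float

    def __post_init__(self) -> None:
        if self.conductivity_boiled <= 0:
            raise ValueError("boiled-sample conductivity must be positive")
        if self.conductivity_sample < 0:
            raise ValueError("sample conductivity must be nonnegative")


def electrolyte_leakage_percent(m: LeakageMeasurement) -> float:
    """Relative electrolyte leakage: 100 x sample / boiled conductivity."""
    return 100.0 * m.conductivity_sample / m.conductivity_boiled


@dataclass
class QpcrRecord:
    """One qPCR measurement: target Ct plus one Ct per reference gene."""

    target_ct: float
    reference_cts: Mapping[str, float]
    condition: str = ""

    def __post_init__(self) -> None:
        values = [self.target_ct, *self.reference_cts.values()]
        if not all(math.isfinite(v) and v > 0 for v in values):
            raise ValueError("Ct values must be finite and positive")

    @property
    def delta_ct(self) -> float:
        refs = list(self.reference_cts.values())
        return self.target_ct - sum(refs) / len(refs)


def relative_expression_ddct(sample: QpcrRecord, calibrator: QpcrRecord) -> float:
    """Fold change 2^(-ddCt), references combined by mean Ct.

    ddCt = (Ct_target - mean reference Ct)_sample - (same)_calibrator,
    assuming the classical amplification efficiency of 2.
    """
    if set(sample.reference_cts) != set(calibrator.reference_cts):
        raise ValueError("sample and calibrator use different reference genes")
    ddct = sample.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct)
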