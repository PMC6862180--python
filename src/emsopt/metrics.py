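"""Crowding and time performance measures for the emergency department.

The work index EDWIN summarizes instantaneous ED load as acuity-weighted
patient counts per physician per free treatment bed,

    EDWIN = sum_i n_i * t_i / (Na * (Bt - BA)),

where ``n_i`` is the number of patients present at triage level ``i``,
``t_i`` the acuity weight of that level, ``Na`` the physicians on duty,
``Bt`` the registered treatment beds and ``BA`` the admitted patients
boarding in the ED.  Under the Taiwan Triage and Acuity Scale (TTAS)
level 1 is the *most* urgent, so the index is used in the transformed
form EDWIN^C with weights ``t_i = 6 - i``.

A second performance measure is the per-patient system time

    ST = sum_i W_i + sum_j S_j,

total waiting plus service time across all stations visited.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DegenerateDenominatorError, InvalidParameterError

__all__ = [
    "EdStateSnapshot",
    "CrowdingLabel",
    "edwin",
    "edwin_c",
    "classify_crowding",
    "system_time",
    "EDWINC_WEIGHTS",
]

#: TTAS acuity weights 6 - i for triage levels 1..5 (level 1 most urgent).
EDWINC_WEIGHTS: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0, 1.0)


@dataclass(frozen=True)
class EdStateSnapshot:
    """Instantaneous ED census used to evaluate the work index.

    Parameters
    ----------
    counts_n : per-triage patient counts (n1..n5), level 1 most urgent.
    physicians_Na : physicians on duty, >= 1.
    beds_Bt : registered treatment beds (lobby/corridor beds excluded), >= 1.
    admitted_BA : admitted patients boarding in the ED, >= 0.
    """

    counts_n: tuple[int, int, int, int, int]
    physicians_Na: int
    beds_Bt: int
    admitted_BA: int = 0

    def __post_init__(self) -> None:
        if len(self.counts_n) != 5 or any(c < 0 for c in self.counts_n):
            raise InvalidParameterError("counts_n must be five non-negative counts")
        if self.physicians_Na < 1:
            raise InvalidParameterError("physicians_Na must be >= 1")
        if self.beds_Bt < 1:
            raise InvalidParameterError("beds_Bt must be >= 1")
        if self.admitted_BA < 0:
            raise InvalidParameterError("admitted_BA must be >= 0")


class CrowdingLabel(enum.Enum):
    """Qualitative ED state derived from the work index."""

    GOOD = "good"
    BUSY = "busy"
    CROWDED = "crowded"


def edwin(snapshot: EdStateSnapshot, acuity_weights: Sequence[float] = (1, 2, 3, 4, 5)) -> float:
    """Acuity-weighted patients per physician per free bed.

    Raises
    ------
    DegenerateDenominatorError
        If ``Bt - BA <= 0`` (a fully boarded ED leaves no free bed).
    """
    if len(acuity_weights) != 5:
        raise InvalidParameterError("acuity_weights must have five entries")
    free_beds = snapshot.beds_Bt - snapshot.admitted_BA
    if free_beds <= 0:
        raise DegenerateDenominatorError(
            f"Bt - BA = {free_beds} <= 0: no free registered treatment bed"
        )
    num = sum(n * t for n, t in zip(snapshot.counts_n, acuity_weights))
    return num / (snapshot.physicians_Na * free_beds)


def edwin_c(snapshot: EdStateSnapshot) -> float:
    """EDWIN transformed for TTAS ordering: weights ``6 - i`` (level 1 most urgent)."""
    return edwin(snapshot, EDWINC_WEIGHTS)


def classify_crowding(index_value: float) -> CrowdingLabel:
    """Map a work-index value to good (< 1.5), busy ([1.5, 2]) or crowded (> 2).

    The boundary points belong to the busy band.
    """
    if index_value < 0:
        raise InvalidParameterError("crowding index must be non-negative")
    if index_value < 1.5:
        return CrowdingLabel.GOOD
    if index_value <= 2.0:
        return CrowdingLabel.BUSY
    return CrowdingLabel.CROWDED


def system_time(waits: Iterable[float], services: Iterable[float]) -> float:
    """Total minutes a patient spends in the system: all waits plus all services."""
    total = 0.0
    for kind, values in (("wait", waits), ("service", services)):
        for v in values:
            if v < 0:
                raise InvalidParameterError(f"negative {kind} time {v}")
            total += v
    return total
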