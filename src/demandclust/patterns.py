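"""Demand-pattern labels: the CV²/AII quadrant scheme and group labelling.

The classic classification of intermittent demand places a series in one of
four quadrants by its squared coefficient of variation of demand sizes
(CV², cutoff 0.49) and average inter-demand interval (AII, cutoff 1.32):

==============  ============  ===========
                AII < 1.32    AII >= 1.32
==============  ============  ===========
CV² < 0.49      smooth        slow
CV² >= 0.49     erratic       lumpy
==============  ============  ===========

Values exactly at a cutoff count as the high side.  Consensus groups are
labelled by majority vote of their members' quadrant labels, which is robust
to a single outlying member.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .consensus import ConsensusResult

__all__ = [
    "CV2_CUTOFF",
    "AII_CUTOFF",
    "GroupLabel",
    "PATTERN_NAMES",
    "classification_report",
    "label_groups",
    "sbc_classify",
]

CV2_CUTOFF = 0.49
AII_CUTOFF = 1.32

PATTERN_NAMES = ("smooth", "erratic", "slow", "lumpy")


def sbc_classify(
    cv2: float,
    aii: float,
    cv2_cut: float = CV2_CUTOFF,
    aii_cut: float = AII_CUTOFF,
) -> str:
    """Quadrant label for one series from its (CV², AII) pair."""
    if cv2 < 0:
        raise ValueError("cv2 must be >= 0")
    if aii < 1:
        raise ValueError("aii must be >= 1")
    high_var = cv2 >= cv2_cut
    intermittent = aii >= aii_cut
    if high_var:
        return "lumpy" if intermittent else "erratic"
    return "slow" if intermittent else "smooth"


@dataclass(frozen=True)
class GroupLabel:
    """Majority pattern label of a consensus group with CV²/AII diagnostics."""

    members: tuple[str, ...]
    label: str
    cv2_range: tuple[float, float]
    aii_range: tuple[float, float]
    tie: bool = False
    votes: tuple[tuple[str, int], ...] = ()


def label_groups(
    cr: ConsensusResult,
    stats: Mapping[str, tuple[float, float]],
    cv2_cut: float = CV2_CUTOFF,
    aii_cut: float = AII_CUTOFF,
) -> list[GroupLabel]:
    """Label each pattern group by the majority quadrant vote of its members.

    ``stats`` maps series id -> (cv2, aii).  A missing series is an error; a
    tied vote is flagged (label = alphabetically first of the tied winners,
    ``tie=True``).
    """
    out: list[GroupLabel] = []
    for group in cr.pattern_groups:
        for sid in group:
            if sid not in stats:
                raise KeyError(f"no (cv2, aii) stats for series {sid!r}")
        votes = Counter(
            sbc_classify(*stats[sid], cv2_cut=cv2_cut, aii_cut=aii_cut) for sid in group
        )
        top = max(votes.values())
        winners = sorted(lab for lab, c in votes.items() if c == top)
        cv2s = [stats[sid][0] for sid in group]
        aiis = [stats[sid][1] for sid in group]
        out.append(
            GroupLabel(
                members=group,
                label=winners[0],
                cv2_range=(min(cv2s), max(cv2s)),
                aii_range=(min(aiis), max(aiis)),
                tie=len(winners) > 1,
                votes=tuple(sorted(votes.items())),
            )
        )
    return out


def classification_report(
    cr: ConsensusResult,
    stats: Mapping[str, tuple[float, float]],
    cv2_cut: float = CV2_CUTOFF,
    aii_cut: float = AII_CUTOFF,
) -> pd.DataFrame:
    """Per-series table: cv2, aii, quadrant label, fine/pattern group, group label."""
    labels = label_groups(cr, stats, cv2_cut=cv2_cut, aii_cut=aii_cut)
    fine = cr.group_of(pattern=False)
    pattern = cr.group_of(pattern=True)
    group_label = {gi: gl.label for gi, gl in enumerate(labels)}
    rows = []
    for sid in cr.series_ids:
        cv2, aii = stats[sid]
        rows.append(
            {
                "series_id": sid,
                "cv2": cv2,
                "aii": aii,
                "sbc_label": sbc_classify(cv2, aii, cv2_cut=cv2_cut, aii_cut=aii_cut),
                "fine_group": fine[sid],
                "pattern_group": pattern[sid],
                "group_label": group_label[pattern[sid]],
            }
        )
    return pd.DataFrame(rows)
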