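"""Expert-panel rating aggregation (modified RAND/UCLA appropriateness method).

Panelists score each candidate indicator 1-9 on two domains, validity and
feasibility (1 = definitely not valid/feasible, 9 = definitely valid/
feasible). A candidate is accepted when its mean score is at least 7 on each
domain; the threshold is inclusive, and classification uses means rounded
half-up to one decimal, the precision at which panel results are reported.

Multi-round workflows (e-mail rounds, face-to-face meetings) are represented
as repeated rating sheets with round labels; acceptance uses the final round.
No disagreement or appropriateness index from the full RAND/UCLA manual is
computed — the acceptance rule here is the two-domain mean threshold only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .util import round_half_up

ACCEPTANCE_THRESHOLD = 7.0


class PanelStatus(Enum):
    ACCEPTED = "accepted"
    DISCARDED = "discarded"


class RatingValidationError(ValueError):
    pass


@dataclass(frozen=True)
class RatingSheet:
    """One candidate's per-panelist (validity, feasibility) scores for a round."""

    candidate_id: str
    validity_scores: tuple[int, ...]
    feasibility_scores: tuple[int, ...]
    round_label: str = "final"

    def __post_init__(self) -> None:
        if not self.validity_scores or not self.feasibility_scores:
            raise RatingValidationError("panel size must be >= 1")
        if len(self.validity_scores) != len(self.feasibility_scores):
            raise RatingValidationError("validity and feasibility need one score per panelist")
        for s in (*self.validity_scores, *self.feasibility_scores):
            if not (isinstance(s, int) and 1 <= s <= 9):
                raise RatingValidationError(f"scores must be integers in [1, 9], got {s!r}")


@dataclass(frozen=True)
class PanelDecision:
    candidate_id: str
    mean_validity: float
    mean_feasibility: float
    status: PanelStatus


def mean_scores(sheet: RatingSheet) -> tuple[float, float]:
    """Arithmetic domain means, reported half-up to one decimal."""
    mv = sum(sheet.validity_scores) / len(sheet.validity_scores)
    mf = sum(sheet.feasibility_scores) / len(sheet.feasibility_scores)
    return round_half_up(mv, 1), round_half_up(mf, 1)


def classify_candidate(
    mean_validity: float,
    mean_feasibility: float,
    threshold: float = ACCEPTANCE_THRESHOLD,
) -> PanelStatus:
    """Accepted iff both rounded domain means reach the threshold (inclusive)."""
    mv = round_half_up(mean_validity, 1)
    mf = round_half_up(mean_feasibility, 1)
    if mv >= threshold and mf >= threshold:
        return PanelStatus.ACCEPTED
    return PanelStatus.DISCARDED


def decide(sheet: RatingSheet, threshold: float = ACCEPTANCE_THRESHOLD) -> PanelDecision:
    mv, mf = mean_scores(sheet)
    return PanelDecision(sheet.candidate_id, mv, mf, classify_candidate(mv, mf, threshold))


def read_ratings_csv(path: str | Path) -> list[RatingSheet]:
    """Load per-panelist ratings (candidate_id, panelist_id, validity,
    feasibility, round) into one sheet per candidate and round."""
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["candidate_id"], row.get("round", "final") or "final")
            grouped.setdefault(key, []).append((int(row["validity"]), int(row["feasibility"])))
    sheets = []
    for (cid, rnd), scores in sorted(grouped.items()):
        sheets.append(
            RatingSheet(
                candidate_id=cid,
                validity_scores=tuple(v for v, _ in scores),
                feasibility_scores=tuple(f for _, f in scores),
                round_label=rnd,
            )
        )
    return sheets


def final_round_decisions(
    sheets: list[RatingSheet], threshold: float = ACCEPTANCE_THRESHOLD
) -> list[PanelDecision]:
    """One decision per candidate, from its lexicographically last round label."""
    last: dict[str, RatingSheet] = {}
    for sheet in sheets:
        cur = last.get(sheet.candidate_id)
        if cur is None or sheet.round_label >= cur.round_label:
            last[sheet.candidate_id] = sheet
    return [decide(last[cid], threshold) for cid in sorted(last)]
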