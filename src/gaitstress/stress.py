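"""Physiological and psychological stress markers.

Salivary cortisol (nmol/L) is summarized per participant by baseline
adjustment (subtracting the arrival sample S0 from S1..S5), the maximum
increase over baseline, its percentage relative to S0, and a responder
flag: a participant counts as a cortisol responder when the maximum
increase exceeds 1.5 nmol/L (strict inequality).

Questionnaires are scored from 5-point Likert items:

* PANAS (20 items): Positive and Negative Affect, 10 items each;
* SSSQ (24 items): six dimensions (Distress, Worry, Confidence,
  Negative Affect, Motivation, Self-evaluation) plus a total score over
  all 24 items.

Scores are reported as item means on the 1-5 scale (matching the
instruments' response scale); item sums are emitted alongside. Item-to-
subscale keys are configuration: the shipped defaults follow the standard
published orderings, and any key can be loaded from YAML, including
per-item reverse coding (response r scored as 6 - r).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .keypoints import CortisolSeries, QuestionnaireResponse

__all__ = [
    "CortisolFeatures",
    "ScoringKey",
    "DEFAULT_PANAS_KEY",
    "DEFAULT_SSSQ_KEY",
    "RESPONDER_THRESHOLD_NMOL_L",
    "cortisol_features",
    "cortisol_feature_table",
    "score_panas",
    "score_sssq",
    "score_table",
    "load_scoring_key",
]

#: Cortisol-responder criterion: maximum increase over baseline must
#: *exceed* this many nmol/L.
RESPONDER_THRESHOLD_NMOL_L = 1.5

PANAS_SUBSCALES = ("positive", "negative")
SSSQ_DIMENSIONS = (
    "distress",
    "worry",
    "confidence",
    "negative_affect",
    "motivation",
    "self_evaluation",
)


@dataclass
class CortisolFeatures:
    """Baseline-adjusted cortisol response features for one participant."""

    participant_id: str
    group: str
    adjusted: np.ndarray  # S1..S5 minus S0, nmol/L
    max_increase: float  # nmol/L
    max_increase_pct: float  # % relative to S0; NaN when S0 == 0
    responder: bool
    threshold: float = RESPONDER_THRESHOLD_NMOL_L


def cortisol_features(
    series: CortisolSeries,
    responder_threshold: float = RESPONDER_THRESHOLD_NMOL_L,
) -> CortisolFeatures:
    """Baseline adjustment, maximum increase, and responder classification.

    The adjusted curve is S1..S5 minus S0; ``max_increase`` is its maximum,
    ``max_increase_pct`` is 100 * max_increase / S0 (NaN-flagged when the
    baseline is zero), and the responder flag is ``max_increase >
    responder_threshold`` (strict).
    """
    raw = series.concentration
    s0 = raw[0]
    adjusted = raw[1:] - s0
    max_increase = float(adjusted.max())
    pct = float(100.0 * max_increase / s0) if s0 > 0 else float("nan")
    return CortisolFeatures(
        series.participant_id,
        series.group,
        adjusted,
        max_increase,
        pct,
        bool(max_increase > responder_threshold),
        responder_threshold,
    )


def cortisol_feature_table(
    series_list: list[CortisolSeries],
    responder_threshold: float = RESPONDER_THRESHOLD_NMOL_L,
) -> pd.DataFrame:
    """One row per participant: adjusted S1..S5, max increase, responder."""
    rows = []
    for s in series_list:
        f = cortisol_features(s, responder_threshold)
        row = {"participant": f.participant_id, "group": f.group}
        row.update({f"adj_S{i}": v for i, v in enumerate(f.adjusted, start=1)})
        row.update(
            max_increase_nmol_l=f.max_increase,
            max_increase_pct=f.max_increase_pct,
            responder=f.responder,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# questionnaire scoring


@dataclass
class ScoringKey:
    """Item-to-subscale mapping for one instrument.

    ``subscales`` maps subscale name -> 1-based item indices;
    ``reverse`` lists items scored as 6 - response. Every item of the
    instrument must be covered exactly once.
    """

    instrument: str
    n_items: int
    subscales: dict[str, tuple[int, ...]]
    reverse: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        covered = [i for items in self.subscales.values() for i in items]
        if sorted(covered) != list(range(1, self.n_items + 1)):
            raise ValueError(
                f"{self.instrument} key must cover items 1..{self.n_items} exactly once"
            )
        if not set(self.reverse) <= set(covered):
            raise ValueError("reverse-keyed items must be part of the instrument")

    def scored_items(self, items: np.ndarray) -> np.ndarray:
        """Apply reverse coding; input/output are 1-based-aligned arrays."""
        out = items.astype(float).copy()
        for i in self.reverse:
            out[i - 1] = 6.0 - out[i - 1]
        return out


#: Standard PANAS ordering: positive-affect items interleaved with
#: negative-affect items (10 each).
DEFAULT_PANAS_KEY = ScoringKey(
    "PANAS",
    20,
    {
        "positive": (1, 3, 5, 9, 10, 12, 14, 16, 17, 19),
        "negative": (2, 4, 6, 7, 8, 11, 13, 15, 18, 20),
    },
)

#: SSSQ key with the six reported dimensions, four items each, in blocks.
#: Published translations order items differently; the key is configuration
#: and can be replaced via YAML.
DEFAULT_SSSQ_KEY = ScoringKey(
    "SSSQ",
    24,
    {
        "distress": (1, 2, 3, 4),
        "worry": (5, 6, 7, 8),
        "confidence": (9, 10, 11, 12),
        "negative_affect": (13, 14, 15, 16),
        "motivation": (17, 18, 19, 20),
        "self_evaluation": (21, 22, 23, 24),
    },
)


def _score_subscales(
    resp: QuestionnaireResponse, key: ScoringKey
) -> tuple[dict[str, float], dict[str, float]]:
    if resp.instrument != key.instrument:
        raise ValueError(
            f"response is {resp.instrument} but key is for {key.instrument}"
        )
    items = key.scored_items(resp.items)
    means = {
        name: float(np.mean([items[i - 1] for i in idx]))
        for name, idx in key.subscales.items()
    }
    sums = {
        name: float(np.sum([items[i - 1] for i in idx]))
        for name, idx in key.subscales.items()
    }
    return means, sums


def score_panas(
    resp: QuestionnaireResponse, key: ScoringKey = DEFAULT_PANAS_KEY
) -> dict[str, float]:
    """PANAS Positive/Negative Affect scores as item means (1-5).

    Item sums (10-50 per subscale) are included under ``*_sum`` keys.
    """
    means, sums = _score_subscales(resp, key)
    out = {f"PANAS_{k}": v for k, v in means.items()}
    out.update({f"PANAS_{k}_sum": v for k, v in sums.items()})
    return out


def score_sssq(
    resp: QuestionnaireResponse, key: ScoringKey = DEFAULT_SSSQ_KEY
) -> dict[str, float]:
    """SSSQ dimension scores plus the total (mean over all 24 items)."""
    means, sums = _score_subscales(resp, key)
    items = key.scored_items(resp.items)
    out = {f"SSSQ_{k}": v for k, v in means.items()}
    out["SSSQ_total"] = float(items.mean())
    out.update({f"SSSQ_{k}_sum": v for k, v in sums.items()})
    out["SSSQ_total_sum"] = float(items.sum())
    return out


def score_table(
    responses: list[QuestionnaireResponse],
    panas_key: ScoringKey = DEFAULT_PANAS_KEY,
    sssq_key: ScoringKey = DEFAULT_SSSQ_KEY,
) -> pd.DataFrame:
    """Long score table: one row per participant x timepoint.

    PANAS and SSSQ responses for the same participant/timepoint are merged
    into a single row; absent instruments leave NaN columns.
    """
    merged: dict[tuple[str, str, str], dict[str, float]] = {}
    for r in responses:
        key = (r.participant_id, r.group, r.timepoint)
        scores = score_panas(r, panas_key) if r.instrument == "PANAS" else score_sssq(r, sssq_key)
        merged.setdefault(key, {}).update(scores)
    rows = []
    for (pid, group, tp), scores in sorted(merged.items()):
        rows.append({"participant": pid, "group": group, "timepoint": tp, **scores})
    return pd.DataFrame(rows)


def load_scoring_key(path: str | Path) -> ScoringKey:
    """Load a scoring key from YAML.

    Expected layout::

        instrument: SSSQ
        n_items: 24
        items:
          - {index: 1, subscale: distress, reverse: false}
          ...
    """
    payload = yaml.safe_load(Path(path).read_text())
    subscales: dict[str, list[int]] = {}
    reverse = set()
    for item in payload["items"]:
        subscales.setdefault(str(item["subscale"]), []).append(int(item["index"]))
        if item.get("reverse", False):
            reverse.add(int(item["index"]))
    return ScoringKey(
        str(payload["instrument"]),
        int(payload["n_items"]),
        {k: tuple(sorted(v)) for k, v in subscales.items()},
        frozenset(reverse),
    )
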