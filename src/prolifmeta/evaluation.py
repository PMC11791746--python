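"""Concordance-index evaluation of continuous risk scores.

Harrell's C: among all pairs of subjects in which the order of events is
observable despite censoring, the fraction in which the higher risk score
belongs to the subject who failed earlier (score ties count one half).  A
pair is usable iff the shorter observed time is an event; pairs with equal
observed times are not usable (no shorter time exists under this reading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import CohortCollection
from .survival_meta import DEFAULT_HORIZON_MONTHS, restrict_followup

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    concordant: int
    discordant: int
    tied: int
    usable_pairs: int

    def __post_init__(self) -> None:
        if self.concordant + self.discordant + self.tied != self.usable_pairs:
            raise EvaluationError("pair counts do not sum to usable pairs")


def concordance_index(scores, times, events) -> ConcordanceResult:
    """Harrell's concordance index for a risk score against censored times.

    Higher score = higher risk = expected shorter time.  Counts are exact
    (vectorized all-pairs comparison).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float).astype(int)
    if not (s.size == t.size == e.size):
        raise EvaluationError("scores, times, events must be aligned")
    n = s.size
    # usable(i, j): t_i < t_j and event_i == 1
    shorter = t[:, None] < t[None, :]
    usable = shorter & (e[:, None] == 1)
    higher = s[:, None] > s[None, :]
    lower = s[:, None] < s[None, :]
    concordant = int((usable & higher).sum())
    discordant = int((usable & lower).sum())
    usable_pairs = int(usable.sum())
    tied = usable_pairs - concordant - discordant
    if usable_pairs == 0:
        raise EvaluationError("no usable pairs (all censored or tied times)")
    c = (concordant + 0.5 * tied) / usable_pairs
    return ConcordanceResult(
        c_index=float(c), concordant=concordant, discordant=discordant,
        tied=tied, usable_pairs=usable_pairs,
    )


def compare_signatures(
    collection: CohortCollection,
    score_sets: dict[str, dict[str, pd.Series]],
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
) -> pd.DataFrame:
    """Head-to-head C-index comparison of risk-score sets across cohorts.

    ``score_sets`` maps score-set name -> {cohort_id -> per-sample scores}.
    Follow-up is restricted to the horizon before pair counting.  Returns a
    long table with one row per (score set, cohort) plus a pooled row per
    score set (sample-size-weighted mean C), sorted by pooled C descending.
    """
    if not score_sets:
        raise EvaluationError("at least one score set required")
    rows = []
    for name, per_cohort in score_sets.items():
        cohort_rows = []
        for cohort in collection:
            scores = per_cohort.get(cohort.cohort_id)
            if scores is None:
                logger.warning(
                    "score set %r missing for cohort %s; skipped",
                    name, cohort.cohort_id,
                )
                continue
            t_all, e_all, mask = cohort.survival()
            if t_all.size == 0:
                logger.warning("cohort %s: no survival data; skipped",
                               cohort.cohort_id)
                continue
            t, e = restrict_followup(t_all, e_all, horizon_months)
            s = scores.loc[cohort.samples[mask]].to_numpy(dtype=float)
            try:
                res = concordance_index(s, t, e)
            except EvaluationError as err:
                logger.warning("cohort %s: %s; skipped", cohort.cohort_id, err)
                continue
            cohort_rows.append(
                {
                    "score_name": name,
                    "cohort_id": cohort.cohort_id,
                    "n": int(t.size),
                    "usable_pairs": res.usable_pairs,
                    "c_index": res.c_index,
                }
            )
        if cohort_rows:
            ns = np.array([r["n"] for r in cohort_rows], dtype=float)
            cs = np.array([r["c_index"] for r in cohort_rows])
            pooled = float((ns * cs).sum() / ns.sum())
            cohort_rows.append(
                {
                    "score_name": name,
                    "cohort_id": "POOLED",
                    "n": int(ns.sum()),
                    "usable_pairs": int(
                        sum(r["usable_pairs"] for r in cohort_rows)
                    ),
                    "c_index": pooled,
                }
            )
        rows.extend(cohort_rows)
    table = pd.DataFrame(rows)
    if table.empty:
        raise EvaluationError("no cohort could be evaluated for any score set")
    pooled_c = (
        table[table["cohort_id"] == "POOLED"]
        .set_index("score_name")["c_index"]
    )
    table["_pooled"] = table["score_name"].map(pooled_c)
    table = table.sort_values(
        ["_pooled", "score_name", "cohort_id"], ascending=[False, True, True]
    ).drop(columns="_pooled")
    return table.reset_index(drop=True)
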