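"""Behavioral statistics for hand-use data, observed or simulated.

Operates on tidy records (one grasp per row) with columns
``participant, age_group, condition, trial, hand, handedness``; hands are
recorded as left/right/both and transformed into the preferred/nonpreferred
frame through each participant's handedness direction, so that left- and
right-handed children can be pooled.

Provides the categorical tests used with such data — Pearson chi-squared
(contingency and goodness-of-fit) and the McNemar test for paired binary
outcomes across two conditions — plus proportion tables and a synthetic
record generator (independent Bernoulli hand choices) for testing the
statistics layer without any study data.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dynamics import NONPREFERRED, PREFERRED
from .protocol import CONDITIONS, TRIAL_LABELS

__all__ = [
    "RECORD_COLUMNS",
    "classify_handedness",
    "to_preferred_frame",
    "chi_squared",
    "mcnemar",
    "proportion_table",
    "generate_fixture_cohort",
]

RECORD_COLUMNS = ("participant", "age_group", "condition", "trial",
                  "hand", "handedness")

_HANDS = ("left", "right", "both")


def classify_handedness(neutral_selections: Sequence[str]) -> str:
    """Handedness direction from hand choices in neutral trials.

    The hand chosen strictly more often among left/right counts is the
    preferred hand; bimanual ("both") grasps count toward neither.  An
    exact tie (including all-"both") yields ``"undetermined"``.
    """
    if len(neutral_selections) == 0:
        raise ValueError("classify_handedness requires at least one selection")
    bad = set(neutral_selections) - set(_HANDS)
    if bad:
        raise ValueError(f"unknown hand values: {sorted(bad)}")
    counts = Counter(neutral_selections)
    if counts["left"] > counts["right"]:
        return "left"
    if counts["right"] > counts["left"]:
        return "right"
    return "undetermined"


def to_preferred_frame(records: pd.DataFrame,
                       handedness: Mapping | None = None) -> pd.DataFrame:
    """Map left/right hand use onto preferred (P) / nonpreferred (NP).

    ``handedness`` maps participant -> "left" | "right"; if omitted, the
    records' own ``handedness`` column is used.  "both" grasps pass through
    unchanged.  Participants with unknown or undetermined handedness raise
    an error naming them.
    """
    df = records.copy()
    if handedness is None:
        handedness = (df.drop_duplicates("participant")
                        .set_index("participant")["handedness"].to_dict())
    unknown = sorted(
        p for p in df["participant"].unique().tolist()
        if handedness.get(p) not in ("left", "right")
    )
    if unknown:
        raise ValueError(f"handedness unknown for participants: {unknown}")
    pref = df["participant"].map(handedness)
    df["hand"] = np.select(
        [df["hand"] == "both", df["hand"] == pref],
        ["both", PREFERRED],
        default=NONPREFERRED,
    )
    return df


def chi_squared(table, corrected: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test on a contingency table.

    A single-row table is tested against the uniform distribution
    (goodness of fit); otherwise the r x c test of independence is used,
    with Yates continuity correction applied to 2 x 2 tables when
    ``corrected`` is set.  Returns (statistic, degrees of freedom, p).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("table must be 2-D with at least two columns")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if arr.shape[0] == 1:
        if arr.sum() == 0:
            raise ValueError("table has no observations")
        stat, p = sps.chisquare(arr[0])
        return float(stat), arr.shape[1] - 1, float(p)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(arr, correction=corrected)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mcnemar(paired, exact: bool = True) -> dict:
    """McNemar test for paired binary outcomes across two conditions.

    ``paired`` is a sequence of (outcome_condition_1, outcome_condition_2)
    booleans/0-1 values, one pair per participant.  Only discordant pairs
    (b = 1/0, c = 0/1) are informative.  The default is the exact two-sided
    binomial test on the discordant counts, appropriate for small samples;
    ``exact=False`` uses the chi-squared approximation (b-c)^2/(b+c) on one
    degree of freedom.  With no discordant pairs the data are exactly
    symmetric and p = 1 by convention.
    """
    arr = np.asarray(paired)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("paired must be a nonempty sequence of outcome pairs")
    x, y = arr[:, 0].astype(bool), arr[:, 1].astype(bool)
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    n = b + c
    if n == 0:
        return {"b": b, "c": c, "p": 1.0, "method": "exact" if exact else "chi2"}
    if exact:
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n, 0.5)))
        return {"b": b, "c": c, "p": p, "method": "exact"}
    stat = (b - c) ** 2 / n
    p = float(sps.chi2.sf(stat, df=1))
    return {"b": b, "c": c, "statistic": float(stat), "p": p, "method": "chi2"}


def proportion_table(records: pd.DataFrame,
                     groupby: Sequence[str] = ("age_group", "condition", "trial"),
                     ) -> pd.DataFrame:
    """Preferred-hand proportions per group, with explicit denominators.

    Records must already be in the preferred frame (hand in {P, NP, both}).
    Bimanual grasps are excluded from both numerator and denominator and
    reported in the ``n_both`` column.  Empty groups simply do not appear.
    """
    if records.empty:
        raise ValueError("proportion_table requires nonempty records")
    bad = set(records["hand"]) - {PREFERRED, NONPREFERRED, "both"}
    if bad:
        raise ValueError(
            f"records must be in the preferred frame; unexpected hands {sorted(bad)}"
        )
    rows = []
    for key, grp in records.groupby(list(groupby)):
        key = key if isinstance(key, tuple) else (key,)
        n_p = int((grp["hand"] == PREFERRED).sum())
        n_np = int((grp["hand"] == NONPREFERRED).sum())
        n_both = int((grp["hand"] == "both").sum())
        row = dict(zip(groupby, key))
        row.update(
            n=n_p + n_np,
            n_preferred=n_p,
            n_both=n_both,
            prop_preferred=(n_p / (n_p + n_np)) if (n_p + n_np) else float("nan"),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def generate_fixture_cohort(n_per_group: int,
                            probs: Mapping[tuple[str, str], float],
                            seed: int,
                            age_group: str = "synthetic",
                            p_right_handed: float = 0.5) -> pd.DataFrame:
    """Synthetic behavioral records: independent Bernoulli hand choices.

    ``probs`` maps (condition, trial) -> probability of a preferred-hand
    choice; missing trials default to 0.5.  Handedness direction is drawn
    per participant (right with probability ``p_right_handed``) and choices
    are emitted in the raw left/right frame, so the preferred-frame
    transform is exercised on the way back.  Reproducible from ``seed``.
    """
    for key, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {key} must be in [0, 1], got {p}")
    if not 0.0 <= p_right_handed <= 1.0:
        raise ValueError("p_right_handed must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_per_group):
        dom = "right" if rng.uniform() < p_right_handed else "left"
        nondom = "left" if dom == "right" else "right"
        for cond in CONDITIONS:
            for lbl in TRIAL_LABELS:
                p = probs.get((cond, lbl), 0.5)
                hand = dom if rng.uniform() < p else nondom
                rows.append(
                    {
                        "participant": i,
                        "age_group": age_group,
                        "condition": cond,
                        "trial": lbl,
                        "hand": hand,
                        "handedness": dom,
                    }
                )
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
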