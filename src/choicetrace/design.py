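"""Choice-task design and per-trial model inputs.

The task presents every unordered pair of the food set exactly once per
participant (18 foods -> 153 trials), in an individually randomized
order.  For modelling, each trial carries difference scores on the three
motives (health, palatability, calories), computed relative to a
randomly assigned *reference* option, with the outcome coded 1 when the
reference was chosen.  This sign-symmetric coding is statistically
identical (up to the sign of every coefficient pair) to chosen-minus-
non-chosen coding, but is non-degenerate.

Trial-level predictors are z-standardized within participant (person
mean); the person-level moderator (restrained eating) is z-standardized
across participants (grand mean).  Cross-level interactions are products
of the already-standardized components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairingPlan",
    "DesignError",
    "DegeneratePredictorError",
    "make_pairings",
    "difference_scores",
    "standardize",
    "build_model_input",
    "MOTIVES",
]

MOTIVES = ("health", "palatability", "calories")


class DesignError(ValueError):
    """Raised for invalid design inputs (duplicate foods, missing ratings)."""


class DegeneratePredictorError(DesignError):
    """Raised when a predictor is constant within a standardization group."""


@dataclass(frozen=True)
class PairingPlan:
    """Per-participant trial lists over all unordered food pairs.

    ``trials`` has one row per participant x pair with columns
    ``participant_id, trial_index, food_ref, food_alt, ref_side``; the
    pair order is shuffled independently per participant and the side
    (and thereby which member is the reference) is uniform random.
    """

    trials: pd.DataFrame
    food_ids: tuple

    @property
    def n_pairs(self) -> int:
        n = len(self.food_ids)
        return n * (n - 1) // 2


def make_pairings(food_ids, participant_ids, seed=None, rng=None) -> PairingPlan:
    """Enumerate all unordered food pairs for each participant.

    Each participant receives all n(n-1)/2 pairs in an independently
    shuffled order; within each trial, one food is uniformly assigned
    the left side and one member of the pair is uniformly assigned the
    reference role (here: reference = the right-hand food is as likely
    as the left; we take the first element after a per-trial swap).

    Raises
    ------
    DesignError
        On fewer than 2 foods or duplicate food ids.
    """
    food_ids = list(food_ids)
    if len(food_ids) < 2:
        raise DesignError("need at least 2 foods")
    if len(set(food_ids)) != len(food_ids):
        raise DesignError("duplicate food ids")
    if rng is None:
        rng = np.random.default_rng(seed)
    base_pairs = [(a, b) for i, a in enumerate(food_ids) for b in food_ids[i + 1:]]
    base = np.arange(len(base_pairs))
    frames = []
    for pid in participant_ids:
        order = rng.permutation(base)
        swap = rng.random(len(base)) < 0.5      # which member is the reference
        side = rng.random(len(base)) < 0.5      # True: reference on the left
        ref = [base_pairs[k][1] if s else base_pairs[k][0] for k, s in zip(order, swap)]
        alt = [base_pairs[k][0] if s else base_pairs[k][1] for k, s in zip(order, swap)]
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "trial_index": np.arange(len(base)),
            "food_ref": ref,
            "food_alt": alt,
            "ref_side": np.where(side, "left", "right"),
        }))
    return PairingPlan(trials=pd.concat(frames, ignore_index=True), food_ids=tuple(food_ids))


def difference_scores(trials: pd.DataFrame, ratings: pd.DataFrame) -> pd.DataFrame:
    """Attach per-trial motive difference scores (reference minus alternative).

    ``ratings`` is long format (participant_id, food_id, motive, value);
    the result adds columns ``d_health, d_palatability, d_calories``.
    A difference of +50 on health means a 50-point health advantage of
    the reference over the alternative option.

    Raises
    ------
    DesignError
        If any (participant, food, motive) rating needed by a trial is missing.
    """
    wide = ratings.pivot_table(
        index=["participant_id", "food_id"], columns="motive", values="value",
        aggfunc="first",
    )
    missing = [m for m in MOTIVES if m not in wide.columns]
    if missing:
        raise DesignError(f"ratings lack motives: {missing}")
    out = trials.copy()
    for which in ("ref", "alt"):
        idx = pd.MultiIndex.from_frame(out[["participant_id", f"food_{which}"]])
        sub = wide.reindex(idx)
        if sub[list(MOTIVES)].isna().any().any():
            bad = idx[sub[list(MOTIVES)].isna().any(axis=1)][:3]
            raise DesignError(f"missing ratings for {list(bad)}")
        for m in MOTIVES:
            out[f"{which}_{m}"] = sub[m].to_numpy()
    for m in MOTIVES:
        out[f"d_{m}"] = out[f"ref_{m}"] - out[f"alt_{m}"]
        out.drop(columns=[f"ref_{m}", f"alt_{m}"], inplace=True)
    return out


def standardize(values, level: str = "person", grouping=None, ddof: int = 1):
    """Two-level z-standardization.

    Parameters
    ----------
    values : Series or array
    level : {"person", "grand"}
        "person": (x - person mean)/person SD within each group of
        ``grouping`` (trial-level predictors).  "grand": across all
        values (person-level moderators such as restrained eating).
    ddof : int
        SD denominator degrees of freedom (1 = sample SD).

    Raises
    ------
    DegeneratePredictorError
        If any group (or the whole series for grand level) has zero SD,
        naming the offending group.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    if level == "grand":
        sd = s.std(ddof=ddof)
        if not sd > 0:
            raise DegeneratePredictorError("grand-level predictor is constant")
        return ((s - s.mean()) / sd).to_numpy()
    if level != "person":
        raise ValueError("level must be 'person' or 'grand'")
    if grouping is None:
        raise ValueError("person-level standardization requires a grouping")
    g = pd.Series(np.asarray(grouping))
    grp = s.groupby(g)
    sd = grp.transform("std", ddof=ddof)
    if (sd <= 0).any() or sd.isna().any():
        bad = g[(sd <= 0) | sd.isna()].unique()[:5]
        raise DegeneratePredictorError(f"constant predictor within group(s) {list(bad)}")
    return ((s - grp.transform("mean")) / sd).to_numpy()


def build_model_input(
    trials: pd.DataFrame,
    ratings: pd.DataFrame,
    participants: pd.DataFrame,
    drop_timeouts: bool = True,
) -> pd.DataFrame:
    """Assemble the analysis-ready trial table.

    Joins difference scores to trials, person-standardizes each motive
    difference (z_d_*), grand-standardizes restrained eating, age and
    BMI (z_re, z_age, z_bmi), and forms cross-level interaction columns
    ``z_d_<motive>:z_re`` as products of the standardized parts.  When
    the trials table carries outcomes (``chose_ref``) and timeout flags,
    timeout trials are dropped (default) — analyses run on completed
    trials only.
    """
    out = difference_scores(trials, ratings)
    if drop_timeouts and "timeout" in out.columns:
        out = out.loc[~out["timeout"].astype(bool)].reset_index(drop=True)
    for m in MOTIVES:
        out[f"z_d_{m}"] = standardize(out[f"d_{m}"], "person", out["participant_id"])
    pp = participants.set_index("participant_id")
    for src, dst in (("re_score", "z_re"), ("age", "z_age"), ("bmi", "z_bmi")):
        if src in pp.columns:
            z = standardize(pp[src].to_numpy(), "grand")
            out[dst] = pd.Series(z, index=pp.index).reindex(out["participant_id"]).to_numpy()
    if "cond_first" in pp.columns:
        out["cond_first"] = pp["cond_first"].reindex(out["participant_id"]).to_numpy()
    for m in MOTIVES:
        out[f"z_d_{m}:z_re"] = out[f"z_d_{m}"] * out["z_re"]
    # chosen-relative difference scores for the conflict analyses: the
    # selected-minus-non-selected advantage is sign-meaningful there
    # (choosing the better-liked food predicts less conflict)
    if "chose_ref" in out.columns:
        sign = np.where(out["chose_ref"].astype(bool), 1.0, -1.0)
        for m in MOTIVES:
            out[f"z_dsel_{m}"] = standardize(
                out[f"d_{m}"] * sign, "person", out["participant_id"])
            out[f"z_dsel_{m}:z_re"] = out[f"z_dsel_{m}"] * out["z_re"]
    return out
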