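"""Alternative Uses Task (AUT) scoring.

Four divergent-thinking indices per participant:

* fluency — number of valid responses over all objects;
* flexibility — mean over objects of the number of distinct conceptual
  categories the participant's responses draw from;
* frequency-based (FB) originality — statistical infrequency, 1 minus a
  response's relative frequency within its object across the whole
  sample, averaged over the participant's responses;
* rater-based (RB) originality — mean of two judges' 1-5 ratings per
  idea, averaged per participant.

Plus ICC(2,k) inter-rater reliability over the full idea set.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

#: Filler phrases removed before frequency matching; longest first.
DEFAULT_STOP_PHRASES = (
    "it can be used as", "it can be used for", "can be used as",
    "can be used for", "you can use it as", "use it as",
    "used for", "use for", "used as", "use as", "used to", "use to",
)

_ARTICLES = {"a", "an", "the"}


def _singularize(word: str) -> str:
    """Light rule-based singular form; deterministic, no dictionary."""
    if len(word) <= 3 or not word.endswith("s"):
        return word
    if word.endswith("ss"):
        return word
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("sses", "xes", "ches", "shes", "zes")):
        return word[:-2]
    return word[:-1]


def normalize_response(raw_text: str,
                       stop_phrases: tuple[str, ...] = DEFAULT_STOP_PHRASES,
                       singularize: bool = True) -> str:
    """Canonical form of a response for exact-match frequency counting.

    Lower-cases, strips punctuation, deletes filler phrases ("used for",
    ...), drops leading articles, unifies singular/plural and collapses
    whitespace.  Returns "" for responses that are empty after cleaning;
    callers treat those as invalid.
    """
    if raw_text is None or (isinstance(raw_text, float) and np.isnan(raw_text)):
        return ""
    text = str(raw_text).lower()
    # iterate to a fixed point: singular/plural rules can expose new
    # stop-phrase or article matches
    for _ in range(5):
        prev = text
        text = re.sub(r"[^\w\s-]", " ", text)
        for phrase in sorted(stop_phrases, key=len, reverse=True):
            text = re.sub(rf"\b{re.escape(phrase)}\b", " ", text)
        tokens = text.split()
        while tokens and tokens[0] in _ARTICLES:
            tokens = tokens[1:]
        if singularize:
            tokens = [_singularize(t) for t in tokens]
        text = " ".join(tokens)
        if text == prev:
            break
    return text


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    """Ensure a ``normalized_text`` column and a validity mask."""
    df = table.copy()
    if "normalized_text" not in df.columns:
        df["normalized_text"] = df["raw_text"].map(normalize_response)
    df["valid"] = df["normalized_text"].astype(str).str.len() > 0
    return df


def score_fb_originality(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Statistical infrequency per response and its per-participant mean.

    For each object, infrequency = 1 - count(normalized response within
    that object) / total responses for that object across the sample
    (e.g. 8 occurrences among 20 -> relative frequency 0.40, infrequency
    0.60).  The participant score pools the participant's valid responses
    over all objects.
    """
    df = _prepare(table)
    valid = df[df["valid"]]
    if valid.empty:
        warnings.warn("no valid responses; FB originality undefined")
        return pd.Series(dtype=float), pd.Series(dtype=float)
    totals = valid.groupby("object_id").size()
    counts = valid.groupby(["object_id", "normalized_text"]).size()
    infreq = 1.0 - valid.apply(
        lambda r: counts[(r["object_id"], r["normalized_text"])]
        / totals[r["object_id"]], axis=1)
    infreq.name = "fb_infrequency"
    per_participant = infreq.groupby(valid["participant_id"]).mean()
    per_participant.name = "fb_originality"
    return infreq, per_participant


def score_flexibility_fluency(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant flexibility and fluency.

    Flexibility averages, over the objects a participant responded to,
    the number of distinct category labels used for that object; fluency
    counts valid responses over all objects.  Participants with zero
    valid responses are excluded with a warning.
    """
    df = _prepare(table)
    invalid_ids = set(df["participant_id"]) - set(
        df.loc[df["valid"], "participant_id"])
    if invalid_ids:
        warnings.warn(
            f"excluding participants with no valid responses: {sorted(invalid_ids)}")
    valid = df[df["valid"]]
    flex = (valid.groupby(["participant_id", "object_id"])["category_label"]
            .nunique().groupby("participant_id").mean())
    fluency = valid.groupby("participant_id").size()
    out = pd.DataFrame({"flexibility": flex, "fluency": fluency})
    out.index.name = "participant_id"
    return out


def score_rb_originality(table: pd.DataFrame,
                         consensus_col: str = "consensus_score") -> pd.Series:
    """Mean of the two judges per idea, then mean per participant.

    A non-missing value in ``consensus_col`` (judges' agreed score after
    a large discrepancy) overrides the two-rater mean for that idea.
    Ideas missing a rating (and without consensus) are excluded with a
    warning.
    """
    df = _prepare(table)
    df = df[df["valid"]].copy()
    idea = (df["rater1_score"].astype(float) + df["rater2_score"].astype(float)) / 2.0
    if consensus_col in df.columns:
        cons = df[consensus_col].astype(float)
        idea = idea.where(cons.isna(), cons)
    missing = idea.isna()
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} ideas with missing ratings")
    out = idea[~missing].groupby(df.loc[~missing, "participant_id"]).mean()
    out.name = "rb_originality"
    return out


@dataclass
class ICCResult:
    icc: float
    variant: str
    n_items: int
    n_raters: int
    note: str = ""


def compute_icc(ratings: pd.DataFrame | np.ndarray) -> ICCResult:
    """ICC(2,k): two-way random effects, absolute agreement, average of k raters.

    ``ratings`` is an ideas x raters matrix.  With no between-idea
    variance the coefficient is undefined and reported as NaN.
    """
    mat = np.asarray(ratings, dtype=float)
    n_items, n_raters = mat.shape
    if n_raters < 2 or n_items < 3:
        raise ValueError("need at least 2 raters and 3 ideas")
    variant = "ICC(2,k) two-way random, absolute agreement, average measures"
    if np.allclose(mat.mean(axis=1).var(), 0.0):
        return ICCResult(float("nan"), variant, n_items, n_raters,
                         note="zero between-idea variance; ICC undefined")
    long = pd.DataFrame({
        "idea": np.repeat(np.arange(n_items), n_raters),
        "rater": np.tile(np.arange(n_raters), n_items),
        "score": mat.ravel(),
    })
    with warnings.catch_warnings():
        # perfect agreement puts a zero in pingouin's F denominator
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(data=long, targets="idea", raters="rater",
                                 ratings="score")
    # pingouin labels the 2-way-random absolute-agreement average-measures
    # coefficient ICC2k (<=0.5.x) or ICC(A,k) (>=0.6)
    row = res[res["Type"].isin(["ICC2k", "ICC(A,k)"])]
    icc = float(row["ICC"].iloc[0])
    return ICCResult(icc, variant, n_items, n_raters)


def score_participants(table: pd.DataFrame,
                       sebr: pd.Series | None = None) -> pd.DataFrame:
    """All four AUT indices per participant, optionally joined with sEBR."""
    ff = score_flexibility_fluency(table)
    _, fb = score_fb_originality(table)
    rb = score_rb_originality(table)
    out = ff.join(fb).join(rb)
    if sebr is not None:
        out = out.join(pd.Series(sebr, name="sebr"))
        out = out[["sebr", "fluency", "flexibility", "fb_originality",
                   "rb_originality"]]
    return out
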