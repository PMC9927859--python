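"""Behavioral measures: word-count lipreading score, continuous
comprehension-rating summary, and their correlation with a
presentation-order control.

The on-site lipreading test presents 10 sentences totalling 50 words; the
skill score is the percentage of target words correctly reported.  Scoring
is an order-free multiset intersection of normalized word tokens: writing
"we eat" for "On Thursday we eat pancakes" scores 2 out of 5.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dataio import BehavioralTable, DataError

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def normalize_words(text: str | Iterable[str]) -> list[str]:
    """Case-fold and strip punctuation; returns word tokens."""
    if isinstance(text, str):
        tokens = text.split()
    else:
        tokens = [t for w in text for t in str(w).split()]
    out = []
    for tok in tokens:
        tok = tok.casefold().translate(_PUNCT_TABLE)
        if tok:
            out.append(tok)
    return out


@dataclass(frozen=True)
class SentenceKey:
    sentence_id: str
    target_words: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.target_words) < 1:
            raise DataError(f"sentence {self.sentence_id!r} has no target words")


@dataclass
class RatingTrace:
    """Continuous comprehension rating sampled at a fixed rate (5 Hz in the
    rating tool), values on [0, 1]."""

    samples: np.ndarray
    rate_hz: float = 5.0

    def __post_init__(self) -> None:
        self.samples = np.clip(np.asarray(self.samples, dtype=np.float64), 0.0, 1.0)
        if self.rate_hz <= 0:
            raise DataError("rate_hz must be positive")

    def resampled(self, rate_hz: float = 5.0) -> "RatingTrace":
        """Nearest-neighbour resampling onto a fixed-rate grid."""
        n_out = max(1, int(round(len(self.samples) * rate_hz / self.rate_hz)))
        src = np.minimum((np.arange(n_out) * self.rate_hz / rate_hz).round().astype(int),
                         len(self.samples) - 1)
        return RatingTrace(samples=self.samples[src], rate_hz=rate_hz)


def score_response(key: SentenceKey, response: Sequence[str] | str
                   ) -> tuple[int, int]:
    """Count target words matched by the response (order-free multiset
    intersection; each response token consumes at most one target token)."""
    target = Counter(normalize_words(key.target_words))
    n_target = sum(target.values())
    if n_target == 0:
        raise DataError(f"sentence {key.sentence_id!r} normalizes to no words")
    resp = Counter(normalize_words(response))
    n_correct = sum(min(c, resp[w]) for w, c in target.items())
    return n_correct, n_target


def lipreading_score(keys: Sequence[SentenceKey],
                     responses: Sequence[Sequence[str] | str]) -> float:
    """Percent of all target words correctly reported across sentences."""
    if len(keys) != len(responses):
        raise DataError(f"{len(keys)} keys but {len(responses)} responses")
    correct = 0
    total = 0
    for key, resp in zip(keys, responses):
        c, t = score_response(key, resp)
        correct += c
        total += t
    return 100.0 * correct / total


def mean_rating(trace: RatingTrace) -> float:
    """Arithmetic mean of the rating trace (the per-subject summary used to
    mitigate moment-to-moment rating variation)."""
    if trace.samples.size < 1:
        raise DataError("rating trace is empty")
    return float(trace.samples.mean())


def center_by_group(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Subtract each group's mean from its members."""
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise DataError("values and groups must align")
    out = values.copy()
    for g in np.unique(groups):
        sel = groups == g
        if not sel.any():
            raise DataError(f"empty order group {g!r}")
        out[sel] -= values[sel].mean()
    return out


def score_rating_correlation(table: BehavioralTable, control_order: bool = False,
                             n_perm: int = 9999, seed: int = 0
                             ) -> tuple[float, float]:
    """Pearson r between lipreading score and mean rating, with permutation p.

    With control_order, per-order-group means are subtracted from both
    variables first (equivalent to including the groups as nuisance
    covariates).  p is two-sided, from shuffling subject labels of the
    rating variable.
    """
    df = table.frame
    if len(df) < 3:
        raise DataError("need at least 3 subjects")
    score = df["lip_score_pct"].to_numpy(dtype=float)
    rating = df["mean_rating"].to_numpy(dtype=float)
    groups = df["order_group"].to_numpy()
    if control_order:
        score = center_by_group(score, groups)
        rating = center_by_group(rating, groups)
    if score.std() == 0 or rating.std() == 0:
        return float("nan"), float("nan")

    def _r(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = _r(score, rating)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(rating))
        if abs(_r(score, rating[perm])) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return r_obs, p
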