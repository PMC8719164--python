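"""Pre/post-induction comparisons of subpopulation composition and scores.

Fraction shifts are tested per subpopulation with the two-sided
Fisher's exact test on the 2x2 table (in-subpopulation vs not) x
(pre vs post); the two-sided p sums the probabilities of all tables
with point probability <= the observed one (the minimum-likelihood
convention).  Per-cell score or entropy shifts use the same Wilcoxon
rank-sum engine as differential expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = ["fraction_shift_test", "score_shift_test", "DEFAULT_STARS"]

DEFAULT_STARS = {"*": 0.05, "**": 0.01, "***": 0.001}


def _stars(p: float, star_map: dict[str, float]) -> str:
    best = ""
    for stars, cutoff in sorted(star_map.items(), key=lambda kv: -kv[1]):
        if p < cutoff:
            best = stars
    return best


def fraction_shift_test(labels_pre, labels_post,
                        star_map: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-subpopulation Fisher's exact test of the pre vs post fraction.

    Returns a DataFrame indexed by subpopulation with counts, fractions,
    the sample odds ratio ((a/b)/(c/d) of the 2x2 table), the two-sided
    p-value, and significance stars (default * <0.05, ** <0.01,
    *** <0.001; the map is configurable since figure-legend conventions
    vary).
    """
    labels_pre = np.asarray(labels_pre)
    labels_post = np.asarray(labels_post)
    if len(labels_pre) == 0 or len(labels_post) == 0:
        raise ValueError("both label vectors must be non-empty")
    star_map = DEFAULT_STARS if star_map is None else star_map
    n_pre, n_post = len(labels_pre), len(labels_post)
    subpops = sorted(set(labels_pre) | set(labels_post))
    rows = []
    for sp in subpops:
        a = int((labels_post == sp).sum())  # in subpop, post
        b = n_post - a
        c = int((labels_pre == sp).sum())   # in subpop, pre
        d = n_pre - c
        if a + c == 0:
            logger.info("subpopulation %r absent from both conditions; skipped", sp)
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({
            "subpop": sp,
            "count_pre": c,
            "count_post": a,
            "fraction_pre": c / n_pre,
            "fraction_post": a / n_post,
            "odds_ratio": float(odds),
            "p_value": float(p),
            "stars": _stars(float(p), star_map),
        })
    return pd.DataFrame(rows).set_index("subpop")


def score_shift_test(scores_pre, scores_post) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum on per-cell scores or entropies.

    Returns (U statistic for the pre sample, p, direction) where
    direction reports whether the post median is higher, lower, or
    unchanged.  NaNs are dropped; a constant pooled vector gives p = 1.
    """
    pre = np.asarray(scores_pre, dtype=float)
    post = np.asarray(scores_post, dtype=float)
    pre = pre[~np.isnan(pre)]
    post = post[~np.isnan(post)]
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("both score vectors need at least 2 finite values")
    stat, p = wilcoxon_rank_sum(pre, post)
    diff = np.median(post) - np.median(pre)
    direction = "up" if diff > 0 else ("down" if diff < 0 else "unchanged")
    return stat, p, direction
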