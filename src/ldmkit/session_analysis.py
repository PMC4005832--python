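"""Session-level summaries and comparisons of performance indices.

Training effects are assessed with a paired t-test on post-minus-pre
differences per index; the accuracy of the operator's spot-size estimate
is assessed with a one-sample t-test of mu against the physical
laser-window side; techniques are compared pairwise per subject with
differences taken relative to the SBS technique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from .exceptions import MissingPairsError
from .indices import PerformanceIndices

__all__ = [
    "SessionRecord",
    "ComparisonResult",
    "paired_comparison",
    "one_sample_comparison",
    "feedback_comparison",
    "technique_comparison",
    "INDEX_NAMES",
]

#: Index columns used by session-level comparisons.
INDEX_NAMES = ("delta0", "deltaz", "mu", "upsilon")


@dataclass(frozen=True)
class SessionRecord:
    """One recorded (or simulated) session and its indices."""

    session_id: str
    subject: str
    technique: str          # "sbs" | "sliding"
    feedback_phase: str     # "pre" | "post"
    indices: PerformanceIndices


@dataclass(frozen=True)
class ComparisonResult:
    """Mean difference and two-sided t-test for one index."""

    index_name: str
    mean_difference: float
    sd_difference: float
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False  # zero-variance differences


def _t_test(diffs: np.ndarray, index_name: str) -> ComparisonResult:
    n = diffs.size
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        # all differences identical: report the forced outcome with a flag
        if mean == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float(np.sign(mean)) * np.inf, 0.0
        return ComparisonResult(index_name, mean, sd, t_stat, p, n, degenerate=True)
    t_stat = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    return ComparisonResult(index_name, mean, sd, float(t_stat), float(p), n)


def paired_comparison(
    pre: Sequence[float], post: Sequence[float], index_name: str = "index"
) -> ComparisonResult:
    """Two-sided paired t-test on post - pre differences."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if pre.size < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    return _t_test(post - pre, index_name)


def one_sample_comparison(
    values: Sequence[float], reference: float, index_name: str = "index"
) -> ComparisonResult:
    """Two-sided one-sample t-test of mean(values) against ``reference``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("one-sample comparison needs at least 2 values")
    return _t_test(values - float(reference), index_name)


def _index_value(record: SessionRecord, name: str) -> float:
    return record.indices.as_dict()[name]


def feedback_comparison(
    records: Sequence[SessionRecord], technique: str
) -> Dict[str, ComparisonResult]:
    """Per-index paired pre/post comparison for one technique.

    Differences follow the post - pre convention, so a negative mean for
    delta0 means omissions decreased after feedback.
    """
    pre = {r.subject: r for r in records
           if r.technique == technique and r.feedback_phase == "pre"}
    post = {r.subject: r for r in records
            if r.technique == technique and r.feedback_phase == "post"}
    subjects = sorted(pre.keys() & post.keys())
    absent = sorted(pre.keys() ^ post.keys())
    if absent:
        raise MissingPairsError(
            f"subjects missing a pre or post session: {absent}"
        )
    return {
        name: paired_comparison(
            [_index_value(pre[s], name) for s in subjects],
            [_index_value(post[s], name) for s in subjects],
            index_name=name,
        )
        for name in INDEX_NAMES
    }


def technique_comparison(
    records: Sequence[SessionRecord],
    phase: str,
    reference_technique: str = "sbs",
) -> Dict[str, ComparisonResult]:
    """Per-index paired comparison of techniques at one feedback phase.

    Differences are (other technique - reference technique) per subject;
    with the default reference this is sliding - SBS.
    """
    at_phase = [r for r in records if r.feedback_phase == phase]
    ref = {r.subject: r for r in at_phase if r.technique == reference_technique}
    other = {r.subject: r for r in at_phase if r.technique != reference_technique}
    subjects = sorted(ref.keys() & other.keys())
    absent = sorted(ref.keys() ^ other.keys())
    if absent:
        raise MissingPairsError(
            f"subjects missing one technique at phase {phase!r}: {absent}"
        )
    return {
        name: paired_comparison(
            [_index_value(ref[s], name) for s in subjects],
            [_index_value(other[s], name) for s in subjects],
            index_name=name,
        )
        for name in INDEX_NAMES
    }
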