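"""Probabilistic combination of evidence channels.

STRING-style scoring treats each evidence channel as an independent estimate
of the probability that a protein pair is functionally associated.  Channel
scores share a common prior ``p`` (the baseline probability that a random
pair is associated, default 0.041); combination removes the prior from each
channel, merges the prior-free probabilities with a noisy-OR, and re-adds the
prior:

    combined = p + (1 - p) * (1 - prod_i(1 - (s_i - p) / (1 - p)))

Direct and transferred evidence for the same pair are merged the same way,
channel by channel, before the cross-channel combination.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .errors import InvalidArgumentError
from .model import CHANNELS, DEFAULT_PRIOR, EvidenceVector


def _check_prior(p: float) -> None:
    if not 0.0 <= p < 1.0:
        raise InvalidArgumentError(f"prior must be in [0, 1), got {p}")


def correct_for_prior(s: float, p: float = DEFAULT_PRIOR) -> float:
    """Remove the prior from a single channel score.

    Returns ``max(0, (s - p) / (1 - p))``: a score at or below the prior
    carries no evidence; a score of 1 stays 1 for any prior.
    """
    _check_prior(p)
    if not 0.0 <= s <= 1.0:
        raise InvalidArgumentError(f"score must be in [0, 1], got {s}")
    return max(0.0, (s - p) / (1.0 - p))


def combine_channels(ev: EvidenceVector, p: float = DEFAULT_PRIOR) -> float:
    """Combine channel scores into one confidence.

    Noisy-OR of the prior-corrected channel scores, with the prior re-added.
    Equals ``p`` for empty evidence and is monotone non-decreasing in every
    channel.
    """
    _check_prior(p)
    prod = 1.0
    for ch in CHANNELS:
        s = ev.get(ch)
        if s > 0.0:
            prod *= 1.0 - correct_for_prior(s, p)
    return p + (1.0 - p) * (1.0 - prod)


def merge_sources(scores: Iterable[float], p: float = DEFAULT_PRIOR) -> float:
    """Noisy-OR of several same-channel scores from independent sources.

    If no source exceeds the prior there is nothing to combine (every
    prior-corrected contribution is 0); the merge then degenerates to the
    maximum of the sources rather than re-adding the prior, so that a lone
    sub-prior score passes through unchanged.
    """
    _check_prior(p)
    scores = list(scores)
    supra = [s for s in scores if correct_for_prior(s, p) > 0.0]
    if len(supra) <= 1:
        # nothing to combine: a lone effective source passes through exactly
        return max(scores, default=0.0)
    prod = 1.0
    for s in supra:
        prod *= 1.0 - correct_for_prior(s, p)
    return p + (1.0 - p) * (1.0 - prod)


def aggregate_evidence(
    direct: EvidenceVector,
    transferred: Sequence[EvidenceVector] = (),
    p: float = DEFAULT_PRIOR,
) -> tuple[EvidenceVector, float]:
    """Merge direct evidence with orthology-transferred evidence.

    Each channel is merged across all sources (direct first, then each
    transferred vector) with a within-channel noisy-OR of prior-corrected
    scores; the merged vector is then combined across channels.

    Returns ``(merged_vector, combined_score)``.  The merged score never
    falls below the direct score in any channel.

    A channel for which every source is 0 stays 0 (rather than being pulled
    up to the prior): absence of evidence is not evidence.
    """
    _check_prior(p)
    merged: dict[str, float] = {}
    for ch in CHANNELS:
        sources = [direct.get(ch)] + [t.get(ch) for t in transferred]
        if any(s > 0.0 for s in sources):
            merged[ch] = merge_sources(sources, p)
    vec = EvidenceVector(merged)
    return vec, combine_channels(vec, p)
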