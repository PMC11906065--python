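"""Jaccard-index evaluation of delineated region masks against references.

The Jaccard index J(A, B) = |A∩B| / |A∪B| scores the overlap of two pixel
sets; 1 means identical, 0 disjoint.  The batch evaluator compares the two
predicted region masks of each video against a reference pair, resolving
the arbitrary region numbering by the pairing that maximizes total Jaccard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from icgmargin.exceptions import DomainError, ValidationError
from icgmargin.margination import MarginationResult
from icgmargin.video_io import BinaryMask

logger = logging.getLogger(__name__)


@dataclass
class JaccardReport:
    """Per-(video, chamber) Jaccard scores with summary statistics."""

    per_chamber: list[tuple[int, int, float]]  # (video id, chamber id, jaccard)
    mean: float
    min: float
    max: float

    def scores(self) -> np.ndarray:
        return np.array([s for _, _, s in self.per_chamber])


def jaccard(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """|A∩B| / (|A| + |B| − |A∩B|) for two same-shape binary masks."""
    ga = a.grid if isinstance(a, BinaryMask) else np.asarray(a)
    gb = b.grid if isinstance(b, BinaryMask) else np.asarray(b)
    if ga.shape != gb.shape:
        raise ValidationError(f"mask shapes differ: {ga.shape} vs {gb.shape}")
    ga = ga.astype(bool)
    gb = gb.astype(bool)
    inter = int(np.count_nonzero(ga & gb))
    union = int(np.count_nonzero(ga)) + int(np.count_nonzero(gb)) - inter
    if union == 0:
        raise DomainError("Jaccard undefined for two empty masks")
    return inter / union


def _pair_masks(pred: tuple[BinaryMask, BinaryMask], ref: tuple[BinaryMask, BinaryMask]):
    """Best assignment of 2 predicted to 2 reference masks by total Jaccard."""

    def safe_j(x: BinaryMask, y: BinaryMask) -> float:
        try:
            return jaccard(x, y)
        except DomainError:  # both empty: no overlap information
            return 0.0

    identity = (safe_j(pred[0], ref[0]), safe_j(pred[1], ref[1]))
    swapped = (safe_j(pred[0], ref[1]), safe_j(pred[1], ref[0]))
    if sum(swapped) > sum(identity):
        return swapped
    if sum(swapped) == sum(identity) and identity != swapped:
        logger.warning("ambiguous chamber pairing; keeping identity assignment")
    return identity


def evaluate_batch(
    predictions: Sequence[MarginationResult | tuple[BinaryMask, BinaryMask]],
    references: Sequence[tuple[BinaryMask, BinaryMask]],
) -> JaccardReport:
    """Score predicted region-mask pairs against reference pairs, per video.

    ``predictions`` may be :class:`MarginationResult` objects (their two
    chamber masks are used; margin-band pixels are excluded by
    construction) or explicit mask pairs.  Region numbering is arbitrary,
    so each video's pairing is resolved by maximal total Jaccard; an exact
    tie keeps the identity pairing and logs a warning.
    """
    if len(predictions) != len(references):
        raise ValidationError("predictions and references must be index-aligned")
    per: list[tuple[int, int, float]] = []
    for vid, (p, r) in enumerate(zip(predictions, references)):
        if isinstance(p, MarginationResult):
            pair = (p.chamber1_mask, p.chamber2_mask)
        else:
            pair = p
        j1, j2 = _pair_masks(pair, tuple(r))
        per.append((vid, 0, j1))
        per.append((vid, 1, j2))
    scores = np.array([s for _, _, s in per])
    return JaccardReport(
        per_chamber=per,
        mean=float(scores.mean()),
        min=float(scores.min()),
        max=float(scores.max()),
    )
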