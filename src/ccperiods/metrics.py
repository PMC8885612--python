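"""CPR quality metrics and segmentation agreement.

Chest compression fraction (CCF) is the fraction of the arrest interval —
from the annotated Arrest time to ROSC or termination — during which chest
compressions are delivered.  :func:`compare` quantifies how well an
algorithmic segmentation reproduces a manual annotation: like-kind period
boundaries are matched one-to-one within a tolerance (0.5 s by default,
the bound beyond which dissenting human annotations are re-assessed in
consensus), and the covered-time overlap is summarized as a Jaccard index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Segmentation

DEFAULT_TOLERANCE_S = 0.5


@dataclass(frozen=True)
class AgreementReport:
    """Boundary-level and interval-level agreement of two segmentations."""

    #: (algorithm time, annotation time, signed deviation alg - ann), seconds.
    matched_pairs: tuple[tuple[float, float, float], ...]
    unmatched_alg: int
    unmatched_ann: int
    #: |intersection| / |union| of compression-covered time, in [0, 1].
    overlap_fraction: float

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)

    @property
    def deviations(self) -> np.ndarray:
        return np.array([m[2] for m in self.matched_pairs])

    @property
    def match_fraction(self) -> float:
        """Fraction of annotated boundaries that found a match."""
        total_ann = self.n_matched + self.unmatched_ann
        return self.n_matched / total_ann if total_ann else 1.0


def ccf(seg: Segmentation, t_arrest: float, t_end: float) -> float:
    """Chest compression fraction over the window ``[t_arrest, t_end]``.

    Periods partially outside the window are clipped, not dropped.
    """
    if not t_end > t_arrest:
        raise ValueError("t_end must be greater than t_arrest")
    covered = 0.0
    for a, b in seg:
        covered += max(0.0, min(b, t_end) - max(a, t_arrest))
    return covered / (t_end - t_arrest)


def _intersection_time(x: Segmentation, y: Segmentation) -> float:
    total = 0.0
    for a, b in x:
        for c, d in y:
            total += max(0.0, min(b, d) - max(a, c))
    return total


def _overlap_fraction(x: Segmentation, y: Segmentation) -> float:
    inter = _intersection_time(x, y)
    union = x.total_time + y.total_time - inter
    return inter / union if union > 0 else 1.0


def _match_boundaries(
    alg: np.ndarray, ann: np.ndarray, tolerance_s: float
) -> list[tuple[float, float, float]]:
    """Greedy one-to-one matching by ascending |deviation|, ties by earlier
    annotation time."""
    pairs = [
        (abs(alg[i] - ann[j]), ann[j], i, j)
        for i in range(len(alg))
        for j in range(len(ann))
        if abs(alg[i] - ann[j]) <= tolerance_s
    ]
    pairs.sort(key=lambda p: (p[0], p[1]))
    used_alg: set[int] = set()
    used_ann: set[int] = set()
    matched = []
    for _, _, i, j in pairs:
        if i in used_alg or j in used_ann:
            continue
        used_alg.add(i)
        used_ann.add(j)
        matched.append((float(alg[i]), float(ann[j]), float(alg[i] - ann[j])))
    matched.sort(key=lambda p: p[1])
    return matched


def compare(
    alg: Segmentation, ann: Segmentation, tolerance_s: float = DEFAULT_TOLERANCE_S
) -> AgreementReport:
    """Agreement between an algorithmic and an annotated segmentation.

    Start markers only match start markers and stops only stops; matching
    is greedy nearest-neighbour within ``tolerance_s`` and one-to-one.
    Deviations are signed as algorithm minus annotation.
    """
    matched: list[tuple[float, float, float]] = []
    for alg_b, ann_b in ((alg.starts, ann.starts), (alg.stops, ann.stops)):
        matched.extend(_match_boundaries(alg_b, ann_b, tolerance_s))
    n_alg = 2 * len(alg)
    n_ann = 2 * len(ann)
    return AgreementReport(
        matched_pairs=tuple(matched),
        unmatched_alg=n_alg - len(matched),
        unmatched_ann=n_ann - len(matched),
        overlap_fraction=_overlap_fraction(alg, ann),
    )
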