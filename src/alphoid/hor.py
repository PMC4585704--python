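"""Higher-order repeat (HOR) periodicity over the ordered monomers of an array.

The profile generalizes a dot plot: d[k] is the mean p-distance between
monomers i and i+k (monomers globally aligned pairwise, gap and ambiguous
columns removed, so the 18-bp insertion of extra-long monomers never
inflates a distance).  A period k is called when d[k] is below an absolute
ceiling sitting between within-HOR divergence (<~6%) and monomeric
divergence (>~10%), and dominates the off-period background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import DEFAULT_PARAMS
from .core import AlignParams, Monomer
from .phylo import pairwise_p_distance

log = logging.getLogger(__name__)

_LABELS = {
    1: "monomeric",
    2: "dimeric",
    3: "trimeric",
    4: "tetrameric",
    5: "pentameric",
    6: "hexameric",
    7: "heptameric",
    8: "octameric",
}


@dataclass
class HORParams:
    max_dist: float = 0.10
    dominance: float = 0.5
    min_units: int = 2


@dataclass
class PeriodicityProfile:
    n: int
    d: dict[int, float]
    matrix: np.ndarray  # full pairwise monomer distance matrix (dot-plot data)


@dataclass
class HORCall:
    period: int | None
    label: str
    d_at_period: float | None
    n_units: int


def periodicity_profile(
    monomers: list[Monomer | str], params: AlignParams = DEFAULT_PARAMS
) -> PeriodicityProfile:
    """Mean distance per monomer offset, plus the full distance matrix."""
    seqs = [m.sequence if isinstance(m, Monomer) else m for m in monomers]
    n = len(seqs)
    if n < 4:
        raise ValueError(f"insufficient monomers for a periodicity profile ({n} < 4)")
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = pairwise_p_distance(seqs[i], seqs[j], params)
    d = {
        k: float(np.mean([matrix[i, i + k] for i in range(n - k)]))
        for k in range(1, n // 2 + 1)
    }
    return PeriodicityProfile(n=n, d=d, matrix=matrix)


def call_hor(profile: PeriodicityProfile, params: HORParams | None = None) -> HORCall:
    """Smallest qualifying period; arrays without one are monomeric.

    A period k qualifies when d[k] <= max_dist, d[k] <= dominance x the
    median of d over offsets that are not multiples of k, and at least
    min_units full units fit.  Because d at any multiple of a perfect
    period is also ~0, the smallest-k rule returns the fundamental period.
    """
    params = params or HORParams()
    n = profile.n
    for k in sorted(profile.d):
        if n // k < params.min_units:
            continue
        dk = profile.d[k]
        if dk > params.max_dist:
            continue
        off = [v for j, v in profile.d.items() if j % k != 0]
        if off and dk > params.dominance * float(np.median(off)):
            continue
        label = _LABELS.get(k, f"other({k})")
        return HORCall(period=k, label=label, d_at_period=dk, n_units=n // k)
    if n < 2 * max(2, params.min_units):
        log.warning("too few monomers to satisfy min_units for any k >= 2")
    return HORCall(period=None, label="monomeric", d_at_period=None, n_units=0)
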