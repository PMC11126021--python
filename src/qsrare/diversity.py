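"""Diversity indices for quasispecies haplotype tables.

Hill numbers of order q,

    qD(p) = (sum_i p_i^q)^(1/(1-q)),

interpolate between richness (q=0), the exponential of Shannon entropy
(q=1, as a limit), the inverse Simpson concentration (q=2) and the inverse
of the dominant-haplotype frequency (q=inf).  As q grows, rare haplotypes
weigh less, so sensitivity to sample size decreases with q — the basis for
the sensitivity ranking implemented here.

Also provided are the quasispecies-specific read-fraction statistics:
singleton fraction, aggregated read fraction between frequency limits
(the rare-haplotype-load / fitness-fraction family) and the fraction of
reads in replicated non-top haplotypes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import FrequencyVector, HaplotypeTable, frequencies


def _as_p(x) -> np.ndarray:
    if isinstance(x, HaplotypeTable):
        return frequencies(x).p
    if isinstance(x, FrequencyVector):
        return x.p
    return np.asarray(x, dtype=float)


def hill_number(p, q: float) -> float:
    """Hill number (effective number of haplotypes) of order `q` >= 0.

    q may be ``math.inf``; q=1 is evaluated as the limit exp(Shannon).
    """
    p = _as_p(p)
    if q < 0:
        raise ValueError(f"Hill order q must be >= 0, got {q}")
    if math.isinf(q):
        return 1.0 / float(p.max())
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(math.exp(shannon(p)))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def shannon(p, base: float = math.e) -> float:
    """Shannon entropy −Σ p_i log p_i, in nats by default."""
    p = _as_p(p)
    h = -float(np.sum(p * np.log(p)))
    if base != math.e:
        h /= math.log(base)
    return h


def gini_simpson(p) -> float:
    """Gini–Simpson index 1 − Σ p_i² (probability two reads differ)."""
    p = _as_p(p)
    return 1.0 - float(np.sum(p * p))


def master_frequency(p) -> float:
    """Frequency of the dominant (master) haplotype, max p_i."""
    return float(_as_p(p).max())


def richness(t: HaplotypeTable) -> int:
    """Number of observed haplotypes, H."""
    return t.H


def singleton_fraction(t: HaplotypeTable) -> float:
    """Fraction of reads in singleton haplotypes (count exactly 1)."""
    return float(np.count_nonzero(t.counts == 1)) / t.N


def fraction_between(t: HaplotypeTable, lower: float, upper: float) -> float:
    """Aggregated read fraction of haplotypes with lower <= p_i < upper.

    The half-open convention means a haplotype sitting exactly at `upper`
    is excluded (so a 1%-haplotype is not "below 1%"); the single exception
    is upper == 1, which is inclusive so that (0, 1] covers everything.
    With upper 0.01 or 0.001 this is the rare haplotype load (RHL);
    arbitrary limits give the fitness-fraction family.
    """
    if not (0.0 <= lower < upper <= 1.0):
        raise ValueError(f"require 0 <= lower < upper <= 1, got [{lower}, {upper})")
    p = frequencies(t).p
    mask = (p >= lower) & ((p < upper) | ((upper == 1.0) & (p <= 1.0)))
    return float(p[mask].sum())


def over1_below_topK(t: HaplotypeTable, K: int) -> float:
    """Read fraction of replicated haplotypes outside the top `K`.

    Sums count_i/N over haplotypes with count >= 2 that are not among the K
    largest counts (count descending, ties by ascending ID).  With K=6 on a
    prominent-haplotypes sample this isolates replicated singletons, the
    artifact of subsampling with replacement.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if K > t.H:
        warnings.warn(
            f"K={K} exceeds the number of haplotypes H={t.H}; returning 0",
            stacklevel=2,
        )
        return 0.0
    rest = t.canonical_order()[K:]
    c = t.counts[rest]
    return float(c[c >= 2].sum()) / t.N


@dataclass(frozen=True)
class DiversityProfile:
    """Hill numbers over a grid of orders plus the named classical indices."""

    q_grid: tuple
    D: tuple
    named: dict

    def as_dict(self) -> dict:
        out = {f"hill_q{q:g}": d for q, d in zip(self.q_grid, self.D)}
        out.update(self.named)
        return out


DEFAULT_Q_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, math.inf)


def diversity_profile(t: HaplotypeTable, q_grid=DEFAULT_Q_GRID) -> DiversityProfile:
    """Compute the Hill-number profile and named indices for one sample."""
    p = frequencies(t).p
    D = tuple(hill_number(p, q) for q in q_grid)
    named = {
        "richness": float(t.H),
        "shannon": shannon(p),
        "gini_simpson": gini_simpson(p),
        "master_frequency": master_frequency(p),
        "singleton_fraction": singleton_fraction(t),
    }
    return DiversityProfile(tuple(q_grid), D, named)


_SENSITIVITY_INDICES = ("richness", "shannon", "gini_simpson", "master_frequency")


def sensitivity_rank(
    t: HaplotypeTable,
    fractions: Sequence[float],
    scheme: str = "with_replacement",
    cycles: int = 500,
    seed: int = 0,
) -> list[str]:
    """Rank diversity indices by sensitivity to subsample size.

    Each classical index is mapped to its Hill-number counterpart
    (richness = 0D, exp(Shannon) = 1D, inverse Simpson 1/(1-G) = 2D,
    inverse master frequency = infD), which puts all four on one common
    "effective number of haplotypes" scale.  For each, the relative
    absolute bias of the B-cycle median at each subsampling fraction versus
    the full-sample value is averaged over fractions; indices are returned
    most-biased first.  On quasispecies with a substantial rare tail this
    recovers richness > shannon > gini_simpson > master_frequency, the
    decreasing-in-q sensitivity of the Hill family.
    """
    from .resampling import SubsampleSpec, repeated_subsample

    if t.H < 2:
        raise ValueError("sensitivity ranking is undefined for a single-haplotype table")
    p = frequencies(t).p
    reference = {
        "richness": float(t.H),
        "shannon": math.exp(shannon(p)),
        "gini_simpson": 1.0 / (1.0 - gini_simpson(p)),
        "master_frequency": 1.0 / master_frequency(p),
    }
    stats = {
        "richness": lambda s: float(s.H),
        "shannon": lambda s: math.exp(shannon(s)),
        "gini_simpson": lambda s: 1.0 / (1.0 - gini_simpson(s)),
        "master_frequency": lambda s: 1.0 / master_frequency(s),
    }
    bias = {name: 0.0 for name in _SENSITIVITY_INDICES}
    for f in fractions:
        spec = SubsampleSpec(fraction=f, scheme=scheme, cycles=cycles, seed=seed)
        summary = repeated_subsample(t, spec, stats)
        for name in _SENSITIVITY_INDICES:
            med = summary.stats.loc[name, "median"]
            bias[name] += abs(med - reference[name]) / abs(reference[name])
    for name in bias:
        bias[name] /= len(fractions)
    return sorted(_SENSITIVITY_INDICES, key=lambda n: -bias[n])
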