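"""Parametric generators for the five benchmark quasispecies structures.

Each generator builds a deterministic :class:`~qsrare.model.HaplotypeTable`
(no RNG involved): the structures themselves are exact by construction and
all randomness enters later through resampling.

The five structures span the spectrum of quasispecies composition seen in
amplicon studies:

* ``all_singletons`` — every haplotype has one read; the most fragile
  structure under bootstrap-style subsampling.
* ``single_dominant`` — one master haplotype plus a sea of singletons.
* ``prominent`` — a geometric ladder of prominent haplotypes (each at half
  the frequency of the preceding one) over a singleton tail.
* ``no_rare`` — a master plus a few equally frequent minors, no rare tail;
  robust under either subsampling scheme.
* ``flat`` — perfectly even, k reads per haplotype; models a sample after
  a low-level abundance filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import HaplotypeTable, ValidationError, make_table

#: Read counts of the six prominent haplotypes in the benchmark composition
#: (each at half the frequency of the preceding one, over 3077 singletons;
#: N = 100,000, H = 3083).
PROMINENT_COUNTS = (49231, 24615, 12308, 6154, 3077, 1538)
PROMINENT_SINGLETONS = 3077


def _hpl_ids(n: int, prefix: str = "hpl", width: int = 4) -> list[str]:
    width = max(width, len(str(n)))
    return [f"{prefix}_{i:0{width}d}" for i in range(1, n + 1)]


def _sng_ids(n: int) -> list[str]:
    return _hpl_ids(n, prefix="sng", width=6)


def _apportion(freqs: Sequence[float], N: int) -> list[int]:
    """Integer counts summing exactly to N, by largest-remainder rounding."""
    raw = [f * N for f in freqs]
    base = [math.floor(r) for r in raw]
    short = N - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def all_singletons(n: int) -> HaplotypeTable:
    """n haplotypes of one read each: H == N == n."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    return make_table(_sng_ids(n), [1] * n)


def single_dominant(N: int = 100_000, master_freq: float = 0.9) -> HaplotypeTable:
    """One master haplotype at `master_freq`; all remaining reads singletons.

    H = N - round(N*master_freq) + 1.
    """
    if not (0.0 < master_freq < 1.0):
        raise ValueError(f"master frequency must be in (0, 1), got {master_freq}")
    mc = round(N * master_freq)
    if mc < 1 or mc >= N:
        raise ValueError(
            f"master count {mc} leaves no room for singletons in N={N}"
        )
    n_sng = N - mc
    return make_table(["master"] + _sng_ids(n_sng), [mc] + [1] * n_sng)


def prominent(
    counts: Sequence[int] = PROMINENT_COUNTS,
    singletons: int = PROMINENT_SINGLETONS,
) -> HaplotypeTable:
    """A few prominent haplotypes (descending counts) over a singleton tail."""
    counts = list(counts)
    if any(c < 1 for c in counts):
        raise ValueError("prominent counts must be positive")
    if any(a < b for a, b in zip(counts, counts[1:])):
        raise ValueError("prominent counts must be non-increasing")
    if singletons < 0:
        raise ValueError("singletons must be >= 0")
    ids = _hpl_ids(len(counts)) + _sng_ids(singletons)
    return make_table(ids, counts + [1] * singletons)


def prominent_case() -> HaplotypeTable:
    """The benchmark prominent-haplotypes composition (N=100,000, H=3083)."""
    return prominent()


def no_rare(
    N: int = 100_000,
    master: float = 0.9,
    n_minor: int = 10,
    minor: float = 0.01,
) -> HaplotypeTable:
    """A master plus `n_minor` equal minors and no rare tail; H = 1 + n_minor."""
    total = master + n_minor * minor
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(
            f"frequencies must sum to 1: master {master} + {n_minor}x{minor} = {total}"
        )
    counts = _apportion([master] + [minor] * n_minor, N)
    if min(counts) < 1:
        raise ValidationError("every haplotype needs at least one read at this N")
    return make_table(["master"] + _hpl_ids(n_minor), counts)


def flat(n: int, k: int) -> HaplotypeTable:
    """n haplotypes of exactly k reads each: N = n*k, perfectly even."""
    if n < 1 or k < 1:
        raise ValueError(f"need n >= 1 and k >= 1, got n={n}, k={k}")
    return make_table(_hpl_ids(n), [k] * n)


_BUILDERS = {
    "all_singletons": all_singletons,
    "single_dominant": single_dominant,
    "prominent": prominent,
    "no_rare": no_rare,
    "flat": flat,
}

SCENARIO_KINDS = tuple(_BUILDERS)


@dataclass(frozen=True)
class ScenarioSpec:
    """Name + parameters for one benchmark structure; `build()` realizes it."""

    kind: str
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _BUILDERS:
            raise ValueError(
                f"unknown scenario {self.kind!r}; choose from {SCENARIO_KINDS}"
            )

    def build(self) -> HaplotypeTable:
        return _BUILDERS[self.kind](**dict(self.params))
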