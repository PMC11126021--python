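"""Subsampling engines and the repeated-resampling harness.

Two schemes are implemented on top of numpy's Generator primitives:

* **without replacement** — a multivariate hypergeometric draw over the
  haplotype counts, jointly equivalent to drawing a uniform random m-subset
  of the N reads.  This is classical rarefaction.
* **with replacement** — a multinomial draw of m reads with probabilities
  count_i/N, i.e. bootstrap-style subsampling from the empirical frequency
  distribution.

Both work in O(H) memory: the N-read vector is never materialized.

`repeated_subsample` runs B independent cycles and summarizes any set of
per-subsample statistics as median / IQR / SD / mean, the shape in which
repeated-rarefaction results are usually reported.  Cycle c draws from an
independent substream derived deterministically from (seed, c), so runs
are reproducible and order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import HaplotypeTable

Statistic = Callable[[HaplotypeTable], float]

SCHEMES = ("with_replacement", "without_replacement")


@dataclass(frozen=True)
class SubsampleSpec:
    """One resampling request: target size, scheme, number of cycles, seed.

    Exactly one of `fraction` (of the input library size, in (0, 1]) or
    `size` (absolute read count m) must be given.  With a fraction, the
    subsample size resolves to round(N * fraction) using round-half-even.
    """

    fraction: float | None = None
    size: int | None = None
    scheme: str = "without_replacement"
    cycles: int = 500
    seed: int = 0

    def __post_init__(self):
        if (self.fraction is None) == (self.size is None):
            raise ValueError("give exactly one of fraction= or size=")
        if self.fraction is not None and not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.size is not None and self.size < 1:
            raise ValueError(f"size must be >= 1, got {self.size}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")

    def resolve_size(self, N: int) -> int:
        """Subsample size m for a sample of N reads."""
        m = round(N * self.fraction) if self.fraction is not None else int(self.size)
        m = max(m, 1)
        if self.scheme == "without_replacement" and m > N:
            raise ValueError(
                f"cannot rarefy upward: requested m={m} from N={N} without replacement"
            )
        return m

    def cycle_rng(self, cycle: int) -> np.random.Generator:
        """Independent, reproducible substream for one cycle."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(cycle,))
        )


def _subtable(parent: HaplotypeTable, sub_counts: np.ndarray) -> HaplotypeTable:
    mask = sub_counts > 0
    seqs = None
    if parent.sequences is not None:
        seqs = tuple(s for s, keep in zip(parent.sequences, mask) if keep)
    return HaplotypeTable(parent.ids[mask], sub_counts[mask], seqs, validate=False)


def subsample_without_replacement(
    t: HaplotypeTable, m: int, rng: np.random.Generator
) -> HaplotypeTable:
    """Draw m reads from `t` without replacement (multivariate hypergeometric).

    The returned counts are jointly distributed as a uniform random m-subset
    of the N-read multiset; haplotypes drawn zero times are omitted.
    """
    if m < 1:
        raise ValueError(f"subsample size must be >= 1, got {m}")
    if m > t.N:
        raise ValueError(f"cannot draw m={m} reads without replacement from N={t.N}")
    sub = rng.multivariate_hypergeometric(t.counts, m)
    return _subtable(t, sub)


def subsample_with_replacement(
    t: HaplotypeTable, m: int, rng: np.random.Generator
) -> HaplotypeTable:
    """Draw m reads from `t` with replacement (multinomial on count_i/N)."""
    if m < 1:
        raise ValueError(f"subsample size must be >= 1, got {m}")
    sub = rng.multinomial(m, t.counts / t.N)
    return _subtable(t, sub)


_SAMPLERS = {
    "without_replacement": subsample_without_replacement,
    "with_replacement": subsample_with_replacement,
}


def _default_statistics() -> dict[str, Statistic]:
    from . import diversity

    return {
        "richness": lambda s: float(s.H),
        "shannon": lambda s: diversity.shannon(s),
        "master_frequency": lambda s: diversity.master_frequency(s),
    }


@dataclass
class ResamplingSummary:
    """Median/IQR/SD/mean of each statistic over B resampling cycles.

    `stats` is a DataFrame indexed by statistic name with columns
    median, IQR, SD, mean; `values` retains the raw per-cycle realizations.
    Quartiles use linear interpolation and SD the n-1 denominator.
    """

    spec: SubsampleSpec
    m: int
    table_digest: str
    stats: pd.DataFrame
    values: dict = field(repr=False, default_factory=dict)

    def median(self, name: str) -> float:
        return float(self.stats.loc[name, "median"])

    def to_records(self, sample: str = "") -> pd.DataFrame:
        """Flat serialization: one row per statistic with full metadata."""
        rows = []
        for name, row in self.stats.iterrows():
            rows.append(
                {
                    "sample": sample,
                    "statistic": name,
                    "scheme": self.spec.scheme,
                    "fraction": self.spec.fraction,
                    "m": self.m,
                    "B": self.spec.cycles,
                    "median": row["median"],
                    "IQR": row["IQR"],
                    "SD": row["SD"],
                    "mean": row["mean"],
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, sample: str = "") -> str:
        return json.dumps(self.to_records(sample).to_dict(orient="records"))


def _summarize(values: np.ndarray) -> dict[str, float]:
    q25, q75 = np.percentile(values, [25.0, 75.0])
    return {
        "median": float(np.median(values)),
        "IQR": float(q75 - q25),
        "SD": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "mean": float(np.mean(values)),
    }


def repeated_subsample(
    t: HaplotypeTable,
    spec: SubsampleSpec,
    statistics: Mapping[str, Statistic] | None = None,
) -> ResamplingSummary:
    """Run B independent subsampling cycles and summarize the statistics.

    Each statistic maps a HaplotypeTable to a real number and is evaluated
    on every cycle's subsample.  Deterministic given (t, spec).
    """
    if statistics is None:
        statistics = _default_statistics()
    m = spec.resolve_size(t.N)
    sampler = _SAMPLERS[spec.scheme]
    values = {name: np.empty(spec.cycles) for name in statistics}
    for c in range(spec.cycles):
        sub = sampler(t, m, spec.cycle_rng(c))
        for name, stat in statistics.items():
            try:
                values[name][c] = stat(sub)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise RuntimeError(
                    f"statistic {name!r} failed at cycle {c}: {exc}"
                ) from exc
    stats = pd.DataFrame({name: _summarize(v) for name, v in values.items()}).T
    stats = stats[["median", "IQR", "SD", "mean"]]
    return ResamplingSummary(spec, m, t.digest(), stats, values)


def rarefy_group(
    tables: Sequence[HaplotypeTable],
    reference_size: int | str = "min",
    *,
    scheme: str = "without_replacement",
    cycles: int = 500,
    seed: int = 0,
    statistics: Mapping[str, Statistic] | None = None,
    names: Sequence[str] | None = None,
) -> list[ResamplingSummary]:
    """Rarefy every sample to a common library size and summarize each.

    `reference_size="min"` uses the smallest library in the group.  Under
    without-replacement sampling, samples smaller than the reference cannot
    be rarefied and the call fails listing them — in a study design those
    are the candidates for rejection under a minimum-coverage rule.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no samples to rarefy")
    sizes = [t.N for t in tables]
    m = min(sizes) if reference_size == "min" else int(reference_size)
    if m < 1:
        raise ValueError(f"reference size must be >= 1, got {m}")
    if scheme == "without_replacement":
        labels = names if names is not None else [f"sample_{i}" for i in range(len(tables))]
        too_small = [lab for lab, n in zip(labels, sizes) if n < m]
        if too_small:
            raise ValueError(
                f"samples below the reference size {m} cannot be rarefied "
                f"without replacement: {', '.join(too_small)}"
            )
    spec = SubsampleSpec(size=m, scheme=scheme, cycles=cycles, seed=seed)
    return [repeated_subsample(t, spec, statistics) for t in tables]


def summaries_to_csv(
    summaries: Sequence[ResamplingSummary],
    path,
    names: Sequence[str] | None = None,
) -> None:
    """Write a group of summaries as one flat CSV."""
    if names is None:
        names = [f"sample_{i}" for i in range(len(summaries))]
    frames = [s.to_records(n) for s, n in zip(summaries, names)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
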