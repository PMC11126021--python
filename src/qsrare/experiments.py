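"""Orchestration: rebuild the benchmark result tables as DataFrames/CSVs.

Each ``run_*`` function generates its scenario, runs the analytic formulas
and/or the repeated-resampling harness, and returns tidy DataFrames shaped
like the corresponding benchmark tables.  Deterministic cells (True/Exact
rows, probability columns) come from closed forms; stochastic cells carry
the median over B resampling cycles, with (B, seed, scheme) recorded in the
output metadata so tolerances are explicit.

Everything is deterministic given one master seed: per-cell seeds are
derived from it via `numpy.random.SeedSequence`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import analytic, diversity, scenarios
from .model import HaplotypeTable
from .resampling import SubsampleSpec, repeated_subsample

TABLE2_FRACTIONS = tuple(f / 10 for f in range(1, 11))
GRID_FRACTIONS = (0.5, 0.25, 0.1, 0.05)
MASTER_FREQS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)
DEFAULT_B = 500


def _cell_seeds(seed: int, k: int) -> list[int]:
    """k reproducible 31-bit child seeds derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(k) % 2**31]


def _freq_of(hid: str):
    """Statistic: frequency of one haplotype by identity (0 if absent)."""

    def stat(s: HaplotypeTable) -> float:
        hit = s.counts[s.ids == hid]
        return float(hit[0]) / s.N if hit.size else 0.0

    return stat


def run_table1(fractions=TABLE2_FRACTIONS) -> pd.DataFrame:
    """Large-n seen/unseen proportions for with-replacement subsampling."""
    rows = [
        {
            "fraction": f,
            "seen": round(analytic.p_seen_fraction(f), 4),
            "unseen": round(1.0 - analytic.p_seen_fraction(f), 4),
        }
        for f in fractions
    ]
    return pd.DataFrame(rows)


def run_table2(
    n: int = 10_000,
    cycles: int = DEFAULT_B,
    seed: int = 0,
    fractions=TABLE2_FRACTIONS,
) -> pd.DataFrame:
    """All-singletons benchmark: with-replacement richness at each fraction.

    Columns: Frac, True (=m, what rarefaction would return), Expected
    (closed form), Median/IQR/SD of observed haplotypes over B cycles,
    Unique (median distinct / m) and Replicated (its complement).
    """
    t = scenarios.all_singletons(n)
    seeds = _cell_seeds(seed, len(fractions))
    rows = []
    for f, s in zip(fractions, seeds):
        spec = SubsampleSpec(
            fraction=f, scheme="with_replacement", cycles=cycles, seed=s
        )
        m = spec.resolve_size(t.N)
        summary = repeated_subsample(t, spec, {"richness": lambda x: float(x.H)})
        st = summary.stats.loc["richness"]
        unique = st["median"] / m
        rows.append(
            {
                "Frac": f,
                "True": m,
                "Expected": analytic.expected_richness_with(t, m),
                "Median": st["median"],
                "IQR": st["IQR"],
                "SD": st["SD"],
                "Unique": unique,
                "Replicated": 1.0 - unique,
            }
        )
    return pd.DataFrame(rows)


def run_single_dominant(
    cycles: int = DEFAULT_B,
    seed: int = 0,
    N: int = 100_000,
    masters=MASTER_FREQS,
    fractions=GRID_FRACTIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-dominant grid: richness and master frequency, both schemes.

    Returns (haplotype-number table, master-frequency table); rows are
    (scenario ID, fraction), columns the per-scheme medians and the exact
    reference ("Exact" is the rarefaction expectation for richness, the true
    master frequency for the frequency table).
    """
    seeds = iter(_cell_seeds(seed, 2 * len(masters) * len(fractions)))
    stats = {
        "hpl_no": lambda s: float(s.H),
        "master": lambda s: diversity.master_frequency(s),
    }
    hpl_rows, freq_rows = [], []
    for mf in masters:
        t = scenarios.single_dominant(N, mf)
        qid = f"Q.{round(mf * 100)}.{round((1 - mf) * 100)}"
        for f in fractions:
            med = {}
            m = None
            for scheme in ("without_replacement", "with_replacement"):
                spec = SubsampleSpec(
                    fraction=f, scheme=scheme, cycles=cycles, seed=next(seeds)
                )
                m = spec.resolve_size(t.N)
                med[scheme] = repeated_subsample(t, spec, stats).stats
            hpl_rows.append(
                {
                    "ID": qid,
                    "Subsz": f,
                    "NoRpl": med["without_replacement"].loc["hpl_no", "median"],
                    "WithRpl": med["with_replacement"].loc["hpl_no", "median"],
                    "Exact": analytic.expected_richness_without(t, m),
                }
            )
            freq_rows.append(
                {
                    "ID": qid,
                    "Subsz": f,
                    "NoRpl": med["without_replacement"].loc["master", "median"],
                    "WithRpl": med["with_replacement"].loc["master", "median"],
                    "Exact": mf,
                }
            )
    return pd.DataFrame(hpl_rows), pd.DataFrame(freq_rows)


def _prominent_stats(n_prominent: int = 6):
    stats = {"SngFr": lambda s: diversity.singleton_fraction(s)}
    for i in range(1, n_prominent + 1):
        stats[f"Hpl_{i}"] = _freq_of(f"hpl_{i:04d}")
    stats["Ov1"] = lambda s: diversity.over1_below_topK(s, n_prominent)
    return stats


def run_prominent(
    cycles: int = DEFAULT_B,
    seed: int = 0,
    fractions=GRID_FRACTIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prominent-haplotypes benchmark, per scheme (without, with replacement).

    Per fraction: median singleton read fraction, the six prominent
    frequencies, and Ov1 (reads in replicated haplotypes outside the top 6
    — the signature of with-replacement subsampling).  The first row holds
    the true full-sample values.
    """
    t = scenarios.prominent_case()
    stats = _prominent_stats()
    true_row = {"Subs": "True"}
    for name, stat in stats.items():
        true_row[name] = stat(t)
    seeds = iter(_cell_seeds(seed, 2 * len(fractions)))
    frames = []
    for scheme in ("without_replacement", "with_replacement"):
        rows = [dict(true_row)]
        for f in fractions:
            spec = SubsampleSpec(
                fraction=f, scheme=scheme, cycles=cycles, seed=next(seeds)
            )
            summary = repeated_subsample(t, spec, stats)
            row = {"Subs": f}
            for name in stats:
                row[name] = summary.stats.loc[name, "median"]
            rows.append(row)
        frames.append(pd.DataFrame(rows))
    return frames[0], frames[1]


def run_no_rare(
    cycles: int = DEFAULT_B,
    seed: int = 0,
    fractions=GRID_FRACTIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """No-rare benchmark, per scheme: haplotype number and all 11 frequencies."""
    t = scenarios.no_rare()
    stats = {"HplNo": lambda s: float(s.H), "Hpl_01": _freq_of("master")}
    for i in range(1, 11):
        stats[f"Hpl_{i + 1:02d}"] = _freq_of(f"hpl_{i:04d}")
    true_row = {"Subs": "True"}
    for name, stat in stats.items():
        true_row[name] = stat(t)
    seeds = iter(_cell_seeds(seed, 2 * len(fractions)))
    frames = []
    for scheme in ("without_replacement", "with_replacement"):
        rows = [dict(true_row)]
        for f in fractions:
            spec = SubsampleSpec(
                fraction=f, scheme=scheme, cycles=cycles, seed=next(seeds)
            )
            summary = repeated_subsample(t, spec, stats)
            row = {"Subs": f}
            for name in stats:
                row[name] = summary.stats.loc[name, "median"]
            rows.append(row)
        frames.append(pd.DataFrame(rows))
    return frames[0], frames[1]


def run_flat(
    n: int = 1000,
    ks=tuple(range(1, 11)),
    grid_n: int = 10_000,
    grid_fractions=TABLE2_FRACTIONS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flat-quasispecies closed forms.

    Returns (bootstrap probability table for n haplotypes across k;
    rarefaction-expectation grid over (k, f) at `grid_n` haplotypes;
    with/without expected-richness ratio over the same grid).
    """
    t11 = pd.DataFrame(
        {
            "nHpl": n,
            "k": k,
            "Reads": n * k,
            "Prob": round(analytic.flat_p_seen(analytic.FlatSpec(n, k)), 7),
            "Limit": round(analytic.flat_p_seen(analytic.FlatSpec(n, k), limit=True), 7),
        }
        for k in ks
    )
    fig5_rows, fig6_rows = [], []
    for k in ks:
        for f in grid_fractions:
            spec = analytic.FlatSpec(grid_n, k, f)
            e1 = analytic.flat_expected_richness_without(spec)
            fig5_rows.append({"k": k, "fraction": f, "expected_haplotypes": e1})
            fig6_rows.append(
                {"k": k, "fraction": f, "ratio": analytic.richness_ratio(spec)}
            )
    return t11, pd.DataFrame(fig5_rows), pd.DataFrame(fig6_rows)


#: Which artifact names run_all / the `tables` CLI subcommand can produce.
TABLE_RUNNERS = (
    "table1",
    "table2",
    "table4",
    "table5",
    "table7",
    "table8",
    "table9",
    "table10",
    "table11",
    "fig5",
    "fig6",
)


def run_all(
    outdir,
    which=TABLE_RUNNERS,
    cycles: int = DEFAULT_B,
    seed: int = 0,
) -> list[Path]:
    """Write the requested benchmark tables as CSVs under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    which = set(which)
    unknown = which - set(TABLE_RUNNERS)
    if unknown:
        raise ValueError(f"unknown tables: {sorted(unknown)}")
    produced: dict[str, pd.DataFrame] = {}
    if "table1" in which:
        produced["table1"] = run_table1()
    if "table2" in which:
        produced["table2"] = run_table2(cycles=cycles, seed=seed)
    if which & {"table4", "table5"}:
        t4, t5 = run_single_dominant(cycles=cycles, seed=seed)
        produced["table4"], produced["table5"] = t4, t5
    if which & {"table7", "table8"}:
        t7, t8 = run_prominent(cycles=cycles, seed=seed)
        produced["table7"], produced["table8"] = t7, t8
    if which & {"table9", "table10"}:
        t9, t10 = run_no_rare(cycles=cycles, seed=seed)
        produced["table9"], produced["table10"] = t9, t10
    if which & {"table11", "fig5", "fig6"}:
        t11, f5, f6 = run_flat()
        produced["table11"], produced["fig5"], produced["fig6"] = t11, f5, f6
    paths = []
    for name in sorted(which):
        path = outdir / f"{name}.csv"
        produced[name].to_csv(path, index=False)
        paths.append(path)
    return paths
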