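# Methods

## Model

A quasispecies sample is a count vector: H unique haplotypes with reads
c₁…c_H, library size N = Σcᵢ, frequencies pᵢ = cᵢ/N.  Sequences are never
interpreted; haplotype identity is the ID string.  Frequencies live on a
grid with step 1/N (the granularity of count data): at N = 1,000 the
resolution is 0.1%, which is why depths above ~100,000 reads are needed
when rare haplotypes are of interest.

## Subsampling schemes

*Without replacement* (classical rarefaction): the subsample of m reads is
a uniform random m-subset of the N-read multiset, so the joint count
vector is multivariate hypergeometric.  We draw it directly with
`numpy.random.Generator.multivariate_hypergeometric`, never materializing
the N-read vector (O(H) memory).  *With replacement*: m i.i.d. draws from
the empirical frequencies, i.e. a multinomial with probabilities cᵢ/N.

Closed forms used throughout:

- P(seen in a full bootstrap) = 1 − (1 − 1/n)ⁿ → 1 − 1/e ≈ 0.6321;
  fraction-f version 1 − (1 − 1/n)^{fn} → 1 − e^{−f}.
- Expected richness without replacement (the rarefaction equation):
  E₁ = Σᵢ [1 − C(N−cᵢ, m)/C(N, m)].
- Expected richness with replacement: E₂ = Σᵢ [1 − (1 − cᵢ/N)^m].
  For the flat case (all cᵢ = k) E₂ = n·[1 − (1 − 1/n)^{nkf}]; the bare
  per-haplotype probability is exposed separately (`flat_p_seen`).  The
  count form is the one used in the E₂/E₁ accuracy ratio, which is then
  dimensionless and ≤ 1.
- Var(p̂) = p(1−p)/n for a proportion, which explains why prominent
  haplotype frequencies are effectively invariant under subsampling at
  high depth.

Binomial-coefficient ratios are evaluated as compensated sums of
log((N−m−j)/(N−j)), j < cᵢ: exact to float precision for singletons
(giving m/N), overflow-free at N = 10⁷, and verified against exact
rational arithmetic on small instances to < 1e−12 relative error.

## Repeated resampling

`repeated_subsample` runs B independent cycles and reports median, IQR
(linear-interpolation quartiles), SD (n−1 denominator) and mean of each
statistic.  B defaults to 500.  Reproducibility contract: cycle c draws
from `SeedSequence(entropy=seed, spawn_key=(c,))`, so results are
deterministic given (table, spec) and independent of execution order.
Subsample size from a fraction is m = round(N·f) with round-half-even.
Group rarefaction refuses, by name, samples smaller than the reference
size under without-replacement sampling — those are rejection candidates
under a minimum-coverage study design.

## Diversity indices

Hill numbers ᑫD(p) = (Σ pᵢᑫ)^{1/(1−q)}, with q = 1 evaluated as
exp(−Σ pᵢ ln pᵢ) (the limit), q = 0 as richness and q = ∞ as 1/max pᵢ.
Shannon entropy is in nats by default (so ¹D = exp S exactly); the base is
a parameter.  Read-fraction statistics: singleton fraction (#{cᵢ = 1}/N),
`fraction_between(lower, upper)` summing pᵢ over lower ≤ pᵢ < upper
(upper = 1 inclusive so (0, 1] covers everything) — the rare-haplotype
load at upper 0.01 or 0.001 — and `over1_below_topK`, the read fraction of
haplotypes with ≥ 2 reads outside the K most abundant (count descending,
ID ascending tie-break), which isolates the replicated-singleton artifact
of with-replacement subsampling.

### Sensitivity ranking

`sensitivity_rank` orders richness, Shannon, Gini–Simpson and master
frequency by their dependence on subsample size.  All four are first
mapped to their Hill-number counterparts (⁰D, ¹D, ²D = 1/(1−G),
∞D = 1/master), putting them on one common effective-number scale; the
relative absolute bias of the B-cycle median versus the full-sample value
is then averaged over the requested fractions.  The common scale is what
makes the comparison meaningful and stable: on an index's raw scale the
systematic gap between the two least sensitive indices (order 1/m) is
smaller than the Monte-Carlo noise of a median at any practical B, and a
raw-scale ranking of that pair is essentially a coin flip.  On the
effective-number scale the ²D statistic carries roughly twice the (highly
correlated) per-cycle noise of ∞D plus a positive systematic term, so the
theoretical ordering richness > Shannon > Gini–Simpson > master frequency
is recovered reliably at B = 500.  Degenerate single-haplotype tables are
rejected (every reference value is trivial and the ranking undefined).

## Benchmark scenarios

The generators are deterministic (no RNG) and parameter defaults are the
benchmark study conditions:

| scenario | defaults | composition |
|---|---|---|
| `all_singletons` | n = 10,000 | H = N = n, all counts 1 |
| `single_dominant` | N = 100,000, master 0.1–0.9 | master + (N − master) singletons |
| `prominent` | counts 49231, 24615, 12308, 6154, 3077, 1538 + 3077 singletons | N = 100,000, H = 3083 |
| `no_rare` | N = 100,000, master 0.9, 10 minors at 1% | H = 11, no singletons |
| `flat` | n, k | n haplotypes × k reads |

`no_rare`'s N is not fixed by the structure itself; 100,000 was chosen for
consistency with the other deep-coverage scenarios.  Non-integral N·f
compositions are resolved by largest-remainder apportionment so counts sum
exactly to N.  IDs are stable and sortable ("master", "hpl_0001"…,
"sng_000001"…).

These structures are idealizations: real quasispecies data carry
sequencing error, platform-dependent abundance noise, and haplotype-calling
artifacts that no generator here emulates.  Passing tests therefore
demonstrate correctness of the resampling mathematics and its
implementation, not robustness of any pipeline to technical noise.

## Experiment runners and problem sizes

`experiments.run_*` rebuild the benchmark tables at their published
conditions: B = 500 cycles, fractions {0.5, 0.25, 0.1, 0.05} for the
scenario grids and {0.1, …, 1.0} for the all-singletons table, scenario
sizes as above.  Per-cell seeds derive from one master seed via
`SeedSequence.generate_state`, so a full reproduction run is deterministic
given a single integer.  Two known quirks of the published reference
values, which we do not force agreement with: the all-singletons
"Expected" column at f = 0.1 prints 952.1 where the formula
10,000·(1 − (1 − 10⁻⁴)^1000) gives 951.67 (likely a simulation mean); and
the single-dominant "Exact" richness column prints values that appear to
exclude the master haplotype (5000 where Σᵢ gives 5001.0) — we report the
unrounded Σᵢ expectation.

## Known limitations

- No extrapolation beyond the observed library size, and no
  coverage-based (as opposed to size-based) standardization.
- No unseen-richness estimators (Chao/ACE family); richness here is
  observed richness.
- Incidence-type indices that need sequence alignments (polymorphic
  sites, mutation frequency) are out of scope: the model carries no
  interpreted sequence information.
- The TSV header heuristic treats a non-numeric second field on line 1 as
  a header; a file whose first data row has a corrupt count and no header
  is silently shortened by one row.
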