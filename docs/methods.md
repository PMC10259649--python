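# Methods

## The moldiness index

A home's mold burden is summarized by the Environmental Relative
Moldiness Index over a fixed 36-species qPCR panel: the sum of common
logs of the 26 water-damage-associated (group 1) concentrations minus
the sum of common logs of the 10 outdoor-origin (group 2)
concentrations, all in cell equivalents per mg dust (CE/mg). The index
is linear in the per-species logs, which gives two identities the test
suite leans on: the cohort mean index equals the difference of the mean
group log-sums exactly (provided scores are computed per home first and
averaged afterwards — the averaging order this package uses for all
summary tables), and scaling every concentration tenfold shifts the
index by 26 − 10 = 16.

The panel is a closed vocabulary. Species names are matched verbatim
after whitespace trimming, missing columns are an error rather than an
imputation target, and the registry orders group 1 before group 2.

## Quantification model

Each assay carries a linear standard curve Ct = intercept +
slope·log₁₀(CE), inverted as CE = 10^((Ct − intercept)/slope). Defaults
are a 100 %-efficiency curve (slope −1/log₁₀ 2 ≈ −3.3219) with 1 CE
crossing threshold at the final cycle (40); real per-assay curves load
from JSON. Replicates are averaged on the linear CE scale — the
quantity that enters the index — not on the Ct scale, which would give
a geometric mean. Concentrations are normalized by the analyzed dust
mass (default 5 mg).

Extraction QC: each sample carries a fixed *Geotrichum candidum*
conidial spike added before DNA extraction. A recovery Ct more than 3
cycles (≈ 8-fold under a doubling curve) from its reference fails the
sample; values are still returned, flagged unreliable. The tolerance is
a configurable convention — no published acceptance number exists.

Non-detects are recorded as 0 and floored to 1 CE/mg *after* the per-mg
division (the pipeline asserts this order), so a log term for an absent
species contributes exactly 0 and the index is total. Flooring is
idempotent and preserves detection flags; floor-valued cells are treated
as censoring artifacts — they enter diversity proportions but not
richness.

## Diversity

Shannon H = −Σ pᵢ ln pᵢ over the 36 floored concentrations treated as
abundances (natural log, so H ≤ ln 36 ≈ 3.584), with equitability
H/ln 36 ∈ [0, 1]. Whether a survey's plotted "diversity index" is H or
the equitability cannot always be determined from a figure, so both are
reported, along with above-floor richness; H in nats is the headline
value, matching the usual alpha-diversity convention. An all-floor row
is legal and maximally even (H = ln 36, richness 0).

## Comparison battery

Per species, the two year-cohorts are compared by the two-sided
Wilcoxon rank-sum test. Floored qPCR data are tie-heavy, so the exact
mode enumerates the permutation null of the mid-rank sum over the
observed value multiset — a subset-sum dynamic program over doubled
mid-ranks (integers even under ties), with the two-sided p as the
probability of a rank sum at least as far from its null mean
n₁(n+1)/2 as observed. Auto mode enumerates when n₁+n₂ ≤ 12 and
otherwise uses the tie-corrected normal approximation with continuity
correction. The approximation tracks the exact p within 0.05 for
continuous data at n = 5+5 but can deviate by ~0.1 at mid-range p under
heavy ties; exactness under ties is what the enumeration mode is for.

Species p-values are Holm–Bonferroni adjusted across the family of
testable species (default: all 36 as one family; per-group families are
a switch). A species constant at the same value in both years carries
no information: it is marked `NM`, excluded from the family, and never
flagged. Group-level comparisons (group log-sums, index) use pooled
Student's t and are reported unadjusted. The battery is unpaired by
default — matching the named tests — with a paired (signed-rank) option
for the resampled-homes design.

Tukey HSD uses the Tukey–Kramer statistic q = |mᵃ − mᵇ| /
√(MSE/2·(1/nₐ+1/n_b)) on the one-way ANOVA mean square error, with
adjusted p from the studentized-range distribution (k groups, N − k
df). The compact letter display uses insert-and-absorb: start with one
column containing every group; for each significant pair, split each
column containing both members; absorb columns that become subsets.
This guarantees the biconditional "two groups share a letter iff their
pair is non-significant", which a brute-force pair audit re-checks on
every output. Zero-MSE layouts are flagged degenerate (distinct means →
all pairs significant); groups with n < 3 are listed as weakly informed.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
data: per (home, year, species), log₁₀ CE/mg ~ Normal(μₛ + effect, σₛ).
Defaults are the study layout of 20 homes in five regions (6, 5, 2, 5,
2) sampled in both years; water damage in regions 2 (two homes), 3 and
5 (one each); μₛ spread over 1–4 within each group (indoor panels span
orders of magnitude; keeping μ ≥ 1 puts baseline censoring at the
1 CE/mg floor below ~2.5 % at σ = 0.5); σ = 0.5 log₁₀ units (roughly
threefold per-home variability — no per-home variance is published, so
this is a generator choice, fixed once). Effects are multiplicative,
hence additive on log₁₀: damaged homes get ×10 on group-1 species in
the first year; every home gets ×3 on group-2 species in the second
year (the post-hurricane phylloplane bloom); remediation removes a
configurable fraction of the damage effect in year 2 (default all of
it). The closed form behind the effect-recovery tests: a fold-change f
on all 10 group-2 species shifts the expected group-2 log-sum by
10·log₁₀ f (4.77 for f = 3), minus a small censoring correction that is
negligible at these defaults.

Every draw comes from its own stream seeded by (seed, home index, year,
species index), so enlarging the panel or cohort never perturbs
existing draws, and a seed fully determines the cohort bit-for-bit.

What the generator does *not* emulate: within-home spatial structure,
species covariance, non-lognormal tails, home dropout between years,
and measurement error beyond the lognormal noise. Passing tests
therefore demonstrate that the pipeline recovers effects of the assumed
multiplicative form at the study's sample sizes — not that real dust
data satisfy those assumptions.

The outdoor spore-count series draws yearly log₁₀ counts at recorded
station means and SDs (4.6812/0.1417, 4.8593/0.1781, 4.7335/0.0895 for
the three years around the event), 50 counts per year (≈ weekly
readings). A caution established by the test battery: with these means,
the two flanking years differ by 0.052 log₁₀ — about 2.6 pairwise
standard errors at n = 50 — so Tukey separates them in roughly 15 % of
seeds, and the canonical "a b a" letter pattern recurs in about 17 of
20 seeds rather than reliably. A printed letter pattern from one
season's data is a single realization, not a reproducible event at
these effect sizes; the corresponding acceptance test documents this by
failing its ≥ 19/20 bar.

## Pipeline and problem sizes

A run validates inputs (aggregating every schema violation before
aborting), floors after per-mg normalization, scores, compares, and
writes CSV reports plus a manifest of SHA-256 checksums; identical
config and seed reproduce byte-identical reports. Stochastic
calibrations in the tests and acceptance script use 20 replicate seeds
of the 20-home cohort — large enough that the family-wise null
calibration (0 species flagged under the global null, expected ≥ 95 %
of seeds) and the bloom-recovery power (≥ 1 group-2 species flagged,
per-seed probability ≈ 0.99) are sharp, and small enough that the whole
battery runs in seconds.
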