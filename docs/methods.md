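# Methods

## Cohort definitions

Each live birth is classified on two independent axes: low birth weight
(LBW, birthweight < 2500 g; the 2500 g boundary itself is normal weight)
and preterm birth (PTB, gestational age < 37 completed weeks; 37 weeks
is term). The cross of the two axes gives four mutually exclusive groups
(LBW_pre, LBW_term, NBW_pre, NBW_term), so that LBW = LBW_term + LBW_pre
and PTB = LBW_pre + NBW_pre are exact partitions — an identity asserted
throughout the test suite.

Exclusions before any analysis: multiple births (plurality > 1, tallied
first) and records with a missing municipality, birthweight, gestational
age or maternal age. Gestational ages outside [20, 45] completed weeks
are treated as missing: values outside that window are not plausible for
a live birth, and silently keeping them would corrupt the preterm
classification. Sex and nationality are pass-through columns used only
in summary tables.

Maternal age is binned twice:

* **9 fine classes** for age standardization: ≤15, (15,20], …, (45,50],
  >50, right-closed throughout. The boundary age 50 falls in class 8;
  the top class is effectively >50. Every age maps to exactly one class.
* **3 coarse reporting strata** for stratified analyses: ≤20, (20,35],
  >35.

## Standardization

**Direct** (feeds the maps): ASRᵢ = Σₐ Wₐ·(Oᵢₐ/nᵢₐ) with reference
weights Wₐ either supplied or derived as the pooled age structure of the
analyzed data. When a municipality has no births in class a, the
denominator is imputed with 1e-4 (numerator stays 0), so the empty
stratum contributes zero rate mass rather than a division failure. The
imputation constant is exposed (`EMPTY_STRATUM_EPSILON`); imputing the
denominator rather than the rate is the only reading that leaves empty
strata unbiased at zero.

**Indirect** (feeds the clustering statistics, which need expected
counts): Eᵢ = Σₐ nᵢₐ·ρₐ with pooled rates ρₐ = ΣᵢOᵢₐ/Σᵢnᵢₐ, then a
multiplicative calibration Eᵢ ← Eᵢ·(ΣO/ΣE) so totals match exactly
(a no-op when ρ is internally derived). Oᵢ/Eᵢ is then a standardized
incidence ratio. Standardization is by maternal age only; stratified
analyses restrict the count table to the stratum's fine classes and
recompute ρ within stratum, so each analysis cell is standardized within
itself.

Report tables round half-up to 2 decimals (display only; computation is
always full precision), and render p-values at the Monte Carlo floor as
"< 0.001".

## Spatial structure

Distances are great-circle (haversine, sphere radius 6371.0 km) for
latitude/longitude input; synthetic layouts use planar km coordinates
with a `planar` metric flag, avoiding projection artifacts in recovery
tests. Two neighborhood constructions are available:

* **queen contiguity** (polygons): neighbors iff boundaries share at
  least one point — edge or corner; islands get an empty set and a
  logged warning;
* **k-nearest neighbors** (centroids, default k = 8), symmetrized by
  union; distance ties break by ascending municipality id, making the
  structure deterministic and order-invariant.

Queen is the natural smoothing neighborhood when polygons exist; k-NN is
the fallback for centroid-only geometries and is a config choice — with
only centroids available in most deployments, k-NN(8) is the pipeline
default.

## Empirical Bayes smoothing (EBSIR)

The smoother is the local (neighborhood) moment estimator of Marshall,
chosen over the global Clayton–Kaldor variant because shrinkage is
explicitly toward the *spatial* neighborhood mean; the global variant
remains available (`neighborhood="global"`) for comparison. With
D_i = N(i) ∪ {i} and rate-consistent pseudo-counts O*ⱼ = asrⱼ·nⱼ:

    m_i  = Σ_{D_i} O*ⱼ / Σ_{D_i} nⱼ
    s²_i = Σ_{D_i} nⱼ (asrⱼ − m_i)² / Σ_{D_i} nⱼ
    A_i  = max(0, s²_i − m_i/n̄_i)          n̄_i = mean denominator in D_i
    w_i  = A_i / (A_i + m_i/n_i)            (0 when both terms vanish)
    ebsir_i = m_i + w_i (asr_i − m_i)

The focal unit is included in its own neighborhood, which keeps m_i
defined when all neighbors are empty; negative variance components are
truncated at zero (full shrinkage), keeping w_i ∈ [0, 1]. Consequences
asserted as invariants: the smoothed value always lies between the raw
rate and the neighborhood mean; w_i is weakly increasing in n_i; a flat
rate surface is returned unchanged; on null simulations smoothing
reduces cross-municipality variance.

Quantile map classes place value v in class 1 + #{boundaries < v}, so
ties at a boundary fall to the lower class; a constant surface is all
class 1.

## Tango's general clustering test

C = r'Ar with rᵢ = Oᵢ/O₊ − Eᵢ/E₊ and the exponential kernel
aᵢⱼ = exp(−dᵢⱼ/λ). The kernel scale λ defaults to the median
nearest-neighbor distance — a data-driven scale matching the resolution
of the municipality system, used because no canonical value exists for
an arbitrary geography. C ≥ 0 (the kernel is positive semidefinite on a
metric) and C = 0 exactly when observed and expected shares coincide.
Significance is Monte Carlo rather than the chi-squared approximation:
replicates O⁽ʳ⁾ ~ Multinomial(O₊, E/E₊), p = (1 + #{C_sim ≥ C_obs})/(nsim+1),
default nsim = 999. Conditioning on the observed total reads
case-location resampling under the constant-risk null.

## Circular Poisson spatial scan

Window family: for each center, units sorted by centroid distance
(ties by id), nested prefixes while cumulative births stay within
`max_fraction` (default 0.5) of the total; duplicate member sets are
deduplicated. The one-sided high-rate LLR is computed for every window
(zero when the inside rate does not exceed the outside rate; x·ln x → 0
at zero counts); a low-rate mode exists behind `direction="low"` but is
off by default, since elevated-risk clusters are the reporting target.

Ranked reporting is greedy non-overlap: take the highest-LLR window,
drop every window sharing a municipality, repeat for n_report (default
3: MLC/SLC/TLC). Each reported window's p-value is
(1 + #{max-LLR over all windows in replicate ≥ LLR_window})/(nsim+1),
with replicates multinomial as above (default nsim = 1000, so the
attainable floor is 1/1001). Secondary clusters are compared against the
same null max-LLR distribution. Two relative risks are emitted: the
reported O_Z/E_Z (matching published cluster tables) and the
inside/outside Kulldorff-style ratio.

The implementation is vectorized (cumulative sums over the
distance-order matrix); correctness is pinned by an exhaustive
brute-force enumeration oracle on small instances, which the scan must
match exactly in both LLR and member set.

## Synthetic registry

The generator emulates the gross features of a national birth registry:
log-normal municipality totals (default median 400 births over a study
period, σ = 1.2, spanning >2 orders of magnitude), a 9-class maternal
age profile whose coarse shares are ≈2.2% / 76.5% / 21.3%, and
age-specific group rates shaped by a U-curve in maternal age
(multipliers 1.45…0.95…1.5) scaled so pooled proportions hit
LBW-term 5.23%, LBW-pre 3.00%, NBW-pre 1.74% (hence LBW 8.23%,
PTB 4.74%). Planted circular clusters multiply a chosen outcome's risk
inside a radius; overlapping clusters compound multiplicatively.

Two simulation paths exist. `simulate_cases` draws per-outcome counts
O_ia ~ Poisson(n_ia·ρₐ·RRᵢ) truncated at n_ia (truncation bias is
negligible at realistic rates). `simulate_birth_records` instead draws
one multinomial per stratum over the four outcome groups and expands it
to record level (birthweights and gestational ages drawn uniformly
within group-consistent ranges, e.g. LBW-term ∈ [1500, 2499] g at ≥ 37
weeks); the multinomial construction is what makes the partition
identities and the record/count agreement exact, which the Poisson path
cannot guarantee jointly. What the generator does **not** emulate:
spatially correlated denominators, secular trends, nationality
structure, multiple births beyond the plurality flag, or realistic
within-group birthweight distributions — so passing recovery tests
demonstrate statistical correctness of the methods, not performance on
real registry idiosyncrasies.

## Problem sizes and numerical choices

Test and acceptance simulations use 225-municipality grids (the scale at
which the scan's behaviour stabilizes while a full Monte Carlo run stays
interactive), 200 outer replicates for calibration checks and 100 for
recovery; these sizes were fixed as part of the study design. The null
rejection band [0.02, 0.09] is the binomial 95% envelope around 5% at
200 replicates, acknowledging the conservatism introduced by the
discrete Monte Carlo p. Comparisons against hand oracles use 1e-12
absolute tolerance; LLR/oracle agreement uses 1e-9 (accumulated float
error over cumulative sums). Per-cell seeds in the pipeline derive from
the run seed via a seed sequence, so cells are independent but the whole
bundle is reproducible bit-for-bit from config + seed alone (the
manifest records the config hash excluding the output directory).

## Known limitations

* The scan family is circular only — elongated or irregular clusters are
  recovered as circular approximations (visible in recovery tests as
  supersets diluting Jaccard overlap).
* Expected counts adjust for maternal age only; other covariates would
  require a regression-based scan, out of scope.
* The local EB smoother is a moment estimator, not a full spatial model
  (no BYM/CAR); its variance truncation can force full shrinkage in
  very homogeneous neighborhoods.
* Queen contiguity trusts the input polygons; invalid topology is not
  repaired.
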