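# Methods

This note documents the statistical model behind `admixkit`, the defaults
it ships with and why, the numerical choices that matter, and what the
bundled simulator does and does not emulate.

## Estimators

### Unbiased f-statistics

All statistics operate on per-population derived-allele counts *d* and
observed allele totals *n* at each site (so pseudo-haploid ancient calls
contribute *n* = 1 per sample, diploids *n* = 2; missing calls contribute
nothing).  With *p = d/n* and the unbiased heterozygosity
*h = p(1−p)·n/(n−1)*:

- per-site f2(A,B) = (a−b)² − h_a/n_a − h_b/n_b, usable when both
  populations have n ≥ 2;
- per-site f3(C;A,B) = (c−a)(c−b) − h_c/n_c, usable when n_C ≥ 2 and
  n_A, n_B ≥ 1 (only the squared-frequency term in C needs correcting);
- per-site f4(A,B;C,D) = (a−b)(c−d), usable when all n ≥ 1 (cross
  products of independent estimates need no correction).

f2/f3/f4 estimates are means over usable sites.  Patterson's D is a ratio
of sums over jointly usable sites:
D = Σ(w−x)(y−z) / Σ(w+x−2wx)(y+z−2yz), never a mean of per-site ratios.
The usable-site set is statistic-specific, so jackknife block weights
differ between statistics computed on the same data.

Representing pseudo-haploid samples with observed ploidy 1 (rather than
forcing homozygous-diploid codes through) is deliberate: the n−1
corrections then see the true number of sampled alleles and the
estimators stay unbiased for ancient samples.

### Weighted block jackknife

Variants are grouped into blocks of `target_size` (default 100)
consecutive variants; the block counter runs across chromosomes but no
block spans a chromosome boundary, and each chromosome's final block
keeps the remainder.  For block sums (N_j, D_j), usable-site weights m_j
(zero-weight blocks dropped, g surviving blocks, M = Σ m_j), whole-data
estimate θ̂ = ΣN/ΣD and leave-one-out estimates θ₍ⱼ₎:

- inverse weights h_j = M/m_j,
- pseudo-values p_j = h_j·θ̂ − (h_j−1)·θ₍ⱼ₎,
- jackknife mean θ_J = g·θ̂ − Σ_j (1−m_j/M)·θ₍ⱼ₎,
- variance = (1/g)·Σ_j (p_j − θ_J)² / (h_j − 1).

With equal weights this reduces exactly to the classic delete-one
jackknife (verified to 1e-12 in the tests).  Reported Z-scores use the
whole-data estimate in the numerator (θ̂/SE), the convention of the
f-statistic tooling ecosystem; θ_J is reported alongside.  Ratio
statistics are jackknifed by deleting block sums from numerator and
denominator jointly.  A zero SE (all leave-one-out estimates identical)
reports signed-infinite Z with a warning rather than failing.

No multiple-testing correction is applied anywhere: batteries report raw
Z-scores against the conventional |Z| > 3 line.

## Test batteries

The Australasian battery computes D(outgroup, Aus; anchor, X) for every
test population X against a panel of Australasian populations and
summarizes each X by the median and the 2.5th–97.5th percentile span of
the Z-scores (quantiles by linear interpolation between order
statistics); `signal` flags median Z > 3.  The regional batteries
enumerate D(outgroup, X; Y, Z) over all population pairs drawn from two
region groups — pairs are enumerated rather than pooling allele
frequencies within regions, because pooling would mix distinct drift
histories into a pseudo-population with no coherent sample-size
correction.  The per-X summary is the median Z across pairs; pairs
containing X itself are skipped with a warning.

## Admixture graphs

A graph is a rooted DAG: ordinary edges carry drift lengths c_e ≥ 0 (f2
units), admixture nodes have two parents and a mixing weight α for the
first.  Routing a lineage from leaf L through admixture nodes with
probabilities α/1−α gives per-edge traversal probabilities v_L, and

E[f2(A,B)] = Σ_e c_e (v_A[e]−v_B[e])²,
E[f4(A,B;C,D)] = Σ_e c_e (v_A[e]−v_B[e])(v_C[e]−v_D[e]).

Fitting minimizes Σ_pairs (f2_obs − f2_exp)²/se² over all leaf pairs with
c_e ∈ [0, 2], α ∈ [0, 1], using bounded trust-region least squares from
10 seeded random starts (early stop when the score falls below 1e-10).
Design choices:

- **Score, not likelihood.**  The reference graph-fitting tools score a
  fit by a likelihood under the full jackknife covariance of the f
  statistics.  We use a diagonal weighted least-squares score (weights
  1/se²): the full covariance is not reconstructible from typical
  published summaries, and for ranking scenarios on the same data the
  diagonal score preserves the ordering in all our validation runs.
- **f2 basis.**  All leaf-pair f2s are fitted; f4s are linear
  combinations of f2s (site-by-site: (a−b)(c−d) =
  ½[(a−d)²+(b−c)²−(a−c)²−(b−d)²], with the bias corrections cancelling),
  so they add no independent information to the fit.  The worst f4
  residual — the quadruple ordering maximizing |obs−exp|/se over all
  three pairings of every 4-subset, ties broken lexicographically — is a
  pure goodness-of-fit diagnostic, with |Z| < 3 the conventional
  "consistent" line.
- **Identifiability caveat.**  Fitted drift lengths are effective values
  in f2 units; the simulator's Balding–Nichols parameters map to them
  only up to heterozygosity factors and (1−c) shrinkage along paths, so
  recovery checks compare α and topology ranking, not raw edge lengths.

### Canonical scenarios

Three peopling scenarios for eastern South America are bundled, sharing a
backbone (outgroup; then a northern reference; then the South American
radiation) and differing in how Amazon, West Andes, Southeast and
Southern attach:

1. **Atlantic route** — Amazon and Southeast form an eastern clade;
   Southern derives from the Southeast lineage with an admixture
   contribution (default α = 0.4) from the West Andes lineage.  The
   admixture edge encodes the far-southern contact with Andean groups
   that any Atlantic-route account needs; it also gives the scenario a
   recoverable mixing parameter, which the validation exercises.
2. **Pacific route** — eastern populations split off the Andean lineage
   in north-to-south waves (Amazon first, Southern closest to West
   Andes); no admixture.
3. **Andes south-then-north** — an eastern clade (Amazon, (Southeast,
   Southern)) with Southeast receiving an admixture edge from West
   Andes.

These topologies are this package's reading of the three verbal
migration accounts; they are configurable as plain edge-list files
(`parent child drift` / `admix child parentA parentB alpha`), and any
output derived from the defaults should be interpreted with that
provenance in mind.  Scenario comparison fits every scenario under every
leaf-role assignment (Cartesian product of candidate populations,
skipping assignments that reuse a population) and ranks by score, with
the per-scenario median score as summary.

## Synthetic data

The simulator drifts i.i.d. per-site frequencies down an admixture
graph: root p ~ Uniform(0.05, 0.95); along an edge with drift c,
child ~ Beta(p(1−c)/c, (1−p)(1−c)/c) (mean p, variance c·p(1−p) — the
Balding–Nichols model, chosen over truncated-Gaussian drift because it
stays in [0,1] with exactly the stated variance); admixture nodes mix
parents linearly.  Contemporary samples draw Binomial(2, p) genotypes,
ancient samples a single Bernoulli(p) allele (ploidy 1); cells go
missing independently (default 5%); sites are assigned round-robin to 10
chromosomes.  Every random stream is keyed by (seed, stage, name hash),
so runs are bit-reproducible and graph variants sharing node names share
draws — a dose sweep of the gene-flow override changes only the admixed
leaf, which makes monotonicity checks nearly noise-free.  For the same
reason the gene-flow override places the admixture event *after* the
test leaf's drift, so the leaf frequency is an exact linear mixture.

Default study-style conditions (used by the validation suite): 50,000
sites; 10 diploids per population; an outgroup, a northern anchor
population, three Australasian proxies, and the four South American
regional populations; 2 extra pseudo-haploid "ancient" samples in the
Southeast population; drift lengths of 0.15 to the outgroup, 0.10 into
the Australasian clade, 0.02–0.08 elsewhere — FST-scale values typical
of the deep outgroup split and the strong drift of isolated American
populations.  Seven-plus populations (rather than a minimal six) are
used because the scenario graphs have six leaf roles and the battery
needs Australasian proxies besides.  Validation problem sizes (20
replicates for rate checks, 200 for SE calibration at 20k sites) were
chosen to make the binomial acceptance bounds decisive while keeping the
default suite quick to run.

**What passing tests do not show.**  Sites are simulated without linkage
disequilibrium, so the block jackknife's defence against locally
correlated sites is exercised only algebraically, not stressed; real
exome data also brings reference bias, error-prone ancient calls and
ascertainment effects the generator does not model.  Calibration results
here validate the estimators' algebra and their behaviour under the
stated sampling model, not robustness to those artefacts.

## Numerical details and degenerate inputs

- Thresholds in the QC filters are strict as worded: a variant missing
  in exactly 25% of samples survives; a sample at exactly 90% native
  ancestry survives.  MAF filtering (pooled across all samples) is
  opt-in because f/D statistics need rare variants.
- Dataset intersection matches sites on (chrom, pos); allele pairs must
  match directly or with ref/alt swapped (counts recoded n−d); anything
  else — including strand-ambiguous A/T–T/A pairs — is dropped rather
  than guessed.
- Beta parameters are guarded by clipping parent frequencies to
  [1e-12, 1−1e-12]; drift c ≥ 1 is rejected.
- D with a zero total denominator (monomorphic input) and jackknives
  with fewer than two non-empty blocks raise errors naming the cause.
- IDW uses great-circle (haversine, R = 6371 km) distances — Euclidean
  lat/lon would distort high-latitude maps — with power 2, 0.5° spacing
  and 2° padding as defaults (all configurable; no authoritative values
  exist for the map products this emulates).  Grid nodes within 1e-9 km
  of a data point take that point's value exactly.

## Known limitations

- No f4-ratio ancestry proportions, qpAdm/qpWave-style rank tests, or
  automated topology search; scenarios must be specified.
- The diagonal-weight graph score understates residual correlation
  between overlapping f2 pairs; scores are comparable across scenarios
  on the same data, not across datasets.
- EIGENSTRAT ingestion assumes the geno digit counts reference alleles;
  pseudo-haploid samples must be declared (e.g. via the panel's
  age-class column) since the format itself cannot express ploidy 1.
- Blocks are variant-count based; physical-distance or centimorgan
  blocks are out of scope.
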