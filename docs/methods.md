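# Methods

## Chemotype fractions

Each plant's chemotype is summarised by four percentages of its total
cannabinoid fraction, computed from the fresh-weight content (mg/g) of
eight analytes:

* alkyl axis — `F_C3` (propyl: CBDVA, THCVA, CBDV, THCV) vs `F_C5`
  (pentyl: CBDA, THCA, CBD, THC), summing to 100;
* cyclic axis — `F_dicyclic` (CBD-type: CBDVA, CBDA, CBDV, CBD) vs
  `F_tricyclic` (THC-type: THCVA, THCA, THCV, THC), summing to 100.

Neutral (decarboxylated) analytes are first expressed as their
carboxylic-acid precursors by multiplying by the acid/neutral
molecular-weight ratio; carboxylation adds one CO₂, so the four
correction factors lie in (1.10, 1.16). Molecular weights are derived in
`chemoseg.constants` from molecular formulas and standard atomic weights,
so the factors are auditable rather than hard-coded. CBN, CBG, CBGA and
CBC are accepted in input files but excluded from all four pools; the
fraction denominators use exactly the eight analytes above.

Extraction replicates are averaged analyte-wise *before* fractions are
computed; per-replicate fractions are retained so repeatability between
duplicate extractions can be reported as the coefficient of
determination (r²) across the plant set, per fraction axis. Plants whose
analyte contents are all zero have no defined chemotype and are excluded
with a warning rather than silently dropped.

The mid-parent value `midparent(p1, p2) = (p1 + p2)/2` is the
additive-inheritance expectation for hybrids; hybrid medians deviating
from it indicate dominance or epistasis.

## KDE demarcation

Chemotype categories are demarcated on one fraction axis at a time.

**Bandwidth.** The Gaussian-kernel bandwidth is selected by the
Sheather–Jones solve-the-equation plug-in: density-derivative functionals
ψ₄ and ψ₆ are estimated with two-stage normal-scale pilot bandwidths
(a = 1.24·λ·n^(−1/7), b = 1.23·λ·n^(−1/9), λ = min(sd, IQR/1.349)), and
the fixed-point equation h = [R(K)/(n·ψ̂₄(α₂(h)))]^(1/5) with
α₂(h) = 1.357·(ψ̂₄(a)/ψ̂₆(b))^(1/7)·h^(5/7) is solved by Brent's method
on a geometric bracket expanded from the normal-reference bandwidth
1.059·σ̂·n^(−1/5). If no root brackets within [h_ref/100, 100·h_ref] the
normal-reference rule is used with a warning. Pairwise distances are
summed exactly (O(n²); n here is a few hundred), so the result matches
R's binned `bw.SJ(…, method="ste")` to well under 1% — the test suite
checks this against R directly. Samples with n < 4 or zero variance are
treated as a single category.

**Density and modes.** The KDE is evaluated on a uniform 512-point grid
spanning the data range padded by 3h, clipped to [0, 100]. 512 points
keep antimode placement stable to < 0.2 percent units. Local maxima and
minima come from sign changes of the first differences, with plateaus
collapsed to their midpoint and boundary grid points allowed as maxima.
When observations pile against a boundary (F_C3 near 0 is common), kernel
mass leaks outside [0, 100] and the grid integral drops below 1; this is
flagged as a warning, not an error.

**Demarcation.** Categories are peak intervals delimited by antimodes
(baseline peak integration), subject to two rules:

* *Baseline resolvability.* An antimode cuts only if the density falls by
  at least `valley_depth_frac` (default **0.5**) of the lower flanking
  peak's height. Genuine between-class valleys in well-separated data
  drop essentially to baseline (relative depth ≈ 1), whereas sampling
  wiggles inside a sparse class produce shallow valleys; requiring a drop
  at least halfway to baseline removes the latter without touching the
  former. Shallower valleys are reported as *unresolvable* rather than
  forced into cuts — mirroring how an intermediate/high cyclic-fraction
  boundary can be genuinely indeterminable. The default was chosen from
  the mixture-recovery simulations in the test suite (50% gives 100%
  category-count recovery on ≥6σ-separated mixtures and ≥92% end-to-end
  generating-ratio acceptance; 5% fragments 1/16-frequency classes).
* *Minimum support.* A peak interval holding fewer than `min_support`
  (default 2) observations is merged into the adjacent interval whose
  shared antimode has the higher density (ties merge toward the
  larger-support neighbour), so singleton kernels never form categories.

Boundaries are the surviving antimode positions; categories are labelled
I, II, … by increasing fraction value. Intervals are left-open/
right-closed, the lowest closed at both ends, so boundary-coincident
values deterministically join the lower category. Demarcation is
invariant to observation order, and category counts always sum to n.

`ChemotypeDemarcator` exposes this as a scikit-learn estimator
(`fit`/`predict`, `get_params`/`set_params`, fitted attributes
`bandwidth_`, `boundaries_`, `labels_`, `counts_`), so it composes with
sklearn tooling; `demarcate`/`assign_categories` are functional wrappers.

## Segregation tests

`chi_square_gof` tests observed category counts against a named ratio
with expected counts N·termᵢ/Σterms, statistic Σ(O−E)²/E, **no**
continuity correction and df = k−1; H₀ is accepted when χ² does not
exceed the upper-tail critical value at α (default 0.05). These
conventions exactly reproduce published breeding-table values. Expected
counts below 5 are permitted (small Mendelian classes routinely produce
them) but warned about. A ratio whose class count differs from the
number of observed categories raises an error — categories are never
aggregated silently (a 7:6:3 model cannot be tested on a quadripartite
distribution). The registry contains exactly the four models: 1:2:1,
1:4:6:4:1, 9:3:3:1 and 7:6:3.

`bartlett_from_summaries` computes Bartlett's homogeneity-of-variances
statistic from per-group (variance, df) pairs —
[(Σdfᵢ)·ln s_p² − Σ dfᵢ·ln sᵢ²]/C with s_p² the df-weighted pooled
variance and C the usual small-sample correction — so published variance
tables can be re-tested without raw data. It agrees with a raw-data
Bartlett computation to 1e-9 when summaries come from the same samples.

`genotype_conditioned_segregation` re-runs KDE demarcation *within* each
B-locus genotype class and tests each planned ratio on the subset's
counts (per-subset mode, the default; a global mode reusing whole-
population boundaries is also available in the pipeline). Genotype
classes with fewer than 8 plants are skipped, and unscored plants are
excluded with a logged count.

## Cross simulator

The simulator provides the study structure the analysis assumes: two
homozygous divergent parents (P1: all-C3 alleles, *B*<sub>THCAS</sub>
homozygote; P2: all-C5, *B*<sub>CBDAS</sub>), an F1 family (default
n = 35), and an F2 (default n = 210) from a single F1 female × F1 male.

**Meiosis.** Gametes follow a two-point recombination chain without
crossover interference: the first locus comes from either haplotype with
probability ½, each next locus switches source with probability r to the
previous locus (r = 0.5 across linkage groups). The default locus order
is A2 — A1 — B — marker with all r = 0.5 except the SCAR marker, which
sits at `marker_r` (default 0, i.e. a perfect assay) from B.

**Gene action.** Three genotype→class maps are implemented; exhaustive
enumeration of the 16 equally likely F2 gamete combinations (exact
rational arithmetic) yields the textbook ratios:

| kind | classes | F2 ratio | rule |
|---|---|---|---|
| additive | 5 | 1:4:6:4:1 | class = # C3 alleles at A1+A2 |
| digenic dominant | 4 | 9:3:3:1 | C5 dominant at both loci; double C3 homozygote is the F_C3 maximum |
| epistatic | 3 | 7:6:3 | C3 dominant at A1, partially dominant at A2; A1 recessive homozygote is epistatic (lowest class) regardless of A2 |

**Phenotype noise.** F_C3 is the class mean plus truncated-normal noise
on [0, 100] (sd `noise_sd`, default 4.5%); F_dicyclic analogously from
the B genotype (means 0.9 / 48.5 / 96.1, the parental anchors with the
heterozygote at the mid-parent). A truncated normal rather than clipping
keeps the distribution atom-free — real fraction measurements never pile
at exactly 0, and a point mass would collapse the SJ bandwidth. Class
means default to a linear grid between the parental anchors 0.8 and
88.3% F_C3. An optional logit-scale noise mode skews classes toward the
nearer boundary (emulating distributions skewed toward the low-F_C3
parent); it is off by default so class means are exact. The default
noise_sd of 4.5% puts the simulated F1 F_C3 variance (≈20) on the order
of the most homogeneous real hybrid families; it is a tunable, not a
measured value.

**Emitted data.** `SimulatedStudy.to_dataframe()` realises each plant's
fractions as the four acid cannabinoids (CBDVA = T·f_C3·f_di etc., with
T ~ U(15, 25) mg/g total content), duplicated per extraction replicate
with multiplicative noise (cv 2%), plus plant id, generation, replicate
and the SCAR b_genotype call — the pipeline's exact input format.
Everything is deterministic given the seed.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the analysis
relies on: Mendelian class frequencies (exactly, by construction),
multimodal fraction distributions, codominant B segregation, marker–locus
discordance and linkage. It does not emulate biochemical flux effects,
lineage-specific gene effects, residual parental heterozygosity,
measurement drift between LC-MS batches, or copy-number variation within
synthase arrays — all plausible in real populations. Passing the
simulation-based checks therefore demonstrates that the pipeline
recovers the generating model under its own assumptions (clean digenic
inheritance, Gaussian within-class noise), not that any real population
follows those models.

## Numerical choices and degenerate inputs

* χ² p-values/quantiles via scipy's chi2 distribution; α default 0.05.
* SJ root-finder: Brent, xtol = 1e-6·h_ref; bracket factor 1.4, at most
  40 expansions.
* Zero-variance or n < 4 samples: single category (warning), no KDE.
* All-zero cannabinoid profiles: excluded with a warning.
* A zero variance alongside nonzero ones makes Bartlett's log undefined
  and raises an error.
* Boundary-coincident fraction values join the lower category by the
  half-open interval convention.
* Reports print percentages at 1 decimal and χ² at 2 decimals; the JSON
  report keeps full precision.

## Known limitations

* The single global bandwidth must serve classes of very different
  widths; a sharp boundary class shrinks h and can fragment sparse
  classes. The baseline-resolvability rule compensates, but K-recovery
  degrades when class separation falls below ~5 within-class sd.
* Bartlett's test is sensitive to non-normality; with the truncated
  classes near 0 it should be read qualitatively.
* The 7:6:3 epistatic model is one of several gene-action schemes
  consistent with a tripartite distribution; accepting its ratio does not
  identify the mechanism, and linkage vs genotype-specific gene action
  cannot be distinguished from a single F2 (the simulator exposes both
  knobs precisely so users can explore that confounding).
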