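# Methods

## Model

A probe on a polyploid SNP array targets one genomic locus or a pair of
homoeologous loci. Each haploid genome is described by an `AlleleState`
`(locus1, locus2)` with alleles in {A, B, null}; `locus2 = absent` encodes a
single-target probe. The observed call is the union of bound alleles
(`superpose`): {A}→AA, {B}→BB, {A,B}→AB, {}→NC. AA/AB/BB/NC are observed
states; `-` (MISSING) marks manually rescored or absent data and never
enters a numerator or denominator.

A doubled-haploid progeny inherits, independently per underlying locus, one
of the two parental alleles with probability ½. With unlinked loci the four
allele combinations are equiprobable, so every parental configuration
induces a progeny call distribution with frequencies in {¼, ½, ¾}.
`enumerate_expectations` enumerates all such configurations exhaustively,
collapsing those with identical (parental call pair, progeny distribution)
into groups. The grouping yields:

* 6 **Pseudo-simple** groups — parental calls mimic a Simple SNP: four
  AA/BB groups segregating non-parental AB (and possibly NC) calls, and the
  two hom/NC groups segregating 3:1 with *no* non-parental calls;
* 2 **sHemi** groups — an AB parent, progeny restricted to parental
  classes (1:1);
* 3 **mHemi** groups — an AB parent with non-parental segregation at
  frequency ≥ ¼;
* 3 **Simple** groups (AA/BB, AA/NC, BB/NC at 1:1). Two-locus
  configurations whose progeny behave identically to a Simple SNP (e.g. a
  homoeologue null in both parents) are merged into these groups: they are
  observationally indistinguishable and harmless for mapping.

Group ids are the package's own deterministic numbering (Pseudo-simple,
then sHemi, mHemi, Simple; within class by parental calls and
distribution). Probes binding more than two loci are not modelled.

## Filtering procedure

1. **Prefilter**: drop probes detected in < 80% of samples and samples with
   call rate < 70% (defaults). NC counts as detected by default, because NC
   is an informative parental state here; a strict mode counts only
   AA/AB/BB.
2. **Split** typeable loci into monomorphic (identical non-missing parental
   calls) and polymorphic; loci with a missing parental call are set aside
   in an `untypeable` report. AB/AB loci are monomorphic by this rule and
   contribute only to line filtering.
3. **Line filter** (monomorphic loci): PNPG = (M−PG)/M over detected calls;
   remove at PNPG ≥ `line_threshold` (default 0.05; the threshold value
   itself removes). Loci with heavy missingness still participate —
   individual missing cells are simply skipped.
4. **Locus filter / classification** (polymorphic loci, authentic lines
   only — line filtering strictly first, since contaminated lines inflate
   locus PNPG):
   * PNPG ≥ `locus_threshold` (0.05) ⇒ multi-locus: mHemi if a parent is
     AB, else Pseudo-simple.
   * PNPG below threshold and parents AA/NC or BB/NC ⇒ Pearson χ² against
     1:1; if rejected at `alpha` (0.05) and 3:1 is not rejected ⇒
     Pseudo-simple; if both rejected ⇒ Unclassified; else Simple. Only the
     two parental call classes enter the test (non-parental calls are
     already accounted for by PNPG); df = cells − 1, no continuity
     correction by default (Yates available via config), no
     multiple-testing correction by default (Bonferroni can be applied by
     tightening `alpha`). Loci with fewer than `min_count = 30` detected
     calls in the tested cells are Unclassified — below that the χ²
     approximation and the 1:1/3:1 discrimination are both unreliable.
     A pooled aggregate χ² over all hom/NC loci per assigned class is
     emitted in the manifest as a secondary, population-level check.
   * Otherwise: sHemi if a parent is AB, else Simple.
5. **Error report** (monomorphic loci with PNPG < threshold, authentic
   lines): per parental class (AA/AB/BB/NC), the fraction of each observed
   progeny call; class PNPG = 1 − own-class fraction; overall PNPG is the
   detected-call-weighted mean and estimates the platform call-error rate.
6. **Export**: retained (Simple ∪ sHemi) loci × authentic lines recoded
   A/B/−; Unclassified loci are removed by default (configurable). A
   rotated R/qtl-style CSV with a placeholder phenotype column and
   chromosome row is also written. Output is ASCII, newline-terminated,
   input row order.

Locus PNPG is computed once after line removal (no iteration): the line
filter is driven by monomorphic loci, which the locus filter does not
touch, so a second pass could only change results through the handful of
borderline loci and is not worth the added coupling.

## Chi-square implementation

The Pearson statistic Σ(O−E)²/E over cells with positive expected
frequency, with the upper tail from `scipy.stats.chi2`. The statistic is
authored in-package (the 1:1-vs-3:1 discrimination is central to the
method); the test suite cross-checks it against `scipy.stats.chisquare` on
random tables to 1e-10 relative as an independent oracle.

## Synthetic populations

`simulate_population` draws, per locus, a parental configuration consistent
with its assigned class (Simple loci from single-locus states; sHemi /
mHemi / Pseudo-simple uniformly over the generating two-locus state pairs
of that class, with random parent orientation), then generates progeny by
the DH two-locus law and superposition. Defaults define the emulated study
conditions:

| parameter | default | rationale |
|---|---|---|
| `n_lines` | 190 | typical DH mapping population |
| `n_monomorphic` | 1000 | composition AA:AB:BB:NC = 1317:16:1441:574, the monomorphic class mix of a real rapeseed 6K array |
| `n_simple/shemi/mhemi/pseudo` | 60/220/80/40 | ≈62% heterozygous-parent loci, ≈15% multi-locus, echoing observed array composition |
| `contamination` | 11 lines at fraction 0.5 | cell-wise replacement with a shared "foreign parent" genome (alleles uniform over {A,B,null} per live locus); 0.5 models an F1-like mixture |
| `call_error_rate` | 1.6e-3 | symmetric replacement by one of the other three observed states; matches the residual error a curated array run shows |
| `missing_rate` | 0.02 | independent cell-wise missingness |

Parents are emitted noise-free (the workflow assumes curated parental
calls). Noise order per progeny cell: contamination → call error →
missingness. Truth tables record per-locus class/states/expected-NPG
frequency, per-line authenticity, and the pre-noise (post-contamination)
calls; `foreign_npg_rate` gives the closed-form NPG probability of a
contaminated cell for the realised foreign genome, so line-filter behaviour
is checkable analytically.

What the simulator does **not** emulate: linkage between loci (irrelevant
to filtering; map construction is out of scope), fluorescence-level
cluster-calling artefacts, asymmetric per-class error (Table-style
asymmetry can be approximated via a per-class error table, but the default
is symmetric), and probes binding three or more loci. Passing tests
therefore demonstrate correctness of the filtering logic under the stated
generative model, not robustness to every artefact of real array data.

## Numerical and scale choices

Thresholds are compared with ≥ for removal; ties at the threshold are
removed. The default validation scenario (190 × 1400, seeded) runs in
about a second; the convergence checks use 10,000 lines on a handful of
loci. Statistical assertions in the tests use 3-binomial-standard-error
bands at fixed seeds. Degenerate inputs: an empty polymorphic set yields a
header-only coded matrix with a warning; zero detected calls for a line or
locus raise immediately rather than emitting NaN.

## Known limitations

* The 1:1-vs-3:1 χ² discrimination has limited power below ~60 informative
  calls; such loci should be treated as Unclassified rather than trusted.
* Lines with PNPG just under the threshold (0.03–0.05) are kept but
  counted in the manifest (`n_kept_in_0.03_to_threshold`) so borderline
  populations are visible.
* Cluster separation scores are accepted as metadata only and never used to
  filter; upstream re-clustering decisions are out of scope.
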