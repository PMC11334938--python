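# Methods

## Scope and model

`sphingolink` infers likely microbial producers of environmental
sphingolipids by combining three independent lines of evidence: spectral
structure (molecular networking groups lipids into subclasses), genomic
capacity (which genomes encode a credible sphingolipid pathway), and
co-abundance (whose depth profile tracks the lipid's). The central claim
the design encodes is that co-abundance alone is not evidence of
production — it must be *gated* on capacity.

Everything operates on a depth-ordered sample series: samples sorted by
increasing depth define the 1-based index `j = 1..t` used for profile
alignment, the weight statistic and zone labels. Redox zones follow the
water-column convention: euxinic where sulfide > 0.2 µM, oxic where
oxygen is detectable and sulfide is not above that cut, suboxic otherwise.

## Spectral similarity

The modified cosine allows a fragment pair to match either directly
(|Δm/z| ≤ 0.02 Da) or shifted by the precursor mass difference, so
homologs differing by chain modifications still align. Intensities are
square-root transformed before scoring; the score is the sum of matched
intensity products over the product of the two spectra's Euclidean norms,
giving exactly 1 for a spectrum against itself. Matching is one-to-one and
greedy by decreasing intensity product, ties broken by smaller m/z
residual and then lower m/z — deterministic, and equal to the optimal
assignment on ≥99% of random small spectra (the test suite checks this
against an exact assignment-problem oracle; greedy is the production
algorithm). Edges require cosine ≥ 0.6 **and** ≥ 6 matched fragments
**and** mutual top-K (K = 10) rank among each endpoint's
threshold-passing candidates. Class propagation assigns each component
the majority class of its annotated seeds; ties are labeled `ambiguous`
rather than silently resolved, seedless components `unknown`.

## Quantification

Response factors are least-squares slopes through the origin
(rf = Σ conc·intensity / Σ conc²): intensities are blank-subtracted, and a
single-species standard curve gives no basis for an intercept. Classes
without a standard borrow a surrogate class's factor through a
configurable mapping (ornithine lipids → DGTS; the three substituted
1-deoxyceramide classes → 1-deoxyCer; Lys-Cer → the ceramide mix); the
provenance (`direct` vs `surrogate:<class>`) is reported with every
conversion. Chain parity calls a species odd-chained if either the
sphingoid base or the fatty acid has an odd carbon count.

## Capacity screen

Hit filters apply the printed operators exactly: Spt homologs at e-value
≤ 1e-70 and query coverage ≥ 70% (inclusive), bCerS/CerR at ≤ 1e-30 and
≥ 50%, each evaluated on the best hit per subject protein (by e-value,
bitscore tie-break). Query coverage is the larger of alignment length and
the qstart–qend span, over the query length; because tabular alignment
output does not always carry query lengths, the reader requires an
explicit length source and errors otherwise. For downstream alignment the
high-scoring pair is extracted when *subject* coverage < 70% (the wording
of the rule does not fix query- vs subject-relative coverage;
subject-relative is used because the concern is non-homologous flanks of
the predicted protein). Co-localization counts ordinal ORF positions, not
base pairs, strand-agnostic, within a 10-ORF window on one scaffold.

Clade gating is made algorithmic: clade A is the smallest clade containing
all reference Spt leaves; clade B grows one ancestor at a time while the
new ancestor's bootstrap support is ≥ 98 (missing support fails, the root
always fails) and every newly absorbed subtree contains at least one leaf
whose gene has a co-localized accessory. All clade-B leaves are Spt-like;
everything else is a divergent α-oxoamine synthase. Whether expansion may
absorb subtrees lacking co-localized members is genuinely open; requiring
at least one per absorbed subtree is the declared proxy, and it excludes
planted decoys with certainty when their attachment fails either
condition. When the references' MRCA is already the root the gate is
degenerate (all leaves returned) and a warning is emitted.

## Co-abundance

Scaffold abundances are mapping depths divided by reads after QC per
sample. Correlation is Spearman's ρ (mean ranks on ties, via SciPy; an
independent rank-then-Pearson oracle pins the implementation in tests),
undefined — and excluded with a count, not zeroed — for constant
profiles. The gated network keeps lipid–scaffold pairs at ρ ≥ 0.9
(inclusive, with a 1e-12 roundoff guard); the naive network links a MAG
when ≥ 10 of its scaffolds each reach ρ ≥ 0.9, a minimum chosen to damp
single-scaffold noise. `compare_networks` lifts gated scaffold edges to
lipid–MAG pairs and reports the naive/gated reduction ratio (∞-flagged
when the gated set is empty) plus per-phylum counts. Lipids enter
correlations as calibrated concentrations where available; Spearman makes
the raw-vs-calibrated choice immaterial within a class (monotone
scaling), asserted by test. The weight statistic P_i = Σ_j P_ij·j is
computed over all t samples by default (the formula's j runs 1..t), with
the euxinic-only restriction available to the caller by slicing profiles.

## Pangenome association

Tests run per sample over association-eligible MAGs
(completeness − 5×contamination ≥ 70). Fisher's exact test is two-sided in
the conventional exact sense (sum of table probabilities ≤ the observed
probability at fixed margins); the Mann–Whitney U test is exact by full
enumeration of group assignments when n₁+n₂ ≤ 12 — enumeration handles
ties without approximation — and a tie-corrected normal approximation
above, with the method recorded per result. Bonferroni correction uses
the family = one sample × functional universe × test; p_adj = min(1, p·m).
The shared-function filter keeps functions present in ≥ 75% of producer
phyla; sub-threshold results are still reported with their prevalence so
the filter is auditable.

## Synthetic study

The generator emulates a 15-depth stratified water column (50–2000 mbsl;
oxic 50–70, suboxic 80–105, euxinic ≥ 110 mbsl with sulfide rising from
0.85 µM) with 200–400 million post-QC reads per sample. Key parameters
(defaults in `SimConfig`):

- **Niches**: each MAG's true abundance is a Gaussian bump over the sample
  *index* (the inference operates on the ordered series, not physical
  depth), scaled by a lognormal size factor. Producer MAGs (8 of 200 by
  default) get evenly spaced centers (offset 0.3 from the integer grid to
  avoid degenerate symmetric ties) with width 0.9 index units —
  effectively disjoint niches; non-producers draw random centers and
  widths (0.8–2.5). A confounder fraction (default 0.3) of non-producers
  is cloned onto producer niches.
- **Scaffold depths**: MAG abundance × per-sample lognormal noise with
  CV = `noise_cv` (default 0.2), times reads per sample. Depths below
  ~1× coverage are recorded as zero: real depth tables are zero where no
  reads map, they do not contain vanishing-magnitude values whose ranks
  are meaningless. Without this floor a rank correlation is dominated by
  noise in samples that carry no information.
- **Lipids**: per-sample intensity = producer abundance × lognormal yield,
  plus additive Gaussian noise (sd = 0.2% of the feature's peak,
  truncated at zero) and a 5σ limit of detection (≈1% of peak) below
  which the feature is unreported — mirroring the scaffold floor so both
  measurement layers resolve a comparable dynamic range. Both floors are
  disabled in the exact noiseless limit, where a lipid's ranks equal its
  producer scaffold's (ρ = 1).
- **Spectra**: seven subclass templates of 10 fragments each (five
  invariant headgroup fragments, five chain fragments that move with a
  homologous-series shift of n·14.01565 + u·2.01565 Da), with
  template-specific spacing so subclasses never cross-match above
  cosine 0.6.
- **Decoys and tree**: homolog tables plant decoy α-oxoamine synthases on
  non-producer scaffolds — half pass the hit filter and must be removed
  by clade gating, half fail e-value or coverage outright; the toy
  phylogeny nests the reference clade inside a 99-support clade with the
  producers' co-localized Spt proteins and attaches decoys outside.
- **Functions**: planted enrichments at presence 0.9 (producers) vs 0.1
  (non-producers), neutral functions at 0.3 in both; counts are
  1 + Poisson, with a higher rate in producers for enriched functions.

All randomness flows through `numpy.random.default_rng(seed)` (lipids,
functions and homolog tables use seed+1/+2/+3 derived streams); identical
config and seed give byte-identical on-disk datasets.

### What the generator does and does not emulate

It reproduces the *structure* that the inference exploits — niche-driven
co-abundance, capacity/co-localization ground truth, subclass-structured
spectra, planted function enrichments — with known truth. It does not
emulate isotope patterns, adducts or chimeric spectra, read-level
sampling noise, compositionality of relative abundances, assembly or
binning errors (beyond decoy homologs), or realistic phylogenetic
branch-length distributions. Passing recovery tests therefore shows the
chain is correct and well-calibrated under its stated noise model, not
that it is robust to every artifact of real multi-omics data.

## Numerical choices and problem sizes

Boundary comparisons follow the printed operators (inclusive hit filters
and ρ/eligibility cuts, strict MAG-quality and "other"-rule cuts), with a
1e-12 guard where float roundoff could defeat an inclusive boundary.
Greedy peak-matching ties and candidate-edge ranking ties break on
deterministic keys (m/z residual, feature id). The test suite runs
recovery at 20 seeds of the default community (200 MAGs × 50 lipids,
15 samples), association calibration at 200 null universes and 50 planted
ones, and exact-oracle sweeps (all 2×2 tables with total ≤ 30; 1000 random
small spectra) — sizes chosen to keep the whole suite around half a minute
on one CPU while leaving the estimates stable.

## Known limitations

Single-producer lipids only in the default truth (the mixing model
supports multiple producers, the generator does not exercise it);
clade gating assumes a rooted tree with supports on internal nodes and
treats the root as unsupported; per-read normalization assumes depths and
read counts on compatible scales; the naive network's minimum-scaffold
rule makes small MAGs structurally edge-free (they are counted and
reported, not silently dropped).
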