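# sphingolink

From environmental MS/MS lipid features to their likely microbial producers.

Untargeted metalipidomics of a stratified water column detects thousands of
lipid-like ion components, most of them unannotated, and co-varying
microbial taxa are easy to find — but co-variation alone badly over-calls
producers, because organisms that merely share a niche with the true
producer have indistinguishable abundance profiles. `sphingolink`
implements the inference chain that fixes this for sphingolipids, whose
bacterial biosynthesis pathway (serine palmitoyltransferase **Spt**,
bacterial ceramide synthase **bCerS**, ceramide reductase **CerR**) is
known:

1. **Molecular networking** — pairwise *modified cosine* similarity between
   MS/MS spectra (fragments match directly or shifted by the precursor
   mass difference Δm), edges kept at cosine ≥ 0.6 with ≥ 6 matched
   fragments and mutual top-K (K = 10) rank; connected components are
   subnetworks of structurally related lipids, and class labels propagate
   from annotated seed nodes. A class below 1% relative abundance in fewer
   than two samples folds into "other".
2. **Quantification** — per-class response factors fitted through the
   origin from external standard curves (rf = Σxy/Σx²), with surrogate
   standards for classes lacking one; plus odd/even chain-parity and
   class-relative-abundance summaries.
3. **Capacity screen** — Spt homolog hits filtered at e-value ≤ 1e-70 and
   query coverage ≥ 70% (bCerS/CerR: 1e-30, 50%); the high-scoring pair is
   extracted when subject coverage < 70%; co-localization requires
   bCerS/CerR within 10 ORFs of the Spt gene; Spt candidates are gated by
   phylogenetic clade (ancestors absorbed while bootstrap support ≥ 98 and
   each absorbed subtree carries a co-localized member), separating true
   Spt from divergent α-oxoamine synthases (Kbl, BioF, HemA). MAGs are
   tiered (medium/high quality: completeness > 50%, contamination < 10%)
   and flagged association-eligible (completeness − 5×contamination ≥ 70).
4. **Co-abundance gating** — lipid profiles (calibrated intensities)
   against per-read-normalized scaffold depths, Spearman ρ ≥ 0.9. The
   *gated* network admits only scaffolds encoding clade-gated Spt-like
   proteins; the *naive* network links any MAG with ≥ 10 correlated
   scaffolds. Their comparison quantifies the false-positive reduction.
   The depth weight P_i = Σ_j P_ij·j (P_ij = relative frequency in the
   j-th depth-ordered sample) summarizes where each feature lives in the
   water column.
5. **Pangenome-wide association** — per sample, functions on eligible MAGs
   tested for producer association with Fisher's exact test (presence)
   and the Mann–Whitney U test (counts), Bonferroni-corrected per
   sample × universe × test family, then filtered to functions shared by
   ≥ 75% of producer phyla.

A fully specified synthetic study (`sphingolink.simulate`) — 15
depth-ordered samples spanning an oxic/suboxic/euxinic redox zonation
(euxinic: sulfide > 0.2 µM), niche-structured MAGs, producer-linked lipids
with subclass-templated spectra, decoy homologs and planted function
enrichments — provides known ground truth, so the whole chain is testable
without any external data.

## Worked example

```sh
python examples/coabundance_gating.py
```

```
candidate pairs: 10000
naive lipid-MAG pairs (rho>=0.9, >=10 scaffolds): 697
gated lipid-MAG pairs (Spt-like scaffold rho>=0.9): 50
reduction ratio: 13.9-fold
gated precision/recall vs planted truth: 1.00 / 1.00
naive precision/recall vs planted truth: 0.07 / 1.00
```

Of the 10 000 possible lipid–MAG pairings (50 lipids × 200 MAGs), naive
co-occurrence calls 697 producer pairs, 93% of them false — confounder
genomes planted on producer niches. Gating candidates by genomic capacity
collapses this to the 50 true pairs, a ~14-fold reduction, without losing
a single planted producer.

The other scripts in `examples/` each demonstrate one capability
(networking, capacity screen, depth weights, association, the end-to-end
CLI-equivalent run). The CLI mirrors the library:

```sh
sphingolink simulate --seed 1 --outdir ds
sphingolink run ds --outdir out      # writes networks + report.json
```

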