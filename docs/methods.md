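# Methods

## Scope and model

`ribojoint` integrates a paired transcriptome (RNA-seq) / translatome
(Ribo-seq) experiment with two groups, here labelled M and B. It consumes
gene-level count tables, or ribosome-footprint alignments in BED6 form plus a
GTF annotation, and produces RPKM matrices, QC summaries, per-level
differential-expression tables, a translational-efficiency (TE) table with
differential-TE calls, a nine-class joint classification and gene-set
statistics. The gene model is deliberately minimal: one single-exon transcript
per gene (5'UTR + CDS + 3'UTR laid out contiguously). Isoforms, introns and
multi-mapping are out of scope; counts are taken as already resolved to genes.

## Quantification and QC

**P-site assignment.** A footprint's P-site is placed `offset` nt downstream
of its 5' end (strand-aware), default 12 nt — the field-standard value for
28–31 nt fragments. The fragment is counted to the single gene whose
transcript contains the P-site and to the region (5'UTR/CDS/3'UTR) it lands
in; P-sites outside any model, and fragments outside the admissible length
window (default 25–35 nt), are tallied as unassigned. The conservation
identity `assigned + unassigned + malformed = records read` is enforced and
tested. Because transcript models never overlap, assignment is unambiguous;
the lexicographic tie-break documented in the API can only matter for
user-supplied annotations that break the non-overlap invariant.

**RPKM.** `count / ((length/1e3) · (total/1e6))` with the per-sample total
taken over the supplied count matrix. RPKM is invariant to per-sample count
scaling, which the property tests exercise. Note the compositional caveat
below.

**QC summaries.** Footprint length histogram with the modal length (smallest
length on ties), per-sample region occupancy percentages (over assigned
records only, summing to 100), expressed-gene counts (RPKM > 0 in at least
one replicate of the group — the replicate rule is a package choice, exposed
in the API), and between-group reproducibility as the squared Pearson
correlation of `log2(mean RPKM + 1)` over genes expressed in both groups.
The `+1` transform is likewise a package choice.

## Differential expression

The two-group test is an **exact conditional negative-binomial test** on
counts first equalised to the mean library size (per-sample scaling and
rounding). With per-sample mean μ and dispersion φ (variance μ + φμ²), each
group sum is NB(nμ, φ/n); conditionally on the grand total *s* the success
parameter cancels and

    P(Y_B = y | s) ∝ C(y + r_B − 1, y) · C(s − y + r_M − 1, s − y),   r = n/φ,

which degenerates to Binomial(s, n_B/(n_B+n_M)) at φ = 0. The two-sided
p-value sums the conditional probabilities of all outcomes no more likely
than the observed one (minimum-likelihood rule). φ is a single common value
estimated by method of moments across genes (pooled within-group sums of
squares), clamped at 0; `dispersion="auto"` is the default and a fixed value
may be supplied. There is no tagwise or trended shrinkage — with 2–4
replicates per group a common dispersion is the defensible choice, and the
simulator uses the same shared-dispersion model, making parameter recovery
interpretable.

Fold changes are `log2((mean_B + c)/(mean_M + c))` on group-mean RPKM with
pseudocount c = 1 RPKM. Flagging uses strict inequalities on raw p-values —
transcriptome |log₂FC| > 1 and p < 0.001, translatome |log₂FC| > 1 and
p < 0.05 — with BH q-values reported alongside for transparency but never
used for flagging. All thresholds are configurable.

## Translational efficiency

`TE(g,s) = RPKM_ribo/RPKM_rna` per matched (group, replicate) pair, undefined
where `RPKM_rna = 0`. Differential-TE testing runs an unpaired two-tailed
pooled-variance t-test on **log₂ TE** (a raw-scale option exists); the TE
fold change is the difference of group means of log₂ TE, i.e. the log ratio
of geometric means. Non-positive TE values (zero footprint counts) are
undefined on the log scale; genes with fewer than two defined values in
either group are reported untested and never flagged. A DTEG satisfies
|log₂FC TE| > 2 and p < 0.05. Degenerate zero-pooled-variance cases map to
p = 1 when the means agree and to the smallest positive representable float
when they differ, keeping p in (0, 1] and orderings meaningful. With two
replicates per group the test has df = 2 and very low power; the module runs
it but logs a warning.

## Nine-class integration

Each gene tested at both levels gets a status pair; the grid (rows =
translatome up/ns/down, columns = transcriptome down/ns/up, labels A–I
row-major) is the unique row-major layout consistent with the anchor cells
E = (ns, ns), B = (ns, up), H = (ns, down), F = (up, ns), D = (down, ns),
C = (up, up), G = (down, down); A and I are then the opposite-direction
cells. Because other layouts of the same grid circulate, the mapping is a
configurable table. Genes missing a call at either level go to a tenth
"unclassified" tally — the manifest asserts
`classified + unclassified = input genes`. By construction the class-C and
class-G sets equal the up∩up and down∩down coordinate-DEG overlaps; a test
enforces the identity on random inputs.

## Enrichment

GSEA uses the weighted Kolmogorov–Smirnov running sum: hits increment by
|score|^weight normalised over hits, misses decrement by 1/(N − N_h); the ES
is the signed maximal deviation, bounded by 1 at weight 0. Default weight 1;
weight 0 is kept for the analytic small-case oracles. Significance uses a
**gene-label permutation null** (membership reassigned uniformly at the same
set size): with two samples per phenotype group, phenotype permutation is
degenerate, so gene-label permutation is the only feasible null at this
design size. p = (1 + #{|ES₀| ≥ |ES|, same sign}) / (1 + #same-sign), with
the +1 avoiding p = 0; NES = ES / mean(|same-sign null ES|). The ranking
metric for transcriptome GSEA is the log₂ fold change (B over M).
Over-representation is the hypergeometric upper tail
P(X ≥ k | N, K, n) after intersecting the set with the universe; the study
list must be a subset of the universe. No GO DAG handling or leading-edge
reporting.

## Synthetic data generator

The generator emulates the assumed data-generating process, not raw reads:

* **Annotation** — gamma-distributed segment lengths around configurable
  means (defaults 150/900/300 nt for 5'UTR/CDS/3'UTR) with floors (UTRs
  ≥ 30 nt, CDS ≥ 90 nt, rounded up to a codon multiple) so every region can
  host a footprint; genes placed left-to-right with 200 nt gaps, so
  non-overlap holds by construction.
* **Truth** — exactly `round(frac·n)` genes per effect type (tx-up, tx-down,
  te-up, te-down; disjoint groups), allocation shuffled by seed. Defaults:
  5% per type, tx effects ±2 log₂ units, TE effects ±3. The implied
  translatome change of a gene is the **sum** of its transcriptional and TE
  effects, which fixes its true class.
* **Counts** — negative binomial (gamma–Poisson; Poisson at φ < 1e-12) with
  mean `base_RPKM · 2^{effects} · (length/1e3) · (lib/1e6)`, shared dispersion
  φ = 0.05 by default, base expression log-normal with a floor of 10 RPKM.
  `n_reps` defaults to 2 per group per assay, the profiled design; the
  packaged demo and the recovery scenario use 4 for adequate power.
* **Footprints** — per gene, exactly `count` records (conservation is exact);
  lengths from a table supported on 28–32 nt with mode 31
  (0.08/0.12/0.20/0.38/0.22), P-site uniform within a region drawn from the
  mixture (default 5% 5'UTR / 62% CDS / 33% 3'UTR, the CDS-dominant,
  3'UTR-heavy profile of the liver libraries this emulates). Records may
  overhang transcript ends in genomic coordinates; only a length exceeding
  the whole transcript triggers a logged redraw. No codon periodicity, no
  sequence content, no rRNA contamination.

Problem sizes used by the packaged scenarios: demo 300 genes at library size
5·10⁵; recovery scenario 1000 genes at 5·10⁶; QC fidelity 10⁵ footprints;
null calibration 2000 genes. All generation is deterministic per seed
(per-sample footprint streams are keyed by sample name), and every writer
emits a JSON sidecar recording config and seed.

What passing tests therefore show: the estimators recover the parameters of
*this* generative model (NB counts, uniform P-sites, single-isoform genes) at
these sizes. They do not certify behaviour under isoform switching, UTR
mis-annotation, periodic P-site structure, overdispersion heterogeneity or
mapping artefacts present in real libraries.

## Numerical and degenerate-input choices

* Conditional NB pmf computed in log space via `gammaln` and normalised with
  `logsumexp`; ties in the minimum-likelihood rule tolerate 1e-10 of log-pmf
  slack.
* All-zero count vectors give p = 1 by convention (logged).
* Length-histogram mode ties break to the smallest length; ES running-sum
  ties break to the earliest position (numpy argmax).
* Malformed BED lines are skipped, logged and counted, never fatal; a GMT
  line with fewer than three fields is fatal with its line number.
* Library-size equalisation rounds to integers; at typical depths the
  rounding perturbation is negligible relative to counting noise.

## Known limitations

* **RPKM compositional bias.** Because the per-million term uses realised
  totals, strongly unbalanced differential composition shifts all fold
  changes (e.g. 20% of genes up 4-fold inflates a library total ~1.6-fold and
  biases every Δlog₂TE by ~0.7). This is intrinsic to RPKM as defined. At
  transcriptome-scale composition (a few percent of genes affected) the bias
  is < 0.1 log₂ units, which the recovery tests quantify.
* The exact test conditions on a single common dispersion; gene-specific
  dispersion in real data would make the reported p-values approximate.
* TE testing with n = 2 per group (df = 2) is formally valid but severely
  underpowered; interpret DTEG lists from such designs as conservative.
* The permutation GSEA p-value is conservative by construction (+1
  estimator) and its resolution is 1/(n_perm + 1).
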