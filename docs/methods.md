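# Methods

## Model and procedure

The pipeline treats each protein-coding gene of a genome as a point in
the plane of second-codon-position base frequencies, x = f(A₂),
y = f(T₂), where f(X_n) is the fraction of the gene's in-frame codons
carrying base X at position n. The second position is the most
constrained position of the codon — it determines the physicochemical
class of the encoded amino acid — so composition there reflects protein
character rather than mutational pressure alone. The working hypothesis
is that a genome's genes form two unequal groups in this plane (a large
group with f(A₂) ≥ f(T₂) and a small group with distinctly higher
f(T₂)) and that the groups differ in functional-category composition.

Stages:

1. **Frequency profiles** (`codon_stats`). Sequences are split into
   consecutive triplets from the first base. A trailing partial codon is
   trimmed (flagged); codons with a non-ACGT base at a given position are
   excluded from that position's denominator only (flagged), which keeps
   maximal data from genes with isolated ambiguity codes. Optionally the
   terminal stop codon is excluded (`drop_terminal_stop`, default off:
   with no exclusion rule available we count every complete codon, and
   the switch allows a sensitivity check). Genes with no countable codon
   are dropped; a genome must retain at least `min_genes` (default 50)
   genes, below which silhouette analysis is not meaningful.
2. **Clustering** (`clustering`). K-means on the raw (f(A₂), f(T₂))
   coordinates — both features already live on commensurate [0,1]
   scales, so no standardization is applied. Lloyd iterations from
   k-means++ starts, best of `n_restarts` = 50 by inertia, fixed default
   seed 20170326; the module is a pure function of (points, seed,
   parameters). K = 2…9 is surveyed and scored by the mean silhouette
   coefficient (Rousseeuw definition, Euclidean; singleton clusters and
   all-zero distances score 0). Ties in the K survey resolve to the
   smaller K (parsimony). The K = 2 solution is split small/large by
   size; an exact size tie is broken by declaring the higher-f(T₂)
   centroid small, which is the empirical signature of the small
   cluster. An optional silhouette subsample cap (default off) exists
   for very large gene sets because the silhouette is O(n²); it is an
   approximation and is never used in tests.
3. **Enrichment** (`cog_enrichment`). The 26 COG categories (4
   super-categories: JKLAB / DYVTMNZWUOX / CGEFHIPQ / RS). Genes with
   multiple letters contribute only their first letter by default
   (`first_letter`), keeping column totals equal to gene totals so the
   2×26 table is well-formed; `all_letters` is available. Pearson χ²
   without continuity correction; categories with zero column totals are
   dropped and the degrees of freedom reduced; expected counts below 5
   raise a warning but never alter the statistic. The
   overrepresentation indicator compares F(P_small) and F(P_large): in
   the default `relative` mode the difference is significant when it
   exceeds threshold × min(F_small, F_large) with threshold 0.05 ("5% of
   the lower proportion"); an `absolute` mode (difference > 0.05) is
   provided because the prose reading of the rule is ambiguous. Reports
   name the mode used. Unannotated genes are clustered but excluded
   from enrichment denominators.
4. **Cohort aggregation** (`cohort_aggregation`). Genomes carry a
   user-supplied phylum label (two-column TSV, compatible with taxonomy
   resolvers' output). Phyla with more than 10 genomes (strict) are
   retained for phylum-level ratios. Per phylum × category, genomes are
   small-wins / large-wins / ties by their indicator pair; ratios use
   the tie-excluded denominator, and a category never decided in a
   phylum has both ratios defined as 0. A category is classified
   consistent-large (-small) when its large (small) ratio is the larger
   one in every retained phylum with a nonzero decided denominator,
   otherwise mixed. Percentages are reported at 2 decimal places;
   underlying ratios are stored at full precision.

## Synthetic data: what it emulates and what it does not

`synthetic_data` draws each gene from one of two components: weight 0.85
with position-2 base probabilities (A .32, C .21, G .20, T .27) and
weight 0.15 with (A .22, C .18, G .15, T .45), placing the component
means at (0.32, 0.27) and (0.22, 0.45) — the visual geometry of real
prokaryotic scatter plots, with axes well inside [0, 0.7]. Positions 1
and 3 share a generic prokaryotic composition (position 1 G/A-rich,
position 3 uniform). Codons are i.i.d., so the within-component spread
of (f(A₂), f(T₂)) is multinomial noise √(p(1−p)/n_codons) ≈ 0.02–0.03
at the lognormal-median gene length of 300 codons (σ_log = 0.3, floor 60
codons); the component means are therefore ≈ 7σ apart and two clusters
are recoverable by construction. Gene counts default to 600 per genome
in the cohort demo and 3000 (a typical bacterial genome) in the
enrichment studies — see below.

COG letters are drawn per gene (probability `annotation_rate` = 0.9 of
being annotated, one letter per annotated gene) from a baseline
26-category distribution with every category ≥ 0.01; the large component
doubles J/K/L and the small component doubles P/U/V/S/G, echoing the
empirical direction of the bias. A truth ledger records every gene's
component and letters.

Stop-codon handling: internal in-frame stop draws are re-drawn at codon
positions 1 and 3 only, keeping the position-2 marginal — the clustering
feature — exactly equal to `base_probs`; the terminal codon is forced to
a stop (TAA/TAG/TGA weighted by the component's own base probabilities).
The position-1/3 marginals are thereby perturbed by at most the stop
probability mass (a few percent); position-2 calibration is tested at a
4-standard-error tolerance.

The generator does **not** emulate codon usage bias, amino-acid-level
realism, operon or strand structure, within-genome GC gradients, overlap
between the two groups, or multi-letter COG assignments. Passing
recovery tests therefore show that the pipeline detects the planted
two-component structure at realistic noise levels — not that real
genomes have that structure, nor how the method behaves when the two
groups blend continuously (real eukaryotic genomes often cluster
poorly).

## Study sizes and numerical choices

- Optimal-K recovery: 20 independent genomes of 600 genes; silhouette on
  all points; expected outcome K = 2 in ≥ 95% of replicates.
- Enrichment recovery: 20 genomes of 3000 genes (~2700 annotated). The
  2× category boosts are a moderate effect: at ~1100 annotated genes the
  25-dof χ² is underpowered for uniform per-genome significance, while
  at typical bacterial scale (~2700 annotated) every genome rejects at
  p < 0.01 and the P/J indicators point the planted way.
- Type-I calibration: 2000 replicate 2×26 tables, 500 annotated genes
  per cluster drawn from the shared baseline distribution; minimum
  expected cell count 5, satisfying the usual χ² adequacy rule.
- K-means convergence: sklearn Lloyd with tol 1e-10; determinism
  guaranteed by the seed, and inertia is the best of 50 restarts.
- Degenerate inputs: fewer distinct points than K is an error at K = 2
  and a skipped K (with warning) in the survey; identical points split
  across clusters score silhouette 0; empty annotation or an empty
  clustered∩annotated intersection is an error the cohort runner records
  as a skipped genome.
- Seeds: cohort child seeds derive from (master seed, phylum, genome
  index) via CRC32, staying below 2³¹ and making cohorts reproducible
  and genome-parallel.

## Known limitations

- The two threshold readings of the 5% rule (relative vs absolute) can
  disagree for rare categories; both are exposed and the report names
  the mode, but results should not be compared across modes.
- `first_letter` counting discards secondary COG letters; the
  `all_letters` alternative breaks the genes-sum-to-total property of
  the 2×26 table and should be used descriptively only.
- The consistency classification is a strict all-phyla rule; with few
  phyla, unboosted categories can classify as consistent by chance
  (visible in the 3-phylum demo cohort).
- Cumulative and phylum-level summaries treat genomes as independent;
  no phylogenetic correction is attempted, and per-genome p-values are
  reported raw, without multiple-testing correction across genomes.
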