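# Methods

## Evidence channels

A phage–bacterium pair is scored on four channels, each grounded in a
biological signature of infection. All alignments are optimal local
Smith–Waterman with affine gaps; the dynamic program is delegated to
Biopython's `PairwiseAligner`, and significance is assessed with
Karlin–Altschul statistics computed by this package:
`S' = (λ·S − ln K)/ln 2` bits and `E = m·n·2^(−S')` with `m, n` the
sequence lengths. Default schemes: nucleotide +1/−2 with gap open −5 /
extend −2 (λ = 1.28, K = 0.46) and BLOSUM62 with gap open −11 /
extend −1 (λ = 0.267, K = 0.041), the standard published constants for
these scoring systems. The constants are configuration, not fitted
values; tests verify the conversion formulas, not the constants.

* **Nucleotide similarity** — bitscore of the best phage-vs-host local
  alignment, searching both phage orientations, kept at E ≤ 1e−10
  (read as a BLAST-style significance ceiling: smaller is more
  significant). Detects integrated prophages.
* **Gene similarity** — mean bitscore over all phage-ORF × host-ORF
  protein alignments at E ≤ 1e−10. The amino-acid threshold is not
  dictated by the nucleotide channel but is adopted equal to it for
  symmetry. ORF pairs without a significant hit contribute nothing
  (they are not zeros).
* **CRISPR targeting** — spacers detected in the host genome are
  aligned to the phage (both orientations, permissive E ≤ 1, mirroring
  a default-parameter short-query search) and the mean percent identity
  of matching spacers is recorded.
* **Domain interaction** — ORFs are assigned protein domains when their
  alignment to a domain consensus reaches 50 bits; for each phage-ORF ×
  host-ORF pair whose domains are a known interacting pair, the mean of
  the two assignment bitscores is recorded, averaged over such pairs.

Absence of evidence is a missing value (`NA` on disk), never a zero.
Multiple nucleotide hits aggregate as best-hit; the gene channel
aggregates as the mean, following the distinct conventions the two
channels are described with.

### ORF caller

Minimal by design: maximal ATG→stop frames on both strands, standard
genetic code, default minimum 30 codons. This suffices to recover
planted genes and domain segments; GC-aware start-site modeling (as in
a production gene caller) is deliberately out of scope, and planted
proteins may carry extra N-terminal residues when an upstream in-frame
ATG extends the call — local alignment makes this harmless.

### CRISPR detector

Arrays are exact tandem repeats: ≥ 3 occurrences of the same word
(default repeat length 21–48 bp) separated by short spacers. Chaining
accepts structural spacer gaps of 10–120 bp so that out-of-range
spacers are *found* and then *discarded* by the biological 20–65 bp
filter rather than silently splitting an array. Overlapping candidate
arrays are resolved by most-copies-first, then longest-repeat: a chance
1-bp extension of the true repeat matches one fewer copy and loses the
tie. Degenerate (mismatched) repeats are out of scope; the generator
plants exact repeats.

## Classifier

A random forest (50 trees — ample for four base features, and sized for
repeated refitting inside nested validation) on the four channel
scores. Missingness
handling preserves the evidence logic: rows with no score on any
channel are excluded from fitting and classified as not interacting at
prediction time with probability 0; partially scored rows impute absent
channels as 0 with a per-channel missingness indicator column, so the
forest can distinguish "weak evidence" from "no evidence".

The features-per-split parameter is tuned over {2, 4, 6} of the 8
encoded columns by 5-fold × 10-repeat stratified CV maximizing AUC;
performance is estimated by nested validation — stratified 80/20
splits (25 outer iterations by default) with tuning inside the training
portion only — reporting per-iteration AUC, sensitivity and specificity
at the 0.5 decision threshold and their medians. ROC curves use the
standard threshold sweep with trapezoid AUC (equal to the normalized
Mann–Whitney U, which the tests verify independently).

Feature importance is exclusion-style: the mean decrease in held-out
accuracy when a channel's column (jointly with its missingness
indicator) is permuted, averaged over repeated 75/25 refits so the
estimate comes with a standard error; a retrain-without-feature variant
is available (`method="retrain"`). Permutation is the default because
it estimates the same quantity at a fraction of the cost.

## OGU binning and abundance

Contigs (≥ 1 kb) are embedded as canonical (strand-collapsed)
tetranucleotide frequencies concatenated with log10(x+1) per-sample
coverage, standardized, PCA-reduced to the components explaining ≥ 90%
of variance, and clustered with full-covariance Gaussian mixtures. The
component count is the smallest k whose BIC lies within 10 of the
minimum — the Kass–Raftery "strong evidence" threshold — because at
desk scale (tens of contigs) the raw BIC argmin occasionally shatters
one genome into two. Clustering is seeded and invariant to contig
input order (rows are processed in sorted-id order).

OGU abundance is the length-corrected pool
`A_O = 1e7 · ΣA_j / ΣL_j` over member contigs, which conserves mass:
summing `A_O · ΣL_j / 1e7` over OGUs returns the raw per-sample total.
The representative contig is the longest member (ties to the smaller
id). The contaminant filter removes a phage OGU iff its representative
has a translated six-frame match (stop-free peptides ≥ 15 aa, protein
scheme, E ≤ 1e−25 against the nucleotide search space) to a bacterial
reference but to no phage reference; dual-matching OGUs are retained as
putative integrated prophages.

## Networks

The master network holds every OGU as a node (role phage/bacterium,
per-sample abundances JSON-encoded so GraphML round-trips) and one
undirected edge per predicted positive pair; bipartiteness is enforced.
A sample graph keeps the nodes with positive abundance in that sample;
relative abundance is normalized **within role** because phage and
bacterial libraries are sequenced separately and their read pools are
not comparable. Edge weight defaults to the arithmetic mean of the
endpoint relative abundances (product and geometric mean selectable;
the choice is recorded in graph attributes and the run log). Diameter
and eccentricities are computed on the largest connected component,
with the disconnection flagged.

## Graph statistics

The per-node centralities implement the printed formulas directly:
closeness is `(Σd)⁻¹` — not the `(n−1)/Σd` convention, which is
available behind `normalized=True` — degree is the row sum of the
(weighted) adjacency, and eigenvector centrality is the leading
eigenvector, max-normalized to 1. Weighted closeness converts affinity
weights to distances as 1/w. Eigenvector centrality uses shifted power
iteration `(A + I)x` (tolerance 1e−10, ≤ 1000 iterations) on the
largest component with other components at 0; the shift breaks the ±λ
symmetry of bipartite spectra that stalls plain power iteration, and
rescaling A by its largest entry conditions the iteration for small
abundance weights. Non-convergence raises with diagnostics.

Centralization follows Freeman: `Σ_i (C_w − c(V_i))` divided by the
same numerator evaluated on the star graph of equal n (computed, not
tabulated, so every kind is covered). For n = 2 the star normalizer is
0 and the score is defined as 0. On connected graphs the value lies in
[0, 1]; on disconnected graphs the per-component eigenvector convention
can push it above 1, which is reported as-is.

Graph dissimilarity is Bray–Curtis on centrality signatures:
`B = 1 − 2C_ij/(C_i + C_j)` with `C_ij` the summed lesser centrality of
shared nodes. The totals `C_i, C_j` default to each graph's summed
centralities — the standard Bray–Curtis convention — with a
vertex-count variant selectable, since the two readings genuinely
diverge in the source description. The default signature is weighted
eigenvector centrality, so dissimilarity reflects both membership and
abundance-weighted position.

Noise tolerance: `perturb_edges` either retains a uniform random
`⌊keep·m⌋` subset of edges or completes the bipartite graph (new edges
weighted from current abundances); `noise_sweep` reruns a chosen group
contrast over perturbed graphs and reports mean ± SE of the p-values
per fraction.

## Statistics

* **ANOSIM**: Clarke's R = (r̄_between − r̄_within)/(M/2) on the ranks of
  the n(n−1)/2 dissimilarities, M = n(n−1)/2; p is the permutation tail
  (1 + #{R* ≥ R})/(n_perm + 1) with labels permuted and the matrix
  fixed; default 999 permutations. The R statistic is cross-checked
  against scikit-bio in the tests.
* **Paired Wilcoxon**: zeros dropped, ties mid-ranked; exact null
  distribution by generating-function DP for ≤ 25 non-zero pairs
  (two-sided p = 2·min(tails), capped at 1), tie-corrected normal
  approximation with continuity correction above. Exact enumeration
  oracles verify small n.
* **Intra vs inter contrast**: per unit (subject or family) with ≥ 2
  timepoints, intra = mean within-unit across-time dissimilarity,
  inter = mean dissimilarity to all other units' samples, optionally
  within a stratum (e.g. same skin site); the paired values enter the
  Wilcoxon test. "All other subjects" averages over all their
  timepoints.
* **ANOVA + Tukey**: one-way F test plus Tukey HSD adjusted p-values
  and 95% CIs via statsmodels.
* **Holm**: step-down with monotonicity enforcement and cap at 1.
* **NMDS**: nonmetric SMACOF (scikit-learn), best of several random
  restarts, normalized stress.

## Synthetic data: what it emulates and what it does not

Genomes are i.i.d. nucleotide sequences at configurable GC — the
simplest background under which chance alignments stay below the
channel thresholds at the 5–8 kb default lengths, so planted signals
are attributable. Planted mechanisms invert the four channels:
prophage = verbatim 2 kb phage substring copied into the host;
shared gene = a 100-codon gene inserted into both genomes, the host
copy substituted to a target amino-acid identity (default 0.7) with
codon usage re-randomized in both copies so the homology is visible to
the protein channel but near-background at the nucleotide level;
CRISPR = an array of exact 28 bp repeats with 3 spacers of 25–30 bp
copied verbatim from the phage (short spacers keep the copied material
below the nucleotide channel's significance threshold, so channels stay
attributable); domain pair = ORFs encoding the consensus sequences of
an interacting domain pair inserted into phage and host respectively.
Cross-channel correlation does occur where it is biologically faithful
— a prophage insertion carries genes, so it may also light the gene
channel.

Training sets place one mechanism per positive pair (equal mix by
default), drawn on fresh genome pairs. Half of the negative pairs share
a background gene at 0.35 amino-acid identity: unrelated phages and
bacteria do carry distant homologs without any infectious relationship,
and without such pairs every negative would be all-missing — leaving
nothing for a classifier to fit after the all-missing exclusion. The
remaining negatives score nothing anywhere.

Communities: a random bipartite ground-truth infection network
(default 30 phage / 45 bacterial OGUs at density 0.8, matching the
highly connected networks typical of gut and skin studies) with
log-normal abundances ln A = μ + σ(√ρ_b·g + √(ρ_w−ρ_b)·u_s + √(1−ρ_w)·ε),
giving expected log-abundance correlation ρ_w within a subject (default
0.9) and ρ_b between subjects (default 0.2); μ = ln 200, σ = 1. Group
connectivity c is realized by subject-specific phage dropout (each
subject keeps a random c-fraction of phages for all its samples), which
masks the corresponding ground-truth edges in every sample graph
because extraction drops zero-abundance nodes. The planted
group-connectivity contrast is measured as per-sample mean degree
centrality (edges per node): the abundance-weighted mean degree is
insensitive to connectivity because relative-abundance weights sum to 1
within each role and cancel.

Not emulated: read-level sequencing (FASTQ), error models, assembly
artifacts, real codon usage, degenerate CRISPR repeats, HMM-grade
domain models, and the compositional quirks of real microbiome
abundance data. Passing tests therefore demonstrate that the pipeline
recovers the structures it is designed to detect when they are present,
not that real communities contain them.

## Problem sizes and numerical choices

The bundled analyses run at desk scale by choice: 200 training pairs of
5–8 kb genomes, communities of 75 OGUs across 8–16 samples, 20
replicate datasets per community-level check, 999 ANOSIM permutations,
and 25 outer validation iterations. Fragmentation robustness uses one
contig per genome at a fixed fraction, mirroring the single-substring
design of the robustness experiment it follows; the multi-contig
shredder exists separately for binning tests.

The fragmentation experiment runs on signal-dense "temperate pair"
positives (`TEMPERATE_PAIR_PARAMS`: a 4 kb integrated prophage, three
shared genes, a four-spacer array and two domain pairs per pair) rather
than the single-locus defaults. The distinction matters: a lone planted
locus survives two independent half-length windows only ~25–40% of the
time, so single-locus positives would measure interval geometry, not
method robustness. Real interacting genome pairs — the inputs of the
experiment this mirrors — carry signal distributed along their genomes,
which is what the dense parameter set emulates. The single-locus
defaults remain in force everywhere channel attribution matters. Alignment e-value
search spaces use raw sequence lengths (no length-adjustment
correction). Tolerances: eigenvector iteration 1e−10; oracle
equivalence asserted at 1e−8; exact Wilcoxon switches to the normal
approximation above 25 pairs.

## Known limitations

* The aligner is exhaustive Smith–Waterman without heuristic seeding —
  correct but not scalable to real metagenome-scale search.
* Karlin–Altschul constants are table defaults, not re-estimated for
  the configured scoring scheme; e-values are therefore approximate in
  the gapped regime (as is standard practice).
* Closeness on disconnected graphs is per-component and flagged, which
  makes cross-sample comparison of closeness sensitive to component
  structure.
* The 4-subject × 2-timepoint design cannot reach two-sided paired
  Wilcoxon significance below its exact floor of 0.125; detecting the
  intra < inter effect at p < 0.05 requires ≥ 6 repeatedly sampled
  units, which the test suite demonstrates.
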