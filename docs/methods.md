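# Methods

This note documents the models and procedures implemented in `cladefill`,
the parameter choices that matter, what the synthetic fixtures do and do
not emulate, and the numerical decisions made where the design was open.

## The discovery model

The method assumes that a gene missing from one species' annotation usually
has annotated homologues in related species, and that those homologues are
similar enough at the nucleotide level for a profile HMM built from the
family to find the unannotated copy. Discovery is therefore limited to
*discoverable* genes: members of an orthogroup with at least one gene from
another species. Genes without homologues (singletons) are out of reach by
design, and so is ab initio prediction — every input genome must already
carry a basic annotation (default minimum 100 genes) from which orthogroups
can be built.

Orthogroup protein alignments are computed first and back-translated
through the source coding sequences into codon alignments; aligning at the
amino-acid level keeps the alignment robust to synonymous substitutions.
The codon alignments seed nucleotide profile HMMs (pyhmmer `Builder` /
`nhmmer`), searched against every genome in one batched call per genome.

## Adjusted scores and the skew-t hit filter

Bit scores grow with hit length, and e-values underflow for long strong
hits, so neither is comparable across genes of different lengths. The
filter instead works on score per base, `score_adj = score/length`.

Hits overlapping a gene of their source orthogroup ("good") and hits
overlapping only foreign genes ("bad") provide labelled samples of the
genuine-match and noise-match score distributions. Both are unimodal but
skewed, so each is modelled with a four-parameter location-scale skew-t
(Azzalini-Capitanio form: location, scale, skewness shape, tail df), fitted
by numerical maximum likelihood (Nelder-Mead on location, log-scale, shape,
log-df; moment-based starts with both skewness signs; skew-normal and
normal fallbacks if no start converges, recorded on the fit object). The
skew-t density is composed from `scipy.stats.t` pdf/cdf terms; no suitable
parameterisation ships with scipy, so density, sampler (skew-normal /
chi-square mixture representation) and fitting are implemented here.
Closed-form mean and variance (valid for df > 1 and > 2) back the
Monte-Carlo checks in the test suite.

A candidate hit (overlapping no annotated gene) is retained iff its
posterior probability of being genuine strictly exceeds 1/2, with class
priors equal to the observed good/bad proportions. Numerical notes:

* densities are evaluated in log space; if both class log-densities fall
  below −700 nats the data carry no information at that score and the
  prior is returned, with a warning;
* a posterior of exactly 1/2 is *not* retained (the hit must be more
  likely genuine than mistaken);
* with unimodal well-separated fits the posterior rule reduces to a single
  score threshold, but it stays well defined if the fitted densities cross
  more than once.

Per-species fitting requires `min_n_fit` samples in each class (default
50; the right order of magnitude for a per-species fit of four parameters,
and deliberately conservative — there is no canonical value). Below that,
good/bad scores from all *other* species are pooled and the model is
fitted to the pool (flagged `pooled`). If even the pool is insufficient the
run aborts and asks for more species — with one documented exception: when
*zero* bad hits exist in the entire run there is no noise distribution to
estimate at all. This happens on clean synthetic clades whose families are
mutually unrelated; real genomes essentially always produce cross-family
hits. In that degenerate case the pipeline retains all candidates with a
logged warning and relies on the two downstream filters.

Hit/gene overlap, everywhere it is used (classification, recovery), means
at least one shared base with a CDS interval, strand-agnostic — the
conservative reading that also blocks annotating an antisense duplicate on
the opposite strand as "novel".

## Hint filter and orthogroup confirmation

Retained candidate hits are exported as exon-part hints. Predicted genes
overlapping a pre-existing gene are dropped immediately (the method adds
genes, it does not revise them), as are predictions overlapping no hint.
For each surviving gene, hints from the same orthogroup are merged into a
hint region, and the hint F-score — algebraically the Dice coefficient of
the base sets — is computed with |G| equal to the gene's total CDS length
(hints are exon-part evidence, so the comparison is against coding bases,
not genomic span). The gene survives if any region reaches 0.8; the
threshold is inclusive ("below 0.8" is discarded), and every passing
orthogroup is recorded as a predictor.

Finally orthogroups are re-inferred over original plus surviving new
genes. A new gene is accepted iff its assigned orthogroup shares at least
one gene with some predictor orthogroup, counting only genes from the
original input annotations — membership fluctuates between inference runs,
so requiring identity would be too strict, while counting other new genes
would let co-predicted errors vouch for each other. Unclustered genes
fail. Accepted genes are named `cladefill_g<N>.t1` per species and added
to the annotation; with `max_iterations > 1` the whole cycle repeats until
an iteration accepts nothing (default is a single pass).

## Evaluation machinery

Removal experiments draw `n_reps` pairwise-disjoint random subsets of the
discoverable genes (one seeded permutation sliced into blocks). Set size
rounds half-up (10% of 5129 → 513); when full-size blocks overrun the pool
by a gene or two even though the fractions sum to one, the final replicate
takes the remainder of the permutation rather than failing.

A removed gene is *recovered* when a newly predicted gene overlaps it;
overlapped by two or more, it is *split* (it still counts once as
recovered, and the best-scoring match is reported). The protein F-score
aligns removed and recovered proteins globally (Biopython PairwiseAligner,
BLOSUM62, gap open −10 / extend −0.5) and counts identical aligned
residues; because co-optimal alignments can differ by argument order, both
orders are aligned and the larger identity count used, making the score
symmetric. The orthogroup F-score compares the gene's original
(full-annotation) orthogroup with the one assigned on re-inference,
restricting all cardinalities to input genes. Reports partition recoveries
at pF 0.95 into high/lower quality, mirroring the standard table layout.

## Synthetic fixtures: what they do and do not show

The generator builds a clade of 2–5 toy genomes sharing `n_families`
gene families. Each family descends from a random ancestral CDS (uniform
100–500 codons plus start/stop — hand-checkable coordinates, no introns by
default, an optional mode adds 1–2 `GT…AG` introns per gene to exercise
multi-interval logic). Species copies apply independent per-site
substitutions (default rate 0.05 — roughly congeneric divergence; any
internal stop codon created is repaired), with 1–2 paralogous copies per
species. Genes land on one contig per species, random strand, separated by
200 nt random spacers; a 600 nt random-sequence decoy region is always
planted in the target genome. `n_hidden` target genes are present in the
genome FASTA but omitted from the GTF; by construction their families span
other species, so ideal recall is 100%.

Substitution-only evolution means family proteins are column-comparable
without alignment, so expected protein F-scores on fixtures are exactly
computable. The fixtures deliberately do **not** model indels, repeats,
pseudogenes, GC heterogeneity, alternative splicing, or annotation errors
in the non-target species — passing tests demonstrate the pipeline logic
and filter arithmetic, not performance on real genomes.

Mock adapters close the loop without external tools: an orthogroup
inferrer that assigns by truth family (exact protein match, then 6-mer
similarity, for unseen genes), a pass-through aligner (valid because
fixtures are indel-free), a mock HMM engine that plants hits at known loci
with scores drawn from configurable skew-t distributions (enabling the
fitted-filter path on fixtures), and a mock predictor that emits truth
models under each hint, optionally degraded by boundary jitter or split
into two abutting half-genes. The real MAFFT and pyhmmer adapters are used
where those tools suffice; OrthoFinder and AUGUSTUS shell adapters are
provided for real-data runs.

## Problem sizes and defaults

The shipped experiments use 3 species × 20 families with 5 hidden genes
(full HMM search, ~1 minute on one CPU) and smaller 4–15-family clades for
filter-path tests — sizes chosen so every stage, including two pipeline
iterations, runs routinely during development. Key defaults: translation
table 1, hint threshold 0.8, `min_n_fit` 50 (20–30 in fixture-scale runs),
`max_iterations` 1 (2 in the experiments, to demonstrate the fixed point),
two-species input refused without an explicit override.

## Known limitations

* Discovery is bounded by orthogroup quality: a gene whose family was
  mis-clustered, or whose only homologues are in-species, cannot be found.
* The skew-t fit needs enough labelled hits; very small or very diverged
  clades fall back to pooling, whose calibration is only as good as the
  assumption that score distributions are comparable across species.
* The hint F-score compares against CDS length; a predictor that adds
  long UTR-adjacent exons is penalised even when the coding model is right.
* Iterating beyond one pass compounds any acceptance error into the next
  round's orthogroups; the default is therefore a single pass.
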