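# Methods

## Scope and model

`comonet` implements a cross-disease transcriptomic workflow: rank-based
per-sample signatures from an expression matrix, consensus signatures
per phenotype group, 1-step expansion of the signature genes on a
physical protein–protein interactome, overlap of the resulting disease
networks, hypergeometric over-representation of any gene list against
GMT collections, and a ΔΔCt + rank-product branch for qPCR panels. The
statistical core is deliberately non-parametric: samples are
characterised by the *identities* of their most extreme fold changes,
not their magnitudes, which makes the signature comparison robust to
monotone distortions of the intensity scale.

Assumptions worth making explicit:

- Expression values are already normalised and, on the default `log2`
  scale, roughly symmetric per feature; the fold-change reference is
  the plain genewise mean over *all* samples (not a control-only mean),
  so every group's profile is expressed relative to the cohort average.
- The interactome is undirected and unweighted; an interaction counts
  once per unordered pair regardless of direction, experimental system
  or publication, and only `physical` records of the target taxon
  (default 9606) are kept. Self-interactions are dropped — they cannot
  change 1-step reachability and only inflate edge counts.
- A disease network contains the seeds' *direct* interactions only
  (edges incident to a seed), not the induced subgraph on the expanded
  node set; neighbour–neighbour edges would densify the network with
  interactions no seed participates in.
- qPCR Ct noise is additive on the cycle scale, equivalent to
  multiplicative (log-normal) noise on expression, which is why the
  rank product operates on log-ratios (ranks are unaffected either way).

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| `n1`, `n2` | 100, 100 | features | signature half-lengths; 200-probe consensus signatures |
| `k` | 10 | percentile | bottom-10 % distance threshold for the sample graph |
| `alpha` | 0.01 | p-value | feature-screen threshold, two-sided pooled t |
| `fdr` | 0.05 | q-value | BH significance threshold for over-representation |
| `min/max_set_size` | 5 / 2000 | genes in universe | standard ORA guard against degenerate p-values |
| `n_perm` | 10000 | permutations | rank-product null resolution ≈ 1e-4 |
| `taxon` | 9606 | NCBI taxon | human interactions |

## Numerical and convention choices

- **Enrichment score.** ES(S, R) is the signed maximum deviation from
  zero of the unweighted running sum (+1/|S| on hits, −1/(G−|S|) on
  misses); ties between the positive and negative extremum resolve to
  the positive one. This is the unweighted Kolmogorov–Smirnov form
  (GSEA with weight p = 0). The signed-extremum convention — rather
  than "maximum for up-lists, minimum for down-lists" — is required for
  the distance to reach its documented extremes: identical signatures
  give distance 0, perfectly reversed profiles give 2, and all
  distances lie in [0, 2] because each ES term lies in [−1, 1].
- **Feature screen.** Classical two-sample Student's t with pooled
  variance, two-sided. Features with zero pooled variance and equal
  means are excluded (no evidence either way); zero pooled variance
  with unequal means counts as p = 0. Selection is the union over the
  configured contrasts; the default contrasts compare T2DM vs non-T2DM
  within each cohort (the selection actually used in the motivating
  design), not disease vs control.
- **Ranking ties.** Everywhere a ranking is cut (signatures, consensus)
  ties break by value descending, then feature id ascending — full
  determinism across platforms. Within rank-product comparisons, tied
  ratios get average ranks (rank-statistic convention).
- **Percentile.** The graph threshold is the k-th percentile with
  linear interpolation over the strictly-upper-triangle distances;
  pairs *at* the threshold are connected.
- **Consensus trimming.** The consensus collects every feature present
  in at least one subject signature but is truncated to the `n1`/`n2`
  most popular (ties: better mean within-list rank, then id), so its
  printed size is always n1 + n2; the full popularity tables remain
  available on the `ConsensusSignature` object and in the written
  output. A feature may legitimately appear in both the up- and
  down-consensus of a group when membership is split across subjects;
  downstream gene mapping deduplicates.
- **ΔΔCt.** Per animal the reference level is the arithmetic mean of
  the reference-gene Ct values — identical to normalising expression by
  the geometric mean of their 2^−Ct levels. ΔΔCt is referenced to the
  control-group mean ΔCt, so control animals average to ratio 1.
- **Rank-product null.** Under a random within-comparison rank
  assignment, any fixed gene's rank is uniform on 1..n_genes
  independently per comparison, so the null RP is sampled directly as
  the geometric mean of iid uniform ranks — exact, and one shared null
  sample makes p-values invariant to gene relabelling. p-values carry
  +1 smoothing: p = (1 + #{null ≤ observed}) / (n_perm + 1); the
  reported false-positive proportion is pfp = p · n_genes / rank(RP).
  RP is reported as the geometric mean (not the raw product) so values
  are comparable across comparison counts.
- **Universe for ORA.** Explicit, with two built-in choices: all
  annotated platform genes (default, the common background-list
  behaviour) or all interactome nodes.
- **Manifests and determinism.** A pipeline run is a pure function of
  config + seed; wall-clock timestamps in the manifest are therefore
  off by default (`record_timestamps` turns them on at the cost of
  byte-identical re-runs).

## What the synthetic data emulates — and what it does not

`generate_expression_dataset` reproduces the crossed two-phenotype,
four-group design (default cohort sizes 20/12/6/19) on a 20000-feature
array-scale background: iid Normal(baseline 8, SD 1) log2 intensities
with `planted_per_group` up- and down-regulated features shifted by
±effect·SD in exactly one group. `generate_interactome` draws uniform
random pairs (optionally wiring a planted module as a path);
`generate_gene_sets` plants one set with a controlled query overlap
among uniform decoys; `generate_ct_table` centres references at Ct 20
and targets at Ct 25 with 0.25-cycle noise and encodes a planted fold
change f as a −log2 f cycle shift in treated animals.

Not emulated: probe-level effects and cross-hybridisation, correlated
co-expression structure, batch and demographic covariates, scale-free
interactome topology, missing data, and amplification-efficiency
differences between qPCR assays. Passing recovery tests therefore shows
the pipeline extracts the signal it is pointed at under its own noise
model — not that the model captures every failure mode of microarray or
qPCR data.

At the default screening threshold (α = 0.01, two contrasts) the null
background alone passes ≈ 2 % of 20000 features, so the signature stage
always has a few hundred features to rank — comfortably above the
n1 + n2 = 200 needed for full-length signatures.

## Problem sizes used in the test and acceptance runs

Unit tests run on toy inputs (≤ 30 features, exhaustive-enumeration
oracles up to N = 12 universes and (3!)² rank assignments). The
end-to-end checks use the default 20000-feature dataset (57 or 40
samples), a 50-set GMT over a 1000-gene universe, an 80-gene qPCR panel
with 10000 permutations, and a 2000-feature pipeline run for the
byte-reproducibility check. A full acceptance run completes in a few
seconds on one CPU.

With per-feature selection power ≈ 0.93 at the planted-recovery
conditions (effect 2 SD, 10 samples/group, α = 0.01; noncentral-t), the
expected consensus recovery is ≈ 93 %, so individual seeds fluctuate
around that value.

## Known limitations

- The enrichment-score distance is O(G) per signature pair via a dense
  running sum; all-to-all comparison is O(S²·G) and is the slowest
  stage for cohorts of hundreds of samples.
- Over-representation only (upper tail); depletion is out of scope, as
  are GO-graph propagation and semantic clustering of terms.
- Single-step network expansion only; no confidence weights, no
  topology statistics beyond degree.
- The qPCR branch exposes pairwise contrasts only (no factorial
  diet × genotype model) and assumes perfect amplification efficiency.
- Headline gene/edge counts of any specific interactome release are
  not reproduced: they depend on the release and on manual annotation
  choices upstream of this package.
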