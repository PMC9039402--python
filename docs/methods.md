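# Methods

`cernet` reconstructs a miRNA-mediated regulatory analysis of a tumor /
adjacent-normal cohort as a tested pipeline: differential expression on count
matrices, candidate regulator→target edges, negative-correlation filtering,
network topology against a degree-preserving null, MCODE module detection,
ceRNA (shared-miRNA) network construction, TF–lncRNA crosstalk with motif
scanning, Cox-coefficient risk scores with Kaplan–Meier validation, and
immune-infiltration association.  This note records the models, the defaults
and why, the numerical choices, and what the synthetic-data experiments do
and do not establish.

## Differential expression

Counts for feature *f* in sample *s* are modelled as negative binomial with
variance μ + φμ² and a single common dispersion φ shared by all features of a
class, estimated by the method of moments (pooled over features and groups,
weighted by within-group degrees of freedom, clipped at 0).  The two-group
test conditions on the total: the group sums are NB with shapes n_a/φ and
n_b/φ and a common success probability, so conditionally on their sum the
group-A total follows a Pólya-like law computed exactly; the two-sided
p-value sums all outcomes no more probable than the observed one.  When φ = 0
this reduces to the exact binomial conditional test.  This is a deliberately
small count-model test in the spirit of the classic exact tests for
sequencing data; it is not a clone of any published package (no empirical-
Bayes moderation, no per-feature dispersion shrinkage).

**Normalization.** Samples are scaled by *median-of-ratios* size factors
(median, over features positive in every sample, of the count over the
feature's geometric mean; factors normalized to geometric mean 1).  Plain
total-count scaling is available (`normalization="total_count"`) but is not
the default: when a third of the features are differential with |log2FC| ≈
2.5, per-sample totals are dominated by the upregulated features and
total-count scaling imposes a spurious ≈ −1.5 log2FC on every null feature
(~65% false-call rate on the default synthetic study).  Median-of-ratios is
robust as long as under half the features are differential.

Selection uses |FC| > 2 and raw p < 0.05 (both strict, both configurable);
p-values are not multiplicity-adjusted by default, matching the screening
character of the procedure, with a Benjamini–Hochberg option.

## Candidate edges and the negative-correlation filter

miRNA–mRNA candidates come from a curated interaction table restricted to
differentially expressed endpoints.  miRNA–lncRNA candidates come from
canonical seed matching: the reverse complement of miRNA positions 2–7 on the
target, classified into 6mer / 7mer-A1 / 7mer-m8 / 8mer by the position-8
match and the literal A opposite position 1.  This is a deterministic,
fully specified stand-in for alignment/energy-based target predictors;
externally predicted edge lists can be loaded instead.

Since miRNAs repress their targets, candidate edges are kept only when the
endpoints' log2 profiles are negatively Pearson-correlated; by default the
correlation-test p must also be < 0.05 (a pure r < 0 mode exists).  The
significance condition suppresses noise edges at the cost of sensitivity in
small cohorts.

## Network topology and the rewiring null

Networks are undirected with typed nodes.  Mean clustering averages local
clustering over all nodes (degree < 2 contributes 0 — one of the two common
conventions, fixed for reproducibility).  Average path length averages
shortest-path lengths over *connected ordered pairs*; regulatory bipartite
networks are usually disconnected and this keeps the statistic finite (a
largest-component-only mode exists).  The degree distribution is summarized
by the R² of a least-squares line on log10(degree) vs log10(frequency) over
unique degrees — a descriptive scale-freeness index, not a maximum-likelihood
exponent fit.

Significance uses a configurable ensemble (default 1,000) of degree-
preserving randomizations: 10×|E| attempted double edge swaps per draw,
rejecting self-loops and parallel edges, which preserves every node's degree
exactly.  One-sided empirical p-values use the (r+1)/(n+1) rank, so p ≥
1/(n+1) and is never 0: clustering is tested against "random ≥ observed",
path length against "random ≤ observed".  Note that swaps do *not* preserve
bipartiteness: a bipartite observed network has clustering 0 while rewired
graphs can close triangles, so its clustering empirical p is necessarily 1 —
visible in the demo run and expected.

## MCODE modules

Vertex weight = k × density of the highest k-core of the closed neighborhood
(weight 0 below the degree cutoff).  Complexes grow greedily from the
highest-weight unvisited vertex, admitting neighbors with weight ≥ seed
weight × (1 − node score cutoff) up to the depth limit; an optional 2-core
haircut strips tree-like fringes (on by default, as in the plug-in; fluff
off).  Module score = density × node count with loop-free density
2E/(V(V−1)); only modules scoring strictly above 5 are reported, vertices
belong to at most one module, and ties in vertex weight break
lexicographically so output is deterministic.  Defaults: degree cutoff 2,
node score cutoff 0.2, k-core 2, max depth 100.  A score > 5 needs ≥ 6 nodes
at density ≤ 1, so sparse triangle-free bipartite networks legitimately yield
no modules.

## ceRNA network

A lncRNA–mRNA pair is a ceRNA candidate when the two share ≥ 1 miRNA neighbor
across the miRNA–mRNA and miRNA–lncRNA networks; candidates with Pearson
correlation strictly above 0.9 are retained, and each retained pair emits one
(lncRNA, miRNA, mRNA) triplet per shared miRNA.  An upper-tail hypergeometric
p-value for the shared-miRNA count (universe = distinct miRNAs in the union
of the two networks) is reported per pair for symmetry with the TF–lncRNA
procedure; filtering on it is off by default.  Note the degenerate case: if a
pair's partner sets exhaust the universe the overlap is forced and the
hypergeometric p is exactly 1.

## TF–lncRNA crosstalk

TFs are the subset of network mRNAs present in a user-supplied TF list.
TF–lncRNA pairs sharing significantly many miRNAs (hypergeometric p < 0.05)
are then checked for binding: position-weight-matrix hits in the ±2 kb
promoter window around the TSS or in enhancers assigned to the gene.
"Assigned" means the enhancer interval overlaps the ±2 kb TSS window — the
*within* reading of a basal regulatory domain; the alternative "beyond ±2 kb"
reading is self-contradictory with promoter/enhancer usage and was not
adopted (this choice is deliberately flagged here).

The scanner scores every window on both strands with the log-odds
log2(P(window|PWM)/P(window|background)) (background uniform by default,
configurable), discretized to 1/1000 bit.  P-values are exact under the
background: the distribution of the discretized score is computed by dynamic
programming (per-position convolution), and a window's p-value is the tail
probability at its score — the same construction FIMO-class scanners use.
Matrix probabilities are floored at 1e−10 so log-odds stay finite.  Planted
consensus sites of motifs with ≥ 8 bits information content are always
recoverable at p < 1e−4.

## Survival analysis

RiskScore_s = Σ_i β_i·Exp_i(s), with β_i the univariate Cox proportional-
hazards coefficient of feature i (Breslow tie handling; Newton iteration with
step halving; Wald standard errors from observed information).  Covariates
are internally standardized for conditioning and β back-transformed.
Monotone likelihood (separation) is detected at |β_standardized| ≥ 10 and
flagged non-converged — with a perfectly ordering covariate the partial
likelihood has no finite maximum.  Patients split at the arithmetic mean
score; samples exactly at the mean go to the low-risk group (deterministic
boundary).  Groups are compared by Kaplan–Meier curves and the log-rank test
(via lifelines), and the score's discrimination is summarized by rank-based
ROC-AUC against the overall event indicator — a time-ignoring summary,
documented limitation versus time-dependent ROC.

## Synthetic studies and what they show

The generator emulates a deep-sequencing tumor/normal cohort with planted
ground truth; the defaults are the package's reference study conditions:

| parameter | default | rationale |
|---|---|---|
| n_tumor / n_normal | 89 / 3 | heavily unbalanced cohort shape typical of adjacent-normal designs |
| n_mirna / n_lncrna / n_mrna | 150 / 100 / 300 | desk-scale feature counts preserving the class ratio |
| frac_de | 0.3 | strong tumor signal |
| log2fc_de | 2.5 | planted effects comfortably beyond the |FC| > 2 gate |
| nb_dispersion φ | 0.05 | deep libraries / moderate biological noise; makes PCC > 0.9 co-expression attainable, as the ceRNA filter presumes |
| edge_effect | 0.7 | latent repression strength (see below) |
| beta_prognostic | 0.7 | log-hazard per log2-expression unit, a strong but realistic marker |
| censor_rate | 0.3 | typical administrative censoring |
| motif_width | 8 | ≈ 11 bits at 0.91 consensus probability per column |

Regulation: each miRNA carries a standardized latent per-sample level z; its
own mean is multiplied by exp(0.4·z) and each target's mean by
exp(−edge_effect·z), producing negative log-scale regulator–target
correlation without distorting count marginals.  A planted ceRNA triplet
gives its lncRNA and mRNA the same repressor (and the same DE sign), so the
pair is positively correlated; planted triplet transcripts draw means from
300–800 (well expressed, like canonical ceRNAs) so PCC > 0.9 is attainable at
high edge_effect.  Survival times are exponential with hazard
h₀·exp(Σβ·Exp), h₀ = 10⁻³/day, on centered log2 expression of the planted
prognostic genes; censoring is independent exponential with the rate solved
(Brent) so the expected censored fraction equals censor_rate.  Sequences are
uniform random with planted 8mer seed sites (exact reverse complement of
miRNA positions 2–8 plus the A anchor); PWMs put 0.91 on the consensus base
per column, with consensus occurrences planted in the promoters of lncRNAs
that share a regulator miRNA with the TF and in one assigned enhancer each.
Everything is drawn from a single seeded generator, so the same config and
seed give a bit-identical bundle.

What the generator does *not* emulate: per-feature dispersion heterogeneity,
GC/length biases, isoform structure, correlated censoring, batch effects, and
realistic promoter base composition.  Passing recovery tests therefore shows
the pipeline implements its own model correctly and has power under clean
conditions — not that it is robust to the full messiness of cohort data.
Two consequences visible in the demo run are themselves informative: with
only 3 normal samples the lncRNA DE sensitivity is ≈ 0.5, and at edge_effect
0.7 most planted triplets fail the stringent PCC > 0.9 gate (recall rises to
≈ 0.96 at edge_effect 0.9).

## Numerical choices

Log2 standardization uses log2(x+1); aggregation of transcripts to genes
(arithmetic mean) happens on the raw scale before the log (means of raw
abundances are the natural transcript summary; the order is configurable by
calling the two steps directly).  Unmapped transcripts are dropped, never
guessed.  Pearson (not Spearman) correlation throughout, matching the PCC
filters.  Zero-variance features are skipped with a warning wherever a
correlation is required.  The exact-test two-sided rule uses a 1+1e−12
relative tolerance when comparing outcome probabilities.  Empirical p-values
always use the +1 correction.  All thresholds are strict inequalities
(|log2FC| > 1, p < 0.05, PCC > 0.9, score > 5, p < 1e−4).

## Problem sizes

The test suite and the acceptance script run simulations at the sizes chosen
for the package's reference experiments: 10⁴ feature-tests for DE
calibration, 100 replicates at n = 200 for Cox recovery, 500 permutations of
a 100-subject cohort for log-rank uniformity, 20 replicates for ceRNA
recall, and 1,000-draw rewiring ensembles (200 where an ensemble is embedded
in a larger experiment).
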