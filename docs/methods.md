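# Methods

## The dwell-time labelling model

Cells enter the tumour as cDCs (state S0) by a homogeneous Poisson process
with intensity λ (`entry_rate`, cells/h) and progress through a
continuous-time Markov chain

    S0 --k01--> S1 --k12--> S2          S1 --e1-->  dLN
                 \--k13--> S3          S2,S3 --e23--> dLN

with all rates in 1/h. Egress is state-dependent: activated DC1 cells leave
quickly (e1) while the terminal DC2/DC3 states are tumour-retained (e23 ≪
e1). Photoconversion at `t_conv` marks every tumour-resident cell red;
later entrants are green; dLN cells keep the label they held at egress, and
their state is frozen at egress (post-egress differentiation in the node is
out of scope). Treatment (a PD-L1-blockade flag) multiplies the
S1→S2 branch probability k12/(k12+k13) by `treatment_split_multiplier`
without changing the total S1 exit rate, emulating a preferential
transition into the DC2 state under checkpoint blockade.

Each harvest offset Δ ∈ {5, 24, 48, 72} h is simulated as an independent
cohort (separate animals in the emulated design). Trajectories are sampled
per cell by competing exponentials — cells are independent, so no
population-level Gillespie loop is needed.

**Closed-form oracle.** Writing Q for the 4×4 generator over tumour states
(egress as loss), the expected state occupancy of the red pool at harvest
is `λ (∫₀^t_conv e₀ᵀ e^{Qu} du) e^{QΔ}` and of the green pool
`λ ∫₀^Δ e₀ᵀ e^{Qu} du`; both integrals are evaluated exactly with the
augmented-matrix (Van Loan) exponential, so the oracle's accuracy is that
of `scipy.linalg.expm` (well below the 1e-8 relative target). The per-state
red fraction is red/(red+green). The Monte-Carlo simulator is validated
against this oracle to within 3 Monte-Carlo standard errors.

**Defaults** (chosen once, before any downstream result was inspected):
λ = 30/h, k01 = 0.08, k12 = k13 = 0.05, e1 = 0.02, e23 = 0.005,
t_conv = 120 h. These give a quasi-stationary tumour compartment at
conversion, ≥ 1000 tumour cells per simulated animal, and the qualitative
design target that at Δ = 48 h the retained DC2/DC3 fraction is > 0.7 red
while cDCs are < 0.3 red (the oracle gives 0.753 and 0.021). They are
documented constants of the generator, not estimates of real kinetics —
the real dwell-time rates are unknown.

**Idealisations.** Conversion efficiency is 100% (an optional
`mislabel_rate` defaults to 0); the residual green signal of converted
cells is not modelled (labels are binary); mouse-to-mouse variability,
real cluster structure and real gene identities are not emulated.

## Expression programs

Counts are NB2: gene g in cell i has mean `L_i · p_gi` with
`p_gi ∝ baseline_g · 2^(θ[g,state] + treatment_shift_g·treated)` normalised
per cell, and variance `μ + φ_g μ²`. Library sizes L are log-normal
(median 5000, σ = 0.3); dispersions φ ~ U(0.1, 0.4); baselines log-normal.
Because p is normalised per cell, the realised fold change of a planted
gene is its nominal 2^Δθ times the ratio of state normalisers (a ~10%
compositional shrinkage for the default programs); tests account for this.

Planted programs (40 genes each out of 2000; disjoint):

| set | θ (S0,S1,S2,S3) | role |
|---|---|---|
| activation | 0, 1, 2, 1 | up in all activated states, strongest in DC2 |
| antigen_presentation | 1.5, 1.5, 0.75, 0 | MHC-II-like decrease along DC1→DC3 |
| ifn_response | 0 (+1.5 log₂ under treatment) | treatment-responsive |
| dc2_marker | 0, 0, 2, 0 | DC2-restricted marker (the planted DE truth) |

## Statistical stages

**QC.** The gene-count rule is read strictly ("> 6000 or < 1000 …
filtered"): boundary cells are retained. The mitochondrial rule retains
< 7.5%. Cell and gene filters are iterated to a fixpoint so the operation
is idempotent (one pass is not: removing genes lowers detected-gene
counts). For the 2000-gene synthetic universe the pipeline config scales
the bounds (200–1900), since the published thresholds presume a ~30k-gene
transcriptome.

**Signature scoring.** Genes are binned into 25 equal-size bins by mean
expression; each signature gene contributes `ctrl_size = 50` control genes
sampled from its bin (signature genes excluded from the pooled control);
the score is mean(signature) − mean(controls). These defaults are the
scoring tool's documented ones; both are configurable.

**Pseudo-bulk bootstrap ranking.** Each group's cells are randomly split
into 3 near-equal pseudo-replicates (sizes differ by ≤ 1, counts conserved
exactly), 3 being the smallest replicate count that supports dispersion
estimation; B = 11 bootstrap re-partitions honour the "more than ten
iterations" design. Size factors are median-of-ratios over genes positive
in every sample, rescaled to geometric mean 1. Per gene, a two-group
log-link NB GLM with size-factor offsets is fitted by expected-information
IRLS (relative tolerance 1e-8, ≤ 100 iterations; non-converged genes are
flagged and excluded from the mean); dispersion is per-gene method of
moments on normalized counts, floored at 1e-8, with no empirical-Bayes
shrinkage — a deliberate simplification. The Wald SE comes from the
observed Fisher information at the optimum. Genes with an all-zero group
receive a 0.5 pseudo-count so the fold change stays finite. The rank
metric is the mean Wald statistic over converged iterations; ties break
alphabetically, never-converged genes sort last.

*Small-sample reference.* With 3 replicates per group the plug-in
dispersion makes the normal-reference Wald anticonservative (empirical
type-I ≈ 0.12–0.14 even with a Cox–Reid ML dispersion), so two-sided
p-values use a Student-t reference with the residual degrees of freedom
(n_samples − 2), the standard small-sample GLM correction; this holds the
null rejection rate at 0.03–0.07 across dispersion regimes from 0.005 to
0.6. The statistic itself is unchanged, and the fit is performed once in
canonical group order with the contrast sign applied afterwards, so
swapping group labels negates log₂FC and the statistic bit-exactly.

**GSEA.** Hits add `|metric|^w / Σ_hits |metric|^w` (w = 1), misses
subtract `1/(N − N_hits)`; ES is the running-sum extremum and the leading
edge the hits at or before it (after, for negative ES). The null permutes
gene sets (random same-size sets), the natural choice for a preranked list
without sample labels; p is one-sided within the sign of the observed ES
with the +1 correction, and NES divides by the same-sign mean |null ES|.
When all same-size subsets are few, `null="exhaustive"` enumerates them
and p is exact. A tie between the positive and negative extremum (possible
because miss decrements are rational) makes the ES sign ill-defined; the
first extremum in rank order is reported. ssGSEA uses exponent 0.25 (the
cited tool's default) on descending within-sample ranks; cohort scores are
scaled to [0, 1], with constant input mapping to zeros.

**Ligand–receptor testing.** min_frac = 0.10 and nperm = 1000 are the
referenced tool's documented defaults. Labels are shuffled globally across
cells; the min-subunit rule applies to permuted scores, the detection
filter only to observed ones (untested combinations report NaN).
p ≥ 1/(nperm+1) by construction.

**Spatial co-localization.** A neighbourhood is the centre spot plus its
k = 6 Euclidean nearest neighbours (k+1 = 7 values; the t test then has
df = 5); ties in the kNN graph break by spot order. A neighbourhood's R is
assigned to the centre only if both scores pass the detection predicate
(non-zero by default; configurable for signed signature scores) at every
spot and the correlation is significant at α = 0.05 — filters applied
before averaging, in that order. Grid binning uses half-open 200 µm bins
with the origin at the data minimum; only occupied bins are emitted, which
induces a small negative bias in the null grid correlation (empty (0,0)
bins are the most concordant ones) — about −0.04 at the default null
density, well inside the ±0.2 acceptance band. Grid-coupling checks use
~20 detections per grid, matching the detection density the 200 µm grid
width was designed around.

**Survival.** ssGSEA score → 0–1 scaling → median split (ties at the
median to "low": deterministic and conservative for protective-signature
claims) → Kaplan–Meier and the two-group log-rank test via lifelines,
with the standard simultaneous-risk-set convention for tied event times.
No Cox modelling: the claim under test is the median-split contrast.

## Pipeline

A single global seed expands into per-stage seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`; every artifact is written
with a fixed float format and recorded in `manifest.json` with its SHA-256,
so identical configs produce byte-identical runs. Stage failures abort
with the stage name (exit code 3); unknown config keys are rejected (exit
code 2).

## Validation problem sizes

The validation suite (`kaede_dcflow.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: 200 dwell
replicates (~3000 tumour cells each at Δ = 48 h); 2000-gene null NB
matrices at 3 pseudo-replicates/group; ~9600 DC2/DC3 cells for ranking
stability/recovery (two independent B = 11 runs); 20 GSEA permutation
seeds at nperm = 1000; 1000 null ligand–receptor pairs at nperm = 1000
plus 20 planted-pair seeds; 20 spot-field and centroid-field seeds; 1000
null survival cohorts (n = 60) and 200 powered cohorts (n = 200,
hazard coefficient −1); and a double end-to-end run on a reduced config
(600 genes) for the determinism check. The full script completes in about
two minutes on one CPU.

## Known limitations

- The generator's rates are free parameters, not estimates; passing tests
  show internal consistency of the pipeline, not correctness of any real
  kinetic claim.
- Method-of-moments dispersion without shrinkage is noisier than the
  empirical-Bayes pipelines it simplifies; the t reference compensates for
  calibration but power at very small effect sizes is lower.
- The label-transfer stage is a plain PCA + kNN vote; no batch correction
  or integration is attempted (cluster labels are inputs throughout).
- Counts are conditionally independent across genes given state and
  library size; no gene–gene correlation beyond the planted programs, no
  ambient RNA, doublets, or batch effects — QC filters are therefore only
  lightly exercised by the synthetic data.
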