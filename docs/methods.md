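# Methods

`allospot` implements a complete computational chain for locating
allosteric hotspots in homodimeric transcription-factor repressors from
deep-mutational-scanning (DMS) sort-seq data, and for learning which
structural and physicochemical properties of a residue make it a hotspot.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Scoring model

The experimental design behind the count tables is a three-population
sort-seq screen of a saturation single-mutant library (every residue from
position 2 mutated to the 19 alternative amino acids): a presorted
population, and low-fluorescence sorted populations with and without
inducer, each sequenced in triplicate. A variant locked in the repressing,
non-inducible state ("dead") appears in the sorted gate under both
conditions; a functional variant appears only in the uninduced sort.

Counts are normalized in two steps: each sub-library pool is rescaled so
its reads total `total_target / n_sublibraries` (default 200,000 total per
protein, 100,000 per pool) across all conditions and replicates; when
several proteins are compared, each protein's reads are then multiplied by
its theoretical library size over the smallest library size in the
comparison. Normalized counts remain real-valued and the read threshold is
applied to them.

With read threshold *t* (default 5):

* present ⇔ presorted reads ≥ *t* in **every** replicate;
* dead in a replicate ⇔ induced-sorted ≥ *t* **and** uninduced-sorted ≥ *t*;
* a variant dead in 1/2/3 replicates gets confidence score 0/1/2; dead
  calls in a single replicate are treated as unconfirmed and carry no
  weight.

The positional score at residue *x* is

    score(x) = (0·D1x + 1·D2x + 2·D3x) / Totalx ∈ [0, 2]

where Dk counts variants dead in exactly k replicates and Total counts
present variants. Residues scoring strictly above the third quartile (Q3)
of the per-protein score distribution are hotspots. Open choices, resolved
as follows:

* Q3 uses the linear-interpolation percentile (configurable);
  ties at Q3 are excluded (strict "above").
* Positions with no present variants are excluded from the quartile
  computation rather than scored 0 — absent data is not evidence of
  mutational tolerance.
* Q3 is computed over all scored positions; removal of ligand-contacting
  residues (any heavy atom within 5 Å of a ligand atom, inclusive) is
  applied afterwards, matching the narrative order of the analysis the
  package reproduces. Both choices are flags.

The dead-vs-not-dead composition report uses variants with confidence ≥ 1
as the dead group and compares amino-acid percentages of the final mutated
state plus six per-residue properties (hydrophilicity, hydrophobicity,
polarity, mass, maximum SASA, polarizability; Welch t-tests). The
per-amino-acid table is vendored as TSV with the source scale for each
column named in its header.

## Structure features

Structures are homodimers; the two chains are renumbered consecutively
(chain A = 1..L, chain B = L+1..2L) so inter-monomer contacts appear in
one contact map. Contacts are Cα–Cα pairs within 8 Å; long-range
interactions (LRIs) additionally require ≥ 10 positions of renumbered
sequence separation. LRIs are clustered by k-means on their (i, j)
contact-map coordinates (10 restarts, seeded); the cluster count is the
knee of the within-cluster-sum-of-squares curve, found as the maximum
second difference with a manual override, since visual judgment is not
reproducible. Clusters are ranked by the percentage of unique hotspot
residues among their unique residues, dimer copies collapsed to monomer
positions, ties broken toward the smaller cluster id.

The residue feature matrix has 27 named columns in three blocks:

* **physicochemical (8)** — per-amino-acid lookups: molecular weight, net
  charge, hydropathy, aromaticity, side-chain hydrogen-bonding capacity,
  polarity, polarizability, flexibility;
* **local (8)** — atomic density (heavy atoms of other residues within
  5 Å of any atom of the residue), Shrake–Rupley SASA (probe 1.4 Å,
  computed on the full dimer), crystallographic B-factor (mean over the
  residue's atoms), plus four imported columns (backbone and side-chain
  conformational-entropy loss, hydrogen-bond count, frustration index)
  and local structural entropy — these come from external tools and are
  supplied as a TSV aligned by residue;
* **global (11)** — Gaussian-network-model (GNM) motional correlations
  and geometric context (below).

The GNM builds the Kirchhoff matrix over Cα atoms at a 7.3 Å cutoff
(configurable; the elastic-network flavor and cutoff were open choices),
takes its pseudo-inverse, and normalizes to unit diagonal, giving
cross-correlations in [−1, 1]. The DNA (ligand) correlation feature of a
residue is its maximum |correlation| with any of the 10 residues nearest
the DNA (ligand) sites; the maximum-correlation feature is the mean of its
5 largest |correlations| with any other residue. Closeness centrality is
computed on the unweighted residue graph with an edge wherever any
heavy-atom pair is within 5 Å; distances to centrality peaks use the 4
most prominent local maxima of the centrality profile (prominence-ranked,
manual override available). Distance-to-DNA/ligand is the minimum Cα
distance to the supplied nucleotide/ligand centers of mass; sequence
propagation is the largest renumbered sequence separation bridged by a
≤ 5 Å Cα contact. All distance comparisons are inclusive at the stated
cutoffs. Feature rows are reported for chain A in the context of the full
dimer.

## Feature importance

For each feature the package reports the F score
|mean_hot − mean_non| / (sd_hot + sd_non) (sample standard deviations,
n−1) and the Jensen–Shannon divergence between the two class histograms
(shared range, 20 bins, base-2 logarithm, hence in [0, 1]). Binning and
base were unspecified in the procedure being reproduced; these choices
make values comparable only in rank, which is how they are used.

## Classifier and feature search

The classifier is one hidden layer of 10 ReLU units and a 2-unit softmax
output, Xavier-initialized, trained with Adam at learning rate 7×10⁻⁴
under categorical cross-entropy; variants add a batch-normalization layer
in front of the hidden layer (used for wide per-mutation inputs) and
per-class loss weights. Inputs are z-scored using training-fold
statistics. Training runs 1000 full-batch epochs with no early stopping:
no epoch count or batch size was prescribed, and on 600-residue synthetic
data the cross-validated F1 of this configuration plateaus by ~1000
full-batch Adam steps (0.48 at 200, 0.89 at 500, 0.96 at 1000, 0.99 at
2000). The training loop is numba-compiled; at this model size a full
training takes ~10–50 ms, which is what makes the genetic-algorithm
search tractable on one CPU.

The fitness of a feature combination is the mean test F1 over 5 repeats
of stratified fivefold cross-validation (stratification stabilizes F1 at
~200 residues with ~25% positives; a non-stratified mode exists).
Precision/recall/F1 use the 0/0 → 0 convention. Combinations of 1–3
features are evaluated exhaustively. For 4–10 features a genetic
algorithm evolves a pool of 300 distinct combinations: each parent
produces one son by a single-feature point mutation chosen so the son was
never evaluated before (an archive enforces this); parents and sons
compete and the fittest 300 survive, so the best fitness is
non-decreasing by construction. The search stops at the generation budget
or after 5 generations without improvement. Feature-frequency analysis
counts how often each feature appears among the top-10 combinations at
each subset size. The random-model reference F1 equals the hotspot
prevalence: a predictor emitting positives at rate p on labels with
prevalence p has precision = recall = p in expectation.

One empirical regime matters for interpreting null results: trained to
convergence on label noise, this over-parameterized network memorizes its
training folds and emits positives at roughly the training prevalence, so
its cross-validated F1 approaches the random-model value; undertrained,
it collapses to the majority class and scores 0. The label-permutation
checks in the test suite therefore use a long epoch budget.

## Cross-protein prediction and transfer learning

Cross-protein prediction (CPP) trains on all residues of one or more
homologs and predicts every residue of a held-out protein; the reported
value is the mean F1 of 5 independent training runs. CPP with transfer
learning (CPP_TL) partitions the target protein's residues into 10 equal
(stratified, configurable) subsets; for each subset the pretrained
network is fine-tuned on that subset — same optimizer and learning rate,
freshly initialized optimizer moments, 1000-epoch budget — and scored on
the other nine; the mean of the 10 scores is reported. Resetting the
optimizer state at fine-tune time is load-bearing: carried-over second
moments from pretraining rescale the fine-tune steps and suppress
adaptation. Relative performance of homology-model-based features is the
F1 ratio to crystal-structure-based features, with least-squares trends
against template identity and RMSD.

Mutation-level models score individual substitutions from per-mutation
feature vectors (imported sequence embeddings, the 27 site features
broadcast per mutant, or their concatenation). Hotspots are then called
by residue-level cross-validation — all mutations of a residue stay in
one fold — ranking residues by the percentage x of their mutations
predicted dead and taking the top N (N = the experimental hotspot count),
ties broken by higher mean predicted dead-probability, then lower residue
index.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, so the whole
chain is testable offline.

**Sort-seq counts.** Variants are dead with probability `p_dead_hotspot`
at planted hotspot positions and `p_dead_other` elsewhere; defaults 0.9
and 0.01 with mean presorted depth 100, dropout 0.05, negative-binomial
counts (dispersion 10; the standard overdispersed sequencing-count
model — no generative model was prescribed). All present variants draw
full-depth uninduced-sorted counts; functional variants' induced-sorted
counts are Bernoulli-thinned (escape rate 0.02) toward zero, a stand-in
for the low-fluorescence gate — no quantitative sorting-gate model is
claimed. Positions split into two contiguous sub-library pools, mirroring
N-/C-terminal pooling. The defaults sit deliberately in the
low-background regime: at `p_dead_other` = 0.05, ~24% of non-hotspot
positions would accumulate ≥ 2 confidently dead variants by chance, the
Q3 threshold rises, and precision of planted-hotspot recovery falls below
0.8 — an analytical property of the quartile rule, not an implementation
artifact.

**Structures.** Chains are ideal helical hairpins (2.3 Å radius, 1.5 Å
rise, 100°/residue, a 4-residue turn arc) packed antiparallel, dimerized
by a 9 Å translation; the geometry guarantees bonded-continuity,
short-range and long-range contacts, and a dimer interface. Ligand sites
sit near the second arm of chain A (the "ligand-binding domain"), DNA
sites off the N terminus (the "DNA-binding domain").

**Homolog families.** Member features are iid standard normal; labels
threshold a noiseless logistic score at the (1 − prevalence) quantile, so
prevalence is exact. Coefficients are a shared rule (defaults
(2.0, −1.5, 1.0, 0.8, −0.6) on features 1–5) plus per-member Gaussian
perturbations of scale `divergence` (default 1.5) on the remaining
features — a conserved core with lineage-specific determinants. This
structure is what makes both transfer-learning effects realizable at
once: pooled multi-homolog training averages away idiosyncrasies
(helping cross-protein prediction), while fine-tuning on 10% of the
target learns them (helping CPP_TL). A mode perturbing every coefficient
isotropically is available; under it the two effects trade off against
each other as divergence varies.

What passing synthetic tests does **not** show: real sort-seq noise is
not negative-binomial with a fixed escape rate (gate drift, growth
effects and barcode crosstalk are absent); real hotspot labels are not a
noiseless function of 27 Gaussian features; and real homologs share a
fold, not an exactly conserved coefficient block. Results on synthetic
data validate the machinery and its contracts, not biological effect
sizes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the stochastic checks at
deliberately scaled sizes chosen for a single-CPU workstation: GA
searches use pool 50 over 10 generations on 300 residues with
single-repeat fivefold CV fitness and a 300-epoch budget; transfer
learning uses 400-residue families over 10 seeds; planted-hotspot
recovery uses 120-position scans over 10 seeds. Degenerate inputs are
handled explicitly: empty hotspot sets on flat score distributions (with
a warning), undefined F scores on constant features (NaN with a warning),
JSD 0 on degenerate ranges, 0/0 → 0 in classification metrics, and
errors that name the offending residue, sub-library, or feature.

## Known limitations

* SASA, closeness centrality and B-factors are computed from the
  coordinates given; no side-chain reconstruction or altloc handling
  beyond what Biopython provides.
* The GNM is the simplest isotropic elastic-network flavor; anisotropic
  models would give directional correlations.
* Imported feature columns (entropy losses, hydrogen bonds, frustration,
  local structural entropy) are consumed as given; the package validates
  alignment, not their provenance.
* The k-means knee and centrality-peak detection replace visual judgment
  with reproducible rules; on profiles with broad plateaus the automated
  choice can differ from what an expert would pick, which is why both
  accept manual overrides.
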