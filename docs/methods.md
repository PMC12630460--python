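# Methods

This note documents the models, conventions and numerical choices behind
`phytodiv`, and what its synthetic tests do and do not demonstrate about
real data.

## Data model and grouping

The atomic record is an occurrence: a standardized compound structure,
one of the seven NPClassifier biosynthetic pathway classes, a species
name, and the set of WGSRPD Level-3 regions the species is native to. A
species' compounds are attributed to **all** of its native regions — the
only reading consistent with grouping by native distributions; a compound
recorded for a species is treated as present wherever that species
natively occurs. Within a region, compounds are deduplicated by their
standardized structure string; a structure reported under two pathway
labels keeps the first label seen, with a logged conflict warning.
Regions with fewer than 7 compounds are discarded before any metric is
computed — 7 being the minimum group admitting the default rarefaction
subsample.

Structure standardization reduces multi-fragment inputs (salts,
solvates) to the fragment with the most heavy atoms and canonicalizes it.
Ties on heavy-atom count are broken by the lexicographically smallest
canonical string, making the choice deterministic. Standardization and
fingerprinting are pluggable backends: the RDKit backend provides real
chemistry (canonical SMILES; hashed circular/Morgan fingerprints, radius
2, 2048 bits), while the hashed backend derives deterministic sparse bit
sets (64 of 2048 bits) from a cryptographic hash of the structure string,
so synthetic pipelines need no chemistry at all.

The bundled region-code list is a curated subset of the Level-3
"botanical country" codes; unknown codes are accepted with a warning
rather than rejected, so user-specific schemes pass through.

## Compound-level metrics

FAD is implemented exactly as the printed double sum over all ordered
pairs including the zero diagonal, so it equals twice the unordered-pair
sum — this matters when cross-checking against packages that sum each
pair once. MFAD = FAD/N and APWD = FAD/(N²−N) follow. For a single
compound FAD = MFAD = 0 and APWD is null. Distances are Tanimoto
(Jaccard) distances on fingerprint bit sets; two empty fingerprints are
defined as identical (distance 0) with a warning. The N×N distance
matrix is computed per group and released afterwards; memory is O(N²)
only within a group. An optional plain-CSV distance cache keyed by the
sorted structure pair lets users persist expensive distances.

## Pathway-level metrics

All sums run over pathways with `p_i > 0` (the 0·ln 0 = 0 convention).
Coverage uses the singleton estimator `C = 1 − f1/N`; doubleton-based
estimators give very similar values on data of this shape and are not
implemented. When every pathway present is a singleton (C = 0) the
adjusted abundances vanish and `Hbc` is reported as null rather than a
degenerate number; likewise Pielou's J is null when P = 1. Nulls
serialize as empty CSV cells so region rows are never silently dropped.

## Rarefaction

Subsamples are drawn **without replacement** — groups are finite
deduplicated sets, and with-replacement draws would admit duplicates the
data model forbids. Defaults: subsample size m = 7 (the number of
pathway classes) and 1000 replicates. One subsample set is shared by all
metrics within a region; this is cheaper than redrawing per metric and
unbiased for the means. Replicates on which a metric is null (e.g. J on
a single-pathway subsample) are excluded from the mean and the null
fraction is reported alongside; if every replicate is null the rarefied
value is null. Each region's random stream is seeded from (master seed,
SHA-256 of the region code), so results are independent of the order in
which regions are processed.

A useful identity for validation: each unordered pair survives a size-m
subsample with probability m(m−1)/(N(N−1)), so the expected subsample
FAD is m(m−1)·APWD = 42·APWD at m = 7. The test suite checks observed
means against this to within Monte-Carlo error.

## Phylogenetic diversity

Faith's PD is the summed branch length of the minimal subtree spanning
the species set. The default convention spans from the set's MRCA down
to its leaves (a singleton species has PD 0); the alternative that also
counts the MRCA-to-root stem is available via `include_root=True` /
`--pd-include-root`, since both conventions are in circulation and the
choice is recorded in the run configuration. Species absent from the
tree are dropped from both SR and PD so the two are computed over the
same leaf set. Missing branch lengths parse as 0 with a warning;
polytomies are preserved; duplicate leaf labels are a hard error.

Richness-independent PD′ is the residual of PD after a LOWESS fit of PD
on SR — local linear fits with smoothing fraction 2/3 and 3 robustifying
iterations (the defaults of the statsmodels implementation used), both
exposed as configuration. Tied SR values receive identical fitted
values. Residualizing fewer than 10 regions is refused.

## Association analysis

Each variable is Yeo–Johnson transformed, with λ chosen by bounded Brent
maximization of the Gaussian profile log-likelihood over λ ∈ [−5, 5],
then standardized to mean 0, SD 1. Nulls are excluded from the fit and
re-inserted as nulls. Because the transform is strictly monotone,
Spearman correlations are identical on raw and transformed data (the
suite asserts this to 1e−12); the transform matters for the LOWESS
residual step, which runs on the transformed scale.

Spearman ρ uses midranks for ties; two-sided p-values use the usual
t-approximation for n ≥ 10 and exact enumeration of all n! rank
permutations below that. Null metric values are deleted pairwise — J's
nulls do not shrink unrelated comparisons — and the per-pair n is
reported. Raw p-values are reported (matching the convention of
presenting uncorrected two-sided tests), with a Holm step-down column
alongside for users who want familywise control.

Outlier flagging fits a LOWESS of each metric on PD and standardizes the
residuals with the sample (n−1) SD; regions with |z| > 2 are flagged
high or low. Residual SDs at numerical-noise level (a curve that fits
exactly) yield no flags. Output is sorted by region code and therefore
independent of input row order.

## Synthetic studies

The generator emulates the statistical shape of compiled phytochemical
data:

- **Compounds per species**: log-series (p = 0.9, so about two-thirds of
  species carry ≤ 3 compounds) with a 2% admixture of "superproducer"
  species with geometric counts of mean 80, reproducing the long tail of
  intensively studied species with > 100 compounds. A zero-truncated
  negative binomial is available as an alternative.
- **Pathways**: a global base mixture skewed toward terpenoids and
  alkaloids; each region draws its own pathway mixture from
  Dirichlet(α · base), and species inherit the mixture of their primary
  native region. The concentration α is an evenness dial: small α gives
  pathway-dominated regions (low J), large α makes every region mirror
  the base mixture. The suite verifies that mean region J increases
  monotonically in α.
- **Regions**: codes drawn from the bundled Level-3 list, with
  log-normal attractiveness weights (σ = 1.5) producing a few
  mainland-like regions and many small, island-like ones; species span
  1 + Poisson(1) regions.
- **Compound sharing**: a global library of 1500 compounds with
  log-normal popularity; species sample compounds ∝ popularity × their
  pathway mixture, so common compounds recur across species and regions.
- **Phylogeny**: a Yule (pure-birth) tree over all species.
- **Fingerprints**: deterministic sparse hashes of the structure ID.

The standard scenario is 500 species, 30 regions, 1500 compounds,
α = 20. Everything derives from one master seed, and reruns are
byte-identical.

What passing tests on such data show — and do not show. The generator
reproduces the sampling-effort skew, pathway unevenness, region-size
heterogeneity and SR–PD coupling that the methods must cope with, so the
tests demonstrate correctness of the metrics and the internal consistency
of the pipeline under realistic distributional shape. They do not
demonstrate anything about real chemistry: hashed fingerprints are
near-equidistant (APWD concentrates around the random-bit expectation,
with none of the clustered similarity structure of real molecules), the
tree is not a dated megatree, and region assembly ignores biogeography.
Conclusions about real floras require real occurrence data, real
fingerprints and a real phylogeny — the pipeline accepts all three
through the same interfaces.

## Problem sizes and defaults

Default analyses use the standard scenario above with 1000 rarefaction
replicates; the whole simulate→compute→associate pipeline on it runs in
about one second on a single core, and the test suite covers groups up
to a few hundred compounds and trees up to 500 leaves. All tolerances in
the suite are stated per test: exact identities at 1e−12 (relative where
sums of hundreds of terms are compared), Monte-Carlo checks at 3
standard errors, and statistical structure-recovery checks at the rates
given in the test docstrings.

## Known limitations

- `Hbc` follows the singleton (Chao–Shen) coverage form given above;
  doubleton-based coverage is not implemented.
- Functional Hill numbers are deliberately excluded: with equal
  abundances 1/N they reduce to functions of FAD.
- β-diversity between regions, abundance-weighted metrics, and
  cumulative-diversity region optimization are out of scope.
- The exact permutation p-value enumerates n! orderings and is used only
  for n < 10.
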