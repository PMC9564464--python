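# Methods

This note documents the models and procedures `spanet` implements, the
choices made where the methodology literature leaves latitude, and what
the synthetic-data experiments do and do not demonstrate.

## Gravity-model network construction

The directed intensity between regions *i* and *j* is

    y_ij = k_ij * (G_i P_i T_i C_i)^(1/4) (G_j P_j T_j C_j)^(1/4) / D_ij^2
    k_ij = C_i / (C_i + C_j)

with G gross regional product (constant-price currency), P population
(persons), T technology level (patents granted), C pollutant
concentration (µg/m³), D inter-capital distance (km). The fourth-root
product is an IPAT-style composite mass (impact = population × affluence
× technology, augmented with the pollutant level itself); the weight
k_ij splits each dyad's intensity by the two regions' pollution shares,
so the matrix is asymmetric with k_ij + k_ji = 1. All four attributes
must be strictly positive (k is undefined at C = 0) and distances
strictly positive off the diagonal.

Binarization takes each row's mean as that row's critical value and
records a directed tie where the intensity strictly exceeds it. Two
conventions needed fixing:

* **Diagonal handling.** The structural zeros on the diagonal are
  excluded from the row mean by default. Including them (an option,
  `include_diagonal=True`) shrinks every threshold by a factor
  (n−1)/n and only adds ties; excluding them is the unbiased reading.
* **Ties.** A value exactly at the row mean maps to 0 (strict `>`); a
  `>=` variant is available for sensitivity checks. With continuous
  attributes ties have probability zero, so the choice matters only
  for degenerate inputs (a constant row produces no ties).

Direction convention: `a[i, j] = 1` means row-region *i* sends an
association to column-region *j*. Useful consequences, all tested:
row-mean thresholding is invariant to rescaling any row of y (hence to
multiplying all regions' attributes by a common constant, which scales
every y_ij by c²), and every non-constant row sends at least one tie.

## Whole-network indices

Density is the arc count over n(n−1). The other three indices follow
Krackhardt's (1994) graph-theoretic dimensions as operationalized in
standard SNA software:

* **connectedness** = 1 − (unreachable unordered pairs)/C(n,2), on the
  underlying undirected graph;
* **hierarchy** = 1 − (mutually reachable pairs)/(pairs reachable in at
  least one direction), on the directed reachability relation, defined
  as 0 when no pair is reachable (edgeless network);
* **efficiency** = 1 − (edges beyond a spanning forest)/(maximum
  possible surplus), per connected component of the underlying graph,
  defined as 1 when no surplus is possible.

Hierarchy is the "one-way reachability" variant; published software
differs in details here, so the implementation is validated against an
independent exhaustive-enumeration oracle on all sampled digraphs with
n ≤ 6 rather than against any single program. Reachability is computed
by boolean matrix squaring; components via scipy.

## Centrality conventions

All three node measures are reported in percent, matching UCINET-style
report tables.

* **Degree.** Two conventions are exposed because report tables in this
  literature are not consistent with the printed formula: `"neighbor"`
  (default) is 100·|unique neighbours in the symmetrized graph|/(n−1),
  which reproduces the packaged worked-example table (e.g. a node with
  27 in- and 6 out-neighbours, 27 unique, scores 90.0); `"eq2"` is
  100·(Ind+Out)/(2(n−1)), the textbook directed form (the same node
  would score 55). In- and out-degrees are always reported alongside.
* **Betweenness.** Freeman betweenness with normalization
  2/((n−1)(n−2)), ×100, computed on the symmetrized graph by default
  (the normalization is the undirected one); pair terms with no
  connecting path contribute zero. A directed option uses directed
  geodesics with the directed normalization.
* **Closeness.** The reciprocal-farness form 100·(n−1)/Σ_j d_ij. (The
  farness form Σd/(n−1) appears in print in this literature; the values
  actually tabulated are its reciprocal ×100, which is what is
  implemented.) For nodes that cannot reach all others the default
  evaluates the formula within the node's reachable set and flags the
  node (isolates score 0); a strict mode scores any such node 0.

## CONCOR blockmodeling

Profiles are each node's adjacency row and column concatenated (the
natural choice for directed data; row-only and column-only variants are
options). The algorithm:

1. Compute the node-by-node Pearson correlation matrix C₁ of profiles.
   Zero-variance profiles (isolated nodes) get correlation 0 with a
   warning, never an exception.
2. Iterate: replace the matrix by the correlation matrix of its own
   rows, until every off-diagonal entry is within `conv_tol` of ±1
   (default 0.2, the "concentration criterion"), capped at `max_iter`
   = 25 iterations.
3. Split by sign against the first node's row. Entries still farther
   than `conv_tol` from ±1 are assigned to the side with the higher
   mean correlation.
4. Recurse on the submatrices of C₁ to the requested depth (default 2,
   at most 4 blocks). Groups of ≤ 2 nodes, and groups that do not
   polarize into two signs, are not split further.

Recursing on submatrices of the *first* correlation matrix (rather than
re-deriving profiles per subgroup) is the classical formulation of the
procedure. The partition is invariant under node relabeling up to block
numbering; blocks are numbered by their first member and labelled with
Roman numerals in reports. `ConcorBlockModel` follows the scikit-learn
clusterer protocol (`fit`, `fit_predict`, `labels_`, `get_params`).

On planted-partition graphs the procedure is validated by recovery: at
p_in = 0.8, p_out = 0.1 with two 8-node blocks, depth-1 CONCOR recovers
the planted bipartition in ≥ 95 of 100 seeded replicates (observed:
100/100).

## Block accounting and spillover roles

For each block: `inside` counts internal arcs (identical from the
sending and receiving perspective), `outside_sent`/`outside_received`
the arcs crossing the block boundary. The expected internal ratio is
100·(n_k−1)/(n−1) — the share of a member's potential partners that are
inside the block — and the actual ratio 100·inside/(inside +
outside_sent). (Published tables in this literature sometimes mix
(n_k−1)/(n−1) and n_k/(n−1) across rows; the implementation reports the
former uniformly, and the fixture-verification harness checks the
packaged table's own arithmetic as printed.)

The block density matrix divides arc counts by n_k·n_l (n_k(n_k−1) on
the diagonal); its size-weighted mean equals the overall density
exactly, which is asserted to machine precision. The image matrix cuts
densities at the overall network density (≥ by default, configurable
to strict >).

Roles are assigned from ρ = total received / total sent: ρ ≥ 2 net
benefit; 1 ≤ ρ < 2 two-way spillover; 0.25 ≤ ρ < 1 broker; ρ < 0.25 net
spillover; blocks that send nothing are unclassifiable. The qualitative
role definitions in the literature do not pin down numeric cutoffs;
these defaults are a deterministic operationalization calibrated to
reproduce the packaged worked example's four assignments, are exposed
as a parameter, and should not be read as canonical constants.

## QAP and MRQAP

Matrices are vectorized over their n(n−1) off-diagonal cells. The
correlation test permutes rows and columns of the second matrix by one
random node relabeling per draw and recomputes the Pearson correlation
(vectorized over all draws). The regression fits OLS with intercept,
then refits under relabelings of the outcome matrix only (classic
Y-permutation; Dekker-style double semi-partialling is deliberately not
implemented — it is a refinement with a different null). The fit is
performed on z-scored covariates for numerical stability (difference
matrices of raw regional attributes span many orders of magnitude) and
coefficients are unscaled afterwards; permutation tails are invariant
to that rescaling. Reported per covariate: unstandardized coefficient,
standardized coefficient b·sd(x)/sd(y), both tail probabilities, and
`significance` = the tail on the observed sign side. Ties (permuted
statistic equal to the observed within 1e-12) count in both tails,
making the tests conservative; p_ge + p_le ≥ 1 always.

Calibration is demonstrated by simulation: under independent
Gaussian-noise matrices (n = 20, 2000 permutations, 500 replicates) the
one-tailed rejection rate at α = 0.05 of both the correlation test and
an MRQAP coefficient test lies within binomial 3σ of 0.05. (The
`significance` column is one-tailed; rejecting on min(p_ge, p_le) ≤ α
is a two-sided test at level ≈ 2α and is not the calibrated quantity.)
Power: a planted dyadic effect β = 2 (noise sd 0.5, n = 25) is detected
at α = 0.05, with the null covariate not detected, in ≥ 90% of 100
replicates (observed: 100%).

Collinear covariate designs are rejected with the offending matrices
named. Zero-variance off-diagonal vectors are errors for the
correlation (undefined r) and for the outcome of the regression.

## Synthetic data: what it emulates, and what it does not

`generate_panel` draws each region's log-attributes once from an
equicorrelated Gaussian (common-factor correlation ρ = 0.5 by default —
larger, richer regions patent more, drive more and pollute more), then
adds small independent year noise (sd 0.05 on the log scale) and a
deterministic annual drift (positive for product, patents and car
ownership, slightly negative for the pollutant). Marginals are
log-normal with locations and scales chosen to mimic the magnitudes of
provincial statistics (population ~10⁷·⁵ persons, product ~10¹² currency
units, PM₂.₅ ~35 µg/m³, fiscal and industrial shares as fractions).
Coordinates are uniform on a square and Euclidean distances rescaled to
[100, 3000] km, the span of inter-capital distances at sub-continental
scale. Defaults: 31 regions × 12 years, first year 2009.

The generator deliberately does **not** reproduce: spatial
autocorrelation of attributes (coordinates and attributes are
independent), real geography or border structure, serially correlated
shocks, policy interventions, or measurement error. Passing tests on
synthetic data therefore demonstrate that the *machinery* is correct
and calibrated — not that any substantive conclusion about real
regional pollution transfers. The packaged worked-example tables cover
the complementary ground: they pin the report-level arithmetic to a
real published analysis whose raw inputs are not redistributable. One
known blemish of those tables is recorded by the verification harness:
the printed block density matrix and flow table disagree by two arcs
(248 vs 250 implied ties), so the weighted-average-density fixture
check is held to rounding tolerance (0.005) rather than machine
precision, which *is* enforced on computed partitions.

## Numerical choices and problem sizes

Correlations are clipped to [−1, 1]; constant profiles correlate 0;
permutation tie tolerance 1e-12; image-matrix cut is ≥; CONCOR depth 2,
tolerance 0.2, max 25 iterations by default. The test suite and the
acceptance script size their simulations to what the statistical claims
need: exhaustive oracles up to n = 6 (enumeration beyond that adds cost,
not information), 100 replicates for recovery/power rates, 500
replicates × 2000 permutations for type-I calibration at n = 20. The
full suite runs in well under a minute on one CPU.

## Known limitations

* Only the inverse-square-distance, fourth-root-mass gravity form is
  implemented; no alternative exponents or economic-distance
  denominators.
* MRQAP offers Y-permutation only (no DSP), and no logit variant for
  binary outcomes — coefficients on a binary network are linear
  probability effects.
* The hierarchy index is one specific variant of a measure that
  published software implements inconsistently; cross-package numeric
  agreement is not guaranteed.
* CONCOR is a deterministic divisive heuristic: it always produces a
  bipartition when signs polarize, even on structure-free data, and
  block counts below 2^depth occur when groups are small or fail to
  polarize.
* QAP covariates built from panel attributes default to
  period-mean difference matrices; year-specific matrices are supported
  but the choice of aggregation is the user's.
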