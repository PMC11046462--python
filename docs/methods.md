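# Methods

## The selection model

The workflow treats scope design as a coverage problem over a reference
chemical space. A reference library (a drug library in the motivating use
case; any SMILES list is accepted) defines the space; candidate substrates
are chosen so that every region of that space is represented by exactly
one substrate. The pipeline is:

ECFP featurization → UMAP 2-D embedding (Jaccard metric) → Ward
agglomerative clustering → candidate filtering → projection onto the
frozen map → greedy per-cluster nearest-center selection.

Assumptions worth stating explicitly:

* Structural similarity (fingerprint Jaccard distance) is a useful proxy
  for "tells you something different about the reaction". The method
  cannot see electronics beyond what circular substructures encode.
* The 2-D embedding preserves enough of the fingerprint geometry for
  center proximity to be meaningful; this is exactly what metric D
  monitors, and why the embedding uses the same Jaccard metric D is
  defined on.
* Cluster centers are taken in embedding space (centroids), not in
  fingerprint space, because the selection operates on the projected map.

## Standardization (chem_io)

Input SMILES are canonicalized as the neutralized largest covalent
fragment: supplier catalogs list salts and solvates, and counterion bits
would distort fingerprint distances. Duplicates (identical canonical
SMILES) keep the first occurrence, which makes deduplication
order-auditable. Molecular weight is always recomputed from the
standardized structure so the MW filter has one source of truth. Records
that cannot be parsed are rejected with machine-readable reasons
(`parse_error`, `duplicate`, `empty`), never silently dropped.

## Fingerprints

Binary Morgan/ECFP fingerprints, radius 2 (bond steps), folded to 2048
bits — the de facto ECFP4-equivalent standard. Binary rather than count
vectors keep Jaccard distance a true metric; chirality is not encoded
because the workflow operates at scaffold level and supplier lists often
omit stereochemistry. Both parameters are configurable; `n_bits` must be
a power of two ≥ 256 (folding collisions shrink monotonically as the
width grows).

## Embedding and its quality metrics

UMAP with `n_components = 2`, `metric = "jaccard"`, and the defaults
`n_neighbors = 30`, `min_dist = 0.1` (the workflow's optimized values).
`n_neighbors` trades local detail against global structure; `min_dist`
sets the packing floor in the plane. Runs are seeded (`seed = 42` by
default), which also forces single-threaded, bit-reproducible fits.

* **D** is the Pearson correlation between fingerprint Jaccard distances
  and embedded Euclidean distances over up to 50 000 unordered molecule
  pairs sampled without replacement from a seeded generator (all pairs
  when fewer exist). The estimator ("pearson"/"spearman") and the sample
  size are configuration knobs; Pearson on sampled pairs is the scalable
  default. Degenerate inputs (zero variance in either distance list)
  raise rather than returning NaN.
* **S** is the silhouette score of the embedding clustered at the working
  cluster count.

`scan_embed_params` fits a grid of (n_neighbors, min_dist) points and
sorts by the descending rank-sum of (D, S): both metrics matter and
rank-sum avoids mixing their scales. Grid points that violate fit
preconditions (e.g., `n_neighbors ≥ n`) become `failed` rows instead of
aborting the scan. Note that `n_neighbors < 2` and `min_dist ≥ 1` are
rejected at parameter construction, before any scan.

Projection of new molecules uses the frozen fit (`umap.UMAP.transform`,
itself internally seeded). A projected copy of a training molecule lands
near — not exactly on — its training coordinate; on the packaged fixtures
its nearest training neighbor is itself for every molecule at the default
seed, and the tested contract is ≥ 90%.

## Clustering

Hierarchical agglomerative clustering with Ward linkage on Euclidean
distances in the plane: compact, visually separable clusters, no RNG.
The default cluster count is k = 15, configurable, with a silhouette scan
over 10–25 (`scan_cluster_numbers`); fewer than ~10 clusters would ignore
relevant structural motifs while more than ~25 substrates is impractical
to test at the bench. Cluster names A, B, C, … are assigned in order of
decreasing cluster size (deterministic and auditable; the naming rule is
a package choice). Centers are centroids — parameter-free and consistent
with measuring candidate distance in embedding space; a medoid variant
would avoid centers falling in empty space between subclusters but adds a
tie-break rule, and was not needed on tested data. Singleton clusters
contribute 0 to the silhouette mean.

## Filtering and selection

`FilterSpec` combines numeric thresholds (MW < 700 Da, price < 100 per
gram by default) with named SMARTS rules. All SMARTS compile at
construction time so configuration errors surface at load, never mid-run.
Shipped exclusion patterns:

* `tetrasubstituted_alkene`: `[C]([#6])([#6])=[C]([#6])[#6]`
* `free_amine`: primary/secondary aliphatic amines that are not amides,
  sulfonamides or anilines —
  `[NX3;H2,H1;!$([NX3][#6X3]=[OX1,SX1,NX2]);!$([NX3]S(=O)=O);!$([NX3]c)]`

These encode the chemical classes by their common definitions; they are
editable data, not code. Candidates with no price are kept by default
(dropping unknowns would bias toward catalog completeness); a
`keep_missing_price = false` switch inverts that.

Every surviving candidate is ranked against **every** cluster center by
Euclidean distance (ties broken by canonical SMILES, then id — fully
deterministic). Selection is greedy nearest-first: clusters are processed
in order of their best rank-1 candidate distance (ties by cluster name),
and each takes its closest available, not-yet-consumed candidate within
the top-n fallback window (n = 5 default). With `unique = true` (default)
no candidate represents two clusters. A cluster whose window is exhausted
is reported unserved with a warning, never an error. The resulting
contract: for every served cluster, no available candidate not already
consumed by an earlier (closer) cluster lies strictly closer to its
center.

## Synthetic fixtures

The fixture generator emulates the one statistical property the method
relies on: a reference library organized into scaffold families with
small intra-family and large inter-family fingerprint distances. Each of
the 15 default families is a distinctive core template (alkyl chain,
styrene, pyridine, pyranose, amide, urea, sulfonamide, terpenoid-like,
lactam, aniline, phenol, halobenzene, morpholine, thiophene, benzamide)
crossed with a 24-point substituent grid; 20 molecules per family are
drawn by seeded sampling of the grid, giving 300 reference molecules with
mean intra-family Jaccard distance ≈ 0.54 versus ≈ 0.91 inter-family.
Candidate fixtures are olefin-bearing analogs of the same families
(12 per family, 180 total), with lognormal prices centered near 40
currency units/g (so the 100/g cutoff bites on a realistic minority) and
85% availability. Generation is enumeration-first: the seed controls only
which grid points are sampled, and every emitted SMILES is validated and
canonicalized at generation time.

What the fixtures do **not** emulate: pharmacological realism,
drug-likeness, the long tail of singleton scaffolds, mixtures/biologics,
or the density imbalance of real supplier catalogs. Passing tests
demonstrate that the machinery recovers planted structure under the
method's assumptions; they say nothing about how well a particular real
reference library clusters.

## Numerical and degenerate-input choices

* Jaccard distance of two all-zero vectors is undefined and raises; a
  molecule with ≥ 1 heavy atom always has at least one bit set.
* All CSV floats are written with fixed precision (6 decimals for
  coordinates/distances) so reruns are byte-identical.
* `k = 1` clustering is rejected (silhouette undefined downstream);
  `k = n` degenerates to one point per cluster and is allowed.
* Problem sizes used in tests and in the acceptance script: 300 reference
  molecules, 180 candidates, 50 000-pair cap for D, 20 permutation seeds
  for the baseline check — sizes at which every stochastic contract holds
  with margin while a full run stays under half a minute.

## Known limitations

* UMAP determinism is per-environment: identical seeds reproduce results
  on one machine/library version, not necessarily across versions.
* Distances for selection are measured in the 2-D projection; molecules
  mapped close may differ in features the projection discarded. Metric D
  quantifies, but does not remove, that loss.
* The greedy unique assignment is order-dependent by design (documented
  tie-breaks), not a globally optimal matching; an optimal-transport
  assignment would change at most a few clusters and is out of scope.
* Only ECFP fingerprints and agglomerative clustering are implemented;
  the module boundaries would admit alternatives, but none are shipped.
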