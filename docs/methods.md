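# Methods

## Model

Images live in a feature space R^d; a database is an ordered list of
(id, class label, vector) records.  Similarity is the Euclidean distance on
raw features — no L2 scaling, centering or whitening is applied, matching
how fully-connected-layer activations are compared in the retrieval
literature this package follows.  Retrieval is exhaustive nearest-neighbour
ranking; no approximate index is used (the intended database sizes are a
few hundred to a few thousand images).

Query expansion is pseudo-relevance feedback specialised to class-labelled
databases.  For a query Q the rapid search keeps, per class, the k nearest
images; their component-wise mean (in double precision) is that class's
expansion (NQE).  The expansion nearest Q (the FNQE) probes the final
search.  The intuition: if Q belongs to class c, the k nearest members of c
are mostly true neighbours and their centroid is a denoised stand-in for Q,
while other classes' centroids sit farther away; choosing the nearest
centroid therefore both classifies Q and replaces it with a more stable
probe.

### Assumptions

- Class labels are exhaustive and mutually exclusive; relevance in
  evaluation is exact label equality.
- Features are finite reals of one common dimension; the distance is
  meaningful on raw (unnormalised) values.
- Classes are at least somewhat compact in feature space: the mean of a
  class's nearest members must be a better probe than a single noisy
  vector for the expansion to help.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `k` | 10 | per-class pool size in the rapid search; classes smaller than k contribute all members (the mean is defined for any member count) |
| `n_retrieved` / cutoffs | 10, curves 1..10 | number of final results scored |
| `include_query` | true | keep the query's own record in the index when it is a database member; the standard protocol does, which is why top-1 precision is 100% by construction |
| `restrict_to_fnqe_class` | false | final search ranks the whole database by default; the flag limits it to the selected class |
| toy descriptor dim | 32 | 16 intensity bins on [0,1] ⊕ 16 gradient-magnitude bins on [0,√2], each block L1-normalised |

All distances are reported as true Euclidean values; ranking internally
sorts plain distances (no squared-distance shortcut is needed at these
sizes).

## Determinism and tie-breaking

Record order in a database is significant and stable: equal distances keep
database order (stable sort), FNQE ties go to the earliest class, and file
trees are traversed in sorted (class, filename) order, so identical inputs
give byte-identical outputs across runs and machines.  The `--no-timestamp`
flag removes the only non-deterministic field (store creation time).

## Feature extractors

The deep backends take the 4096-dim activations of AlexNet's sixth
(first fully connected) layer or VGG-16/19's FC1 (FC2 selectable, since FC2
occasionally wins on CT data).  Preprocessing — resize to the backbone's
native input (227 px AlexNet, 224 px VGG), grayscale replicated to three
channels, ImageNet channel normalisation — is a documented choice, not a
claim of bit-compatibility with any particular published pipeline.  DICOM
pixel data gets rescale slope/intercept applied, then per-slice min–max
scaling to [0,1], so CT values reach the dynamic range the backbones expect.
These backends are optional (`pip install rbqe[deep]`); requesting one
without torch installed raises an explicit error rather than falling back
silently.

The `toy_histogram` descriptor exists so the full pipeline can run and be
tested without network access or model weights.  It is deliberately crude
(a global intensity + gradient histogram) but deterministic, format-
invariant, and separable on the synthetic textures the generator produces.

## Synthetic data

`gen_feature_db` draws one isotropic Gaussian cluster per class.  Centers
sit at (separation/√2)·e_c on orthogonal axes, so every pair of centers is
exactly `separation` apart (this requires dim ≥ n_classes); `sigma` is the
within-class standard deviation, making `separation/sigma` the single
difficulty knob.  Defaults (4 classes of 75/50/58/41 images, 64 dims,
separation/sigma = 50) mirror the shape of a small CT benchmark at desk
scale.  Each class draws from its own substream seeded by (seed, class
index), so adding a class never perturbs earlier classes.  `gen_image_tree`
writes PNG textures (per-class mean intensity and oriented grating, plus
pixel noise) for end-to-end extractor tests.

What the generator does **not** emulate: anatomical structure, correlated
feature dimensions, heavy-tailed activation distributions, unequal
within-class spreads, or label noise.  Passing tests on these fixtures
therefore demonstrate correctness of the algorithmic pipeline and its exact
small-sample behaviour, not retrieval accuracy on real CT/MR collections —
the published full-scale benchmark figures require the original image
databases and pre-trained weights and are out of scope here.

## Numerical choices

- Means and distances accumulate in float64 regardless of input precision;
  the six-component worked example reproduces its printed means exactly at
  the printed rounding.
- F-score at ARP = ARR = 0 is defined as 0 (the harmonic mean's limit) with
  a logged note, since the formula is otherwise undefined there.
- Metrics are computed in double precision and printed at 2 decimals.
- The recall denominator is the full class size, including the query image
  itself when it is in the database (flag-controlled in the evaluator).

## Test design

Every pipeline stage is checked against an independent brute-force oracle
written as plain Python loops (per-component sum of squares, stable
distance-then-index sort, filtered global ranking, one-component-at-a-time
averaging, argmin over a distance list) on databases up to 200 records with
deliberately tie-heavy integer features.  Metric identities (harmonic-mean
bounds, ARR = ARP·N/s for uniform class size s, record-order invariance,
weighted per-class ARP reconstitution) are asserted exactly.  Recovery
tests use separation/sigma = 50, where perfect ARP@10 and expansion-class
accuracy are guaranteed by construction and verified over five seeds.  A
soft robustness check at moderate noise (separation 6, sigma 1.5) logs the
seed-averaged ARP@10 of expansion vs direct retrieval — the expansion
comfortably exceeds direct there — and asserts only a generous lower bound,
since the magnitude of the gain on real data is not something synthetic
clusters can establish.

## Problem sizes

Test and acceptance databases range from 5 to 235 records (dims 1–64);
evaluation runs every image as a query, so the largest single computation
is a few hundred exhaustive rankings of a few hundred records — chosen to
exercise every code path and all tie-breaking exactly, which small dense
problems do better than large ones.

## Known limitations

- Exhaustive search scales linearly in database size per query; no ANN
  index is provided.
- The expansion assumes the database's class partition is meaningful; with
  random labels it degrades to direct retrieval quality.
- Deep-backend preprocessing choices (resize, channel replication,
  windowing) are defaults, documented above; activations will differ from
  pipelines that made different choices.
- Alternative distances (Manhattan, chi-square) are not implemented.
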