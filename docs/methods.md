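# Methods

## Problem setting

`plmsim` evaluates whether pooled per-residue embeddings from pretrained
protein language models behave as proxies for protein *function*, using
sequence identity as the evolutionary baseline. Three readouts are
implemented: prediction of cross-species complementation among candidate
orthologs, concordance between the identity-preferred and
embedding-preferred paralog in one-to-two orthogroups, and a regression of
embedding similarity on percent identity per orthology category with
flagging of low-similarity outliers.

## Pooling

**Mean pooling** is the column-wise average of the residue rows — the
d-dimensional first moment of the residue-embedding distribution.

**Sliced-Wasserstein embedding (SWE).** The residue matrix *E* (n × d) is
treated as an empirical distribution. With L frozen unit directions θ_ℓ
(normalised iid Gaussian draws) and M frozen reference points R (iid
Gaussian entries), each slice computes the signed monotone-transport
displacements between the projected protein and the projected reference:

    u_ℓ[m] = q_{E·θ_ℓ}((m − ½)/M) − sort(R·θ_ℓ)[m]

with q the empirical quantile function under the midpoint convention
(sorted value x_(i) sits at level (i − ½)/n; linear interpolation between,
clamped at the extremes). For n = M this is exactly sorted(x) − sorted(r),
the optimal 1-D transport map, which the tests verify against exhaustive
assignment search for M ≤ 4.

Open design points the SWE literature leaves to the implementer, and the
choices made here (all config-exposed):

* **Slice combination.** Per-slice vectors are *concatenated* into a
  length-L·M representation (an `average_slices` option averages them to
  length M instead). Concatenation preserves per-slice information.
* **Layer combination.** When the last k ∈ {1, 4, 8} model layers are used,
  pooling happens per layer and the pooled vectors are averaged
  element-wise — a deliberately learning-free replacement for the learned
  combination weights of trainable SWE variants.
* **Signed displacements**, not absolute distances: the zero case (protein
  distribution equals the reference on every slice) is then exactly the
  zero vector.
* **Defaults** L = 64, M = 128, standard-Gaussian reference, following the
  scale used by frozen-SWE set-pooling practice. Ties in sorting are broken
  by stable sort for determinism.

## Embedding backends

The default backend is a deterministic mock: each residue's vector is a
seeded hash of its centred window k-mer and the layer index, so sequences
sharing local context share rows and every downstream stage runs with no
model weights. The transformer backend adapts any Huggingface checkpoint,
extracts the hidden states of the last k layers, and strips special-token
(BOS/EOS/CLS) rows before pooling — pooled vectors must represent residues
only, since length-dependence of mean pooling is one of the effects under
study. Whether published PLM analyses strip special tokens before averaging
is usually unstated; this choice is therefore a reproduction risk when
comparing against published accuracies. Matrices round-trip through a
`.npy` + JSON-sidecar cache losslessly; cached entries short-circuit the
backend entirely.

## Complementation prediction and its statistics

The predicted complementer of a case is the candidate with the maximum
cosine similarity to the reference protein's pooled embedding; an exact tie
yields no prediction and scores as incorrect. Pooling strategies are
compared on *paired* per-model accuracies with a Wilcoxon signed-rank test:
zero differences are discarded (classic convention; a Pratt option keeps
their ranks), ranks of tied absolute differences are averaged, and the null
distribution of W⁺ is computed exactly for ≤ 25 nonzero pairs via the
generating-polynomial convolution over doubled ranks (equivalent to
enumerating all 2ⁿ sign patterns, which the tests do directly for n ≤ 10);
beyond that, a normal approximation with tie-corrected variance
Var(W⁺) = Σrᵢ²/4 and continuity correction is used.

## Sequence identity

Identity is computed from an optimal global alignment (Needleman–Wunsch
with affine gaps) as identical columns divided by full alignment length,
gap columns included (a `nongap` denominator is available). Defaults follow
the EMBOSS-needle convention: BLOSUM62, gap open 10, gap extend 0.5, end
gaps free. Residues outside the matrix alphabet (U, O) are mapped to X.
Alignment is delegated to Biopython's `PairwiseAligner`; the test suite
checks its configured scores against an independent quadratic-time Gotoh
DP. Pair identity is computed in a canonical sequence order so it is
symmetric regardless of traceback tie-breaking. Note one domain limit: for
substitution-only pairs the gap-free alignment is score-optimal only up to
roughly 25% substitution load under these defaults — beyond that, a
higher-scoring shifted alignment with free end gaps can change the identity
slightly, so "identity equals Hamming fraction" is asserted only in that
regime.

## Orthology analyses

Orthogroups are read from two-species TSV tables (`group_id`, `species`,
`protein_id`); groups are categorised purely by member counts — (1,1)
one-to-one, (1,2) one-to-two, (1,≥3) one-to-many, (≥2,≥2) many-to-many.
The LDO of a single-copy gene is the co-ortholog with the highest percent
identity; exact ties propagate a `tied` status. A one-to-two group is
concordant when LDO and embedding-top paralog coincide. The conjecture
analysis fits similarity on identity by OLS *per category*, once, with
prospective outliers included (no robust or iterative refit — the simplest
defensible reading), uses the N−2 residual SD, and flags |residual| > k·SD
with k = 3 by default. Identity bins are half-open 10-point bins with the
last bin closed at 100; both k and the width are parameters.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *decision structure* of the real analyses, not
protein biology:

* **Residue matrices** are isotropic Gaussians around a protein centroid —
  no residue correlations, no length-composition coupling. Protein lengths
  are drawn independently of functional shift so length sensitivity of mean
  pooling can be isolated. Default d = 16 (real models use 320–1152) for
  speed on identical code paths.
* **Complementation cases** place both candidates on one random direction
  *orthogonal* to the yeast centroid, at distances 0.5·δ and 1.5·δ
  (δ = `delta_func`, default 1). Along a straight ray the angle subtended
  at the origin grows monotonically, so with zero residue noise the nearer
  candidate strictly wins the cosine ranking under any pooling affine in
  the centroid — mean pooling and SWE both are. This makes the noise-free
  benchmark a geometric guarantee, not a statistical tendency. Shift
  directions are uniform on the (orthogonal) sphere to avoid axis
  artifacts; which candidate slot complements is randomised. Default
  per-residue noise SD 0.5: noticeable scatter, but well-resolved cases at
  the default δ.
* **Orthogroup tables** draw pair identities uniformly in 25–95% and set
  similarity = 0.2 + 0.006·identity + N(0, σ), σ = 0.02 by default — a
  monotone trend with scatter on the cosine scale. One-to-two paralogs'
  identities differ by ≥ 8 points; discordant groups swap the two trend
  components so the embedding metric prefers the non-LDO. Planted outliers
  sit 8 trend-SDs below the line and are planted only outside one-to-two
  groups so the discordance ground truth stays clean. Because the 3-SD rule
  uses the *fitted* residual SD of a single-pass fit, the planted outliers
  inflate their own threshold (~2× at a 5% rate); recall of planted
  outliers is therefore high but not certain — typically 0.85–1.0 across
  seeds at rate 0.05 — which is a property of the prescribed single-pass
  rule itself, not of the detector implementation.

Passing tests on these generators therefore demonstrates correctness of the
pipeline's decision logic and numerics, not that real PLM embeddings carry
functional signal; the latter requires the real inputs (UniProt sequences,
model weights, curated complementation outcomes), for which two integration
tests activate when the downloaded files are placed under `tests/data/`.

## Numerical and degenerate-input conventions

Bit-reproducibility under fixed seeds for every generator and for the
frozen SWE parameters; empty matrices, zero-norm vectors in cosine,
all-zero Wilcoxon differences, one-species orthogroups, < 3 regression
points, and zero identity variance all raise informative errors rather than
returning values. Cosine outputs are clipped to [−1, 1] against rounding.
Problem sizes used by the acceptance script (50–200 synthetic cases, ~300
one-to-two groups, ~1000 pairs, 100 tiny transport instances) were chosen
as the smallest sizes at which the Monte-Carlo checks are stable.

## Known limitations

* The transformer backend is an adapter contract; it is exercised in tests
  only through its cache path and unavailability error, since model weights
  are not bundled.
* The synthetic identity–similarity trend is linear by construction; the
  real relationship is monotone but saturating, so slopes and residual SDs
  from synthetic runs are not comparable to real-data fits.
* Concordance analysis covers one-to-two groups only, mirroring the LDO
  definition; extending to one-to-many requires a ranking-based notion of
  concordance that is out of scope.
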