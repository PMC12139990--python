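# Methods

This note records the model, the numerical and design choices, and what the
synthetic benchmark does and does not demonstrate.

## Interaction scoring

A protein's binding-site predictions each consist of a template ligand
fingerprint and a confidence in [0, 1], consumed as given (no rescaling of
the upstream predictor's scores is attempted). The score of a compound
against a protein selects the prediction with the **highest Dice
similarity** to the compound's fingerprint and multiplies that similarity by
the selected prediction's confidence. When several predictions tie exactly
on Dice, the highest confidence among them is used — a deterministic,
optimistic tie rule chosen because prediction order in an input file should
never affect results. The alternative reading — maximise dice × confidence
jointly — is available as the `max-product` scoring variant; the two differ
whenever a lower-similarity site carries a much higher confidence.

Properties that follow directly: scores lie in [0, 1]; a score is 0 exactly
when the protein has no predictions, the best Dice is 0, or the selected
confidence is 0; raising the confidence of the best-Dice prediction never
lowers the score. Compounds whose structures fail to parse stay in the
library with an all-zero signature (so ranks over the full library remain
comparable) and are excluded from candidate output.

Fingerprints are hashed Morgan fingerprints of radius 2 (ECFP4 semantics).
The hash width defaults to 2048 bits, standard practice for this fingerprint
family; it is a run parameter recorded in output metadata, and synthetic
runs use narrower widths for speed. Ligands and compounds may alternatively
supply precomputed sparse bit sets (`i1;i2;...`), which bypasses chemistry
entirely.

## Similarity ranking

Signatures are compared with cosine distance, computed from row-normalised
vectors as 1 − N·Nᵀ and clamped at 0 (the normalised-product and
dot/(‖x‖‖y‖) formulations agree to ~1 ulp; tests compare them at 1e−12).
Distance to an all-zero signature is defined as 1.0, the maximum, so
unscoreable compounds sink to the bottom of every list instead of producing
undefined values. Ranked lists exclude the query, use 1-based consecutive
ranks, and break exact distance ties by compound id ascending — stability
under input permutation is tested. Full lists are retained (no truncation,
no approximate nearest-neighbour indexing); the library sizes this package
targets, up to tens of thousands, fit comfortably in memory.

## Consensus lists and chance probability

For an indication, every compound appearing within the cutoff of at least
one approved drug's similarity list is tallied: consensus score = number of
such lists, average score = mean of its ranks **over the lists where it
appears** (averaging over all lists would be incompatible with observed
average scores smaller than the number of lists whenever consensus < n).
Ordering is consensus descending, then average ascending, then id. Novel
candidates are the non-approved entries, re-ranked and truncated (default
top 100, tally cutoff default 100).

The chance probability attached to each entry models the n approved-drug
lists as independent uniform draws of a cutoff-sized top list from
library_size − 1 candidates: per-list inclusion probability
p = cutoff/(L−1), and P(X ≥ k) is summed exactly over the binomial tail.
This parameterisation is deliberate and documented rather than inherited:
it is seed-free, exactly computable, strictly decreasing in k, and verified
against exhaustive enumeration and Monte Carlo in the tests. It is *a*
defensible null model, not the only one; published tables produced by other
implementations of this metric family need not print identical
probabilities, and no test asserts that they do.

## Benchmarks

IA treats each approved drug as a leave-one-out query (its list already
excludes itself) and succeeds if any other approved drug ranks within the
cutoff; AIA is the unweighted mean over indications with ≥2 approved drugs.
The random control is the exact hypergeometric chance of catching ≥1 of the
K−1 relevant compounds in a cutoff-sized uniform draw from L−1 candidates.

nIA measures recovery of approved drugs within **one fixed consensus list
per indication**, built from all approved drugs' lists at a single tally
cutoff (default: the largest evaluation cutoff) and then evaluated at each
rank cutoff. Rebuilding the consensus at every evaluation cutoff would make
nIA non-monotone in the cutoff — enlarging the tally pulls new compounds
into the list and can push approved drugs past the very cutoff being tested
— whereas recovery within a single list is monotone by construction. A
stricter variant that rebuilds the consensus without the evaluated drug's
own list sits behind the `strict_loo_nia` flag; note it is not uniformly
harsher, because removing a drug's list also removes tallies that benefit
its competitors.

NDCG uses binary relevance and the log2(rank+1) discount — the standard IR
form; the discount and relevance grading are our choice, as is averaging
per-query NDCG (including zeros) within an indication. nNDCG applies the
same form once to the consensus list with all approved drugs relevant,
ideal = min(n_approved, cutoff). When the ideal gain is empty NDCG is
defined as 0.

A structural note visible in the worked example: approved drugs can appear
in at most n−1 of the n lists (never their own), so background compounds
close to all n drugs can legitimately out-consensus them; nIA at tight
cutoffs is therefore systematically below IA. This is a property of the
metric, not a defect.

## Target corroboration

Per-compound top targets sort proteins by score descending, ties by protein
id. Overlap statistics for a drug set against a gold-standard protein set:

- **Frequency histogram** — unit is the gold protein; each gold protein
  found among the drug set's targets contributes its best (minimum)
  per-drug rank to one of five width-20 bins over ranks 1–100. Gold
  proteins beyond rank 100 are reported as unbinned mass, never silently
  dropped. Collapsing multi-drug ranks by the minimum is our choice.
- **Cumulative overlap** — percent of gold proteins with best rank ≤ c for
  c = 10, 20, …, 100; nondecreasing by construction.
- **Jaccard** — between the pooled rank-≤10 targets of the drug set and the
  gold set (pooling cutoff configurable).

Controls: top-k, seeded uniform random-k, and bottom-k slices of the ranked
candidate table (k = 24 by default), the bottom slice filtered to compounds
with ≥5 heavy atoms so trivially small molecules are not used as controls;
compounds with unknown heavy-atom counts fail that filter. The random seed
is recorded in the run configuration, and all report statistics are
bit-reproducible under a fixed seed.

## Synthetic data

The generator plants recoverable structure: each indication draws a private
seed fingerprint; its approved drugs are independent noisy copies of the
seed, its theme proteins carry binding-site ligands that are noisy copies of
the same seed, and its gold standard is exactly its theme proteins.
Everything else — background compounds, non-theme ligands — is i.i.d. noise.
Defaults are sized for desk-scale validation and run the full pipeline in
seconds: 200 compounds, 100 proteins, 5 indications × 5 drugs, 10 theme
proteins per indication, 2 predictions per protein, width-256 fingerprints,
confidences uniform on [0.5, 1], noise rate 0.05.

Noise is a symmetric per-bit flip with probability r. Two consequences fix
the remaining defaults. At r = 0 co-indicated drugs have identical
signatures (pairwise cosine distance 0, IA = 100% trivially). At r = 0.5 a
flipped copy is uniform over all bit sets regardless of its seed, so the
planted structure is erased *exactly* — provided background fingerprints
follow the same marginal distribution. The background bit density therefore
defaults to 0.5: at half noise, planted and background compounds become
statistically exchangeable and measured AIA collapses onto the analytic
hypergeometric control, giving the generator a clean, provable null. This
density is far higher than real circular fingerprints (typically 1–2%
on-bits); it is chosen for the exactness of the null, not for chemical
realism. An optional `smiles_mode` instead assigns real SMILES from a small
fragment vocabulary (one scaffold per indication) so the RDKit
fingerprinting and heavy-atom paths are exercised end to end.

What passing the synthetic benchmark shows: the scoring rule, distance
ranking, consensus tally, metrics and overlap statistics are implemented
correctly and recover planted signal at the expected noise thresholds. What
it does not show: performance on real chemistry — the generator does not
reproduce fingerprint sparsity, the heavy-tailed similarity structure of
real compound libraries, correlated binding-site templates across related
proteins, or incomplete/biased indication mappings. Absolute metric values
on real data will differ substantially.

## Numerical choices and degenerate inputs

- Scores and distances are float64 throughout; matrices serialise at 6
  decimal places (configurable) and round-trip exactly at that precision.
- Dice of two empty fingerprints is 0; Jaccard of two empty sets is 0;
  cosine distance involving an all-zero vector is 1.
- All orderings (similarity, consensus, targets) break exact ties
  lexicographically by id; no ordering depends on input row order.
- Indications with fewer than two approved drugs are retained by the IO
  layer but skipped (with a log line) by every benchmark.
- The chance-probability tail and the hypergeometric control use exact
  integer combinatorics (`math.comb`), not normal approximations.
- Each pipeline stage writes a `# stage=… # config=<hash>` header; the
  12-hex config hash is the SHA-256 of the canonical JSON of the resolved
  run configuration, so artifacts are traceable to the exact parameters
  that produced them.

## Known limitations

- The binomial-tail chance probability treats approved-drug lists as
  independent; correlated lists (common for structurally similar drugs)
  make it anti-conservative.
- The platform-level random control for consensus recovery reuses the
  similarity-list control form and is an approximation.
- Gold-standard corroboration is binary set overlap; it ignores prediction
  scores and relative ranks beyond the pooling cutoff.
- Bottom-k control selection depends on heavy-atom annotations; libraries
  without structures must supply counts explicitly.
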