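# Methods

This note records the models, parameters, numerical conventions and design
choices behind `remotethread`, and what the synthetic study conditions do
and do not demonstrate about real data.

## The detection model

The pipeline rests on one biological premise: a protein fold persists under
far more sequence divergence than profile searches can track. A
sequence-based hit that is statistically insignificant (E-value between
1e-4 and 50) is therefore treated as a *hypothesis* whose expected fold can
be checked against a structure library, and — when the E-value is above
0.1 — corroborated in orthologs.

Per reported hit the decision table is:

| E-value band | structure mapped | fold accepted | validation level | tier |
|---|---|---|---|---|
| E < 1e-4 | any | not run | not run | `significant` |
| ≥ 1e-4 | no | — | — | `rejected` |
| 1e-4 ≤ E < 0.1 | yes | yes | — | `confirmed_weak` |
| 1e-4 ≤ E < 0.1 | yes | no | — | `rejected` |
| E ≥ 0.1 | yes | yes | ≥ required (default 2) | `remote_validated` |
| E ≥ 0.1 | yes | yes | < required | `remote_unvalidated` |
| E ≥ 0.1 | yes | no | — | `rejected` |

The table is total: every combination of band × mapping × fold × level maps
to exactly one tier (`pipeline.decide_tier`, exhaustively enumerated in the
tests). Proteins without ortholog data are reported `remote_unvalidated`
with an explicit no-data marker rather than dropped. Profiles shorter than
50 match positions set a short-domain flag, since short domains are
empirically the least reliable calls.

## Search engine and E-values

The built-in engine aligns a sequence to per-position log-odds scores
(bits, against a uniform 20-letter background) by glocal dynamic
programming: global in the profile, local in the sequence, linear gap
penalties of 4 bits for skipping a profile position or an aligned sequence
residue. Mask tokens (`X`) score zero everywhere. This is intentionally a
simplified profile scorer, not a full profile-HMM implementation with
insert-state emission priors or posterior decoding; the engine contract
(`search_domains`'s pre/post conditions) is pluggable so a production
search can stand in. It reports one best-scoring region per
(sequence, profile) pair.

E-values follow profile-search convention — database-relative, `E =
n_profiles × exp(−λ(S − μ))` — with (μ, λ) fitted per profile by
maximum-likelihood Gumbel estimation over the maximal alignment scores of
`n_random` i.i.d. uniform-background sequences (default 500 in the
synthetic studies; minimum 200; sequence length twice the profile length,
floor 100). On held-out random sequences the fitted tail is accurate to
well within a factor of two at E ≈ 0.05 per profile. Ties in the hit
ordering break by (accession, envelope start); greedy overlap resolution
keeps hits in ascending E-value order with a configurable shared-residue
tolerance (default 0).

One consequence of database-relative E-values matters for interpretation:
against the synthetic studies' six-profile database, absolute thresholds
like E ≤ 50 or the ortholog ceiling E ≤ 100 are far more permissive per
profile than against a release-scale database of thousands of profiles.
The thresholds are kept at their published values for fidelity; in the
small-database regime the fold-recognition stage, not the reporting
ceiling, is what rejects junk.

## Pre-processing

Low-complexity masking uses a Shannon-entropy two-threshold scheme: a
12-residue window below 2.2 bits triggers a segment, which extends over
adjacent windows below 2.5 bits; the reported interval covers the
contributing windows. Windows containing an existing mask token are
excluded, which makes masking idempotent. Coiled-coil masking scans
28-residue windows under all seven heptad registers against a compact
bundled log-propensity table (core positions a/d favour aliphatic
hydrophobics, e/g favour charged residues, proline is strongly penalized);
windows with best-register mean propensity ≥ 0.5 merge into intervals. The
cutoff is a documented constant chosen so an ideal heptad repeat is
detected and a polyproline stretch is not. Neither component aims for
bit-compatibility with the classical segment-masking or coiled-coil
programs — for this pipeline masking only needs to keep degenerate
sequence out of the threading scores. A hook accepts an externally
computed 3-state secondary-structure string per protein; the surrogate
threader ignores it, a real backend may not.

## Surrogate threading

The bundled backend scores sequence–structure compatibility as a gapped
local BLOSUM62 alignment (open −11, extend −1) of the query against each
structure's reference sequence, normalized by the geometric mean of the
two lengths, then standardizes raw scores across the library into
per-query Z-scores and ranks them (ties by structure id). It is
deterministic and fast (~60 ms for a 60-residue query against 1000
structures), and exists so the statistical layer can be exercised without
external threading software; it makes no attempt to reproduce any real
threading program's energies. A replacement backend implements
`raw_scores(query, library) -> one score per entry in entry order`; ranking,
standardization and everything downstream are shared.

The top window inspected for expected structures is 0.5% of the library
(minimum 1), with the historical absolute window of 60 applying at full
fold-library scale (≥ 12,000 structures).

## The combined statistic

`score_threading` computes, for a ranking of `N` structures with window
`n`, expected-structure set of size `m` and `k` of them inside the window:

* `p_hyper = P(X ≥ k)`, `X ~ Hypergeometric(N, m, n)`, evaluated exactly by
  log-gamma summation (verified against exhaustive enumeration for all
  N ≤ 12 and against an independent library implementation at scale);
* `p_cdf`, the upper-tail probability of the best expected Z-score inside
  the window under an empirical background CDF with an add-one pseudocount,
  `p(z) = (#background ≥ z + 1)/(n_bg + 1)`, so no p-value is ever zero
  (background sample minimum 10,000 values);
* `p_combined`, by default the product of the two — the simplest rule
  consistent with combining "the score is exceptional" with "the family is
  over-represented"; Fisher's method is available as an alternative
  strategy. Acceptance requires `p_combined ≤ 0.001` **and** `k ≥ 1`; with
  `k = 0` both factors default to 1 and the domain is rejected, so an
  expected structure below the window contributes to neither statistic.

No multiplicity correction is applied across the domains of a proteome; the
fixed 0.001 threshold is part of the method.

**Null behaviour and its floor.** Conditional on any expected structure
landing in the top window, both factors are orders of magnitude below the
threshold (the in-window Z is by construction in the background's top
0.5%, and `p_hyper ≤ n·m/N`), so under a uniform-placement null the
acceptance rate is essentially `P(k ≥ 1) ≈ 1 − (1 − n/N)^m`. The statistic
therefore has a structural false-positive floor of about `m·n/N` — ~0.5%
per single-structure family at full library scale — and its discriminative
power against *frequent* folds comes from `p_hyper` penalizing large `m`
relative to `k`, not from rejecting in-window singletons. The null
calibration test simulates the conservative case (m = 1, N = 12,430,
window 60, 10,000 trials, fixed seed) where the floor is 60/12430 ≈ 0.48%.

## Validation

Ortholog validation re-runs the identical search (ceiling E ≤ 100),
pre-processing, threading and scoring on each listed ortholog; "the same
domain" means the same profile accession with ≥ 1 residue of envelope
overlap against the query envelope when a region is supplied (fixture
orthologs preserve coordinates; real deployments may pass no region, in
which case any hit of the accession counts). The level is the number of
species with both re-detection and fold acceptance; it is permutation
invariant and level ≥ 2 is the default requirement, configurable 0–3.
Essential-residue classification maps annotated consensus positions
through the hit alignment: identity, similarity (BLOSUM62 score > 0, which
subsumes identities — the 25% pass threshold applies to
identity-plus-similarity over evaluable positions), or null (including
unaligned positions); a profile without annotation yields "not evaluable",
distinct from failing. Consensus mapping comes from the package's own
profile alignment rather than an external domain-alignment service.

## Synthetic study conditions

`FixtureSpec` defaults define the conditions under which the end-to-end
behaviour is asserted:

* **6 families**, consensus length 55–70, profiles built from 20 members at
  3% divergence with pseudocount 0.1 — sharp profiles, so that the remote
  E-value band (see below) occurs at divergences where fold recognition
  still has signal.
* **Substitution model:** i.i.d. per-site replacement at a given rate, with
  the replacement drawn proportionally to `exp(BLOSUM62/2)` excluding the
  original residue. This encodes the premise that remote members drift
  through biochemically plausible residues, which is what keeps them
  fold-detectable by the alignment-based surrogate.
* **Structure library of 1000:** one reference per family at 10% divergence
  from its consensus plus unrelated random decoys whose lengths are drawn
  from the same range as the family domains, so length normalization is
  exchangeable under the null. One structure per family is the
  conservative minimal-family case; the combined statistic's null rate
  scales with the number of mapped structures.
* **Proteome:** 40 proteins with zero-divergence plants (statistically
  significant by construction), 8 with *engineered* remote members, and
  100 decoys, all with 40-residue random flanks. A remote member is
  engineered by walking a divergence grid (0.70–0.80) and keeping the
  first draw whose in-context E-value, measured with the package's own
  search, lands in [0.3, 20] *and* whose region passes fold recognition —
  the two guarantees the recovery claims rest on. Five of the eight
  receive three-species ortholog trios (3% re-divergence), each verified
  at generation time to re-detect the domain at E ≤ 100 and to re-pass
  fold scoring, with bounded seeded resampling.
* **Background Z-scores:** 100,000 standard-normal draws. The surrogate's
  real per-query Z-scores are heavier-tailed than normal; since window
  membership is rank-based and in-window p_cdf values are tiny either way,
  this choice does not move the accept/reject boundary in practice.
* **Strict/relaxed release pairs:** the old profile sees 20 near members;
  the new one additionally absorbs 10 far members (divergence grid
  0.70–0.90, stepped up until at least 4 members qualify). Ground truth is
  the measured qualifying set (old E > 0.1, new E < 0.1, ≥ 10-fold drop,
  read as a ratio ≥ 10 with a strict-mode flag), measured in protein
  context with the same search the benchmark uses. Candidate regions
  significant in both releases are excluded from classification — they are
  ordinarily conserved domains, neither remote truth nor negatives.

**What passing shows, and what it does not.** Recovery of planted domains
and rejection of decoys demonstrate that the machinery — thresholds,
masking, ranking, the combined statistic, validation plumbing — behaves as
specified under conditions where ground truth is known exactly. The
generator does not emulate real domain architecture (multi-domain
proteins, repeats, compositional bias beyond what masking removes), real
fold-space redundancy (clans sharing structures), insertions/deletions
within domains, or realistic threading energetics; measured
precision/recall on these fixtures is not a forecast of performance on a
real proteome. One measured property worth knowing: decoy regions that
reach threading are *profile-selected* (each is the best-matching window
of its protein), which roughly doubles their chance of placing the
family's structure in the top window relative to the uniform null — the
observed decoy false-call rate sits near 1% against the 0.5% structural
floor. This selection enrichment is intrinsic to the method class, and is
the synthetic counterpart of the substantial false-positive rates the
approach exhibits on real benchmarks.

## Numerical conventions

Coordinates are 0-based half-open internally, 1-based inclusive in all
written reports (stated in file headers). Hit ordering, threading ranks
and overlap resolution all carry stated deterministic tie-breaks. E-values
are floored at 1e-300; empirical p-values are pseudocounted; metric
percentages round half-up to integers (matching the presentation of the
published comparison table, whose printed percentages the metric layer
reproduces from the printed counts — with FPR = FP/(FP+TN) and
FNR = FN/(TP+FN), the only formulas consistent with that table).
Degenerate metric denominators report "undefined" rather than zero. All
generators are pure functions of a seeded spec; identical seeds give
byte-identical artifacts, and pipeline runs are deterministic given their
inputs.

## Known limitations

* The surrogate threader is sequence-based; genuinely structure-only
  relationships (fold conservation with no residual sequence signal) are
  outside what it — and hence the default pipeline — can confirm.
* One hit per (sequence, profile): tandem repeats of the same domain are
  reported once.
* The combined statistic cannot reject a single expected structure that
  lands in the top window (see the null floor above); users who need a
  lower false-positive rate should require validation level ≥ 2, which is
  the default operating point.
* Orthology is consumed, never inferred; validation quality is bounded by
  the supplied ortholog tables.
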