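# remotethread

Detection of **remotely conserved protein domains** — family members so
diverged that profile searches no longer score them as significant — by
combining a deliberately relaxed profile search with a fold-recognition
rescoring step, cross-species validation, and a benchmark framework for
measuring how well such a method performs.

It is written for computational biologists who annotate proteomes: standard
domain searches (profile HMMs against Pfam-style databases) are reliable
above their significance threshold but miss divergent family members in and
below the twilight zone (~20% sequence identity). Because a domain's
three-dimensional fold outlasts its sequence, a weak sequence hit whose
predicted region is also compatible with the family's known structures is
far more trustworthy than the E-value alone suggests.

## The method

1. **Relaxed domain search.** Each protein is searched against a profile
   database up to a permissive E-value ceiling of 50. Hits with E < 1e-4
   are accepted outright; everything weaker continues only if the profile
   has at least one mapped 3-D structure.
2. **Pre-processing.** Low-complexity segments (entropy-based, two-threshold
   trigger/extension) and predicted coiled coils (heptad-register propensity
   scan) are masked to `X`; the hit envelope is cut from the masked protein.
3. **Fold recognition.** The region is threaded against a structure library,
   producing a complete Z-score ranking (a deterministic alignment-based
   surrogate backend is bundled; the backend contract is pluggable).
4. **Combined scoring.** With `N` structures ranked, `n` the top window
   (0.5% of the library, the historical 60 at full fold-library scale), `m`
   structures mapped to the expected domain and `k` of them observed in the
   window, the domain's fold score is

   ```
   p = p_CDF × P(X ≥ k),   X ~ Hypergeometric(N, m, n)
   ```

   where `p_CDF` is the upper-tail probability of the best expected
   structure's Z-score under an empirical background distribution of
   threading Z-scores. The hypergeometric factor separates folds that score
   well merely because they are frequent in the library from folds that are
   genuinely over-represented near the top. A domain is accepted when
   `p ≤ 0.001` and `k ≥ 1`.
5. **Validation.** Hits with E ≥ 0.1 are additionally re-detected in the
   orthologs of up to three related species (at a looser E ≤ 100, with the
   identical fold rescoring); the validation level is the number of
   confirming species, with level ≥ 2 the default operating point. Family
   positions annotated as functionally essential are classified as
   identity / similarity (positive BLOSUM62 score) / null, passing at ≥ 25%
   identity-or-similarity.
6. **Benchmark.** A hide-and-seek truth set exploits profile-database
   growth: a domain scoring E > 0.1 under an old profile release but E < 0.1
   under a newer one with a ≥ 10-fold drop is a known remote member under
   the old profiles. Candidate decisions are reduced to a confusion table
   (clan-mates of the regional truth profile are excluded from the counts)
   and to precision / recall / accuracy / FPR / FNR.

Every input the pipeline needs — profile databases, structure libraries with
reference sequences, proteomes with planted domains at controlled
divergence, ortholog tables, background Z-scores — can be generated
deterministically by `remotethread.fixtures`, so the whole system is
testable offline.

## Worked example

`examples/01_domain_search.py` builds a 60-position family profile,
calibrates it, and searches proteins carrying planted members at increasing
divergence:

```
divergence      E-value     envelope
       0.0     2.01e-21     41-100
       0.3     2.43e-16     41-100
       0.5     2.94e-08     41-100
       0.7     0.000178     41-100
       0.8        0.427     41-91
```

At 80% divergence the member is far beyond significance (E = 0.43) yet still
reportable under the relaxed ceiling. `examples/02_fold_scoring.py` then
threads a 70%-diverged member against a 1000-structure library:

```
remote: expected structures in top-5: k = 1 of m = 1
  best expected Z = 19.95
  p_cdf = 1e-05, p_hyper = 0.005, combined = 5e-08
  accepted at 0.001: True

decoy: expected structures in top-5: k = 0 of m = 1
  accepted at 0.001: False
```

The expected structure tops the ranking (combined p = 5e-8, accepted), while
an unrelated decoy region leaves it outside the window and is rejected.
`examples/03_full_pipeline.py` runs the full decision pipeline on a small
synthetic proteome and `examples/04_benchmark.py` exercises the benchmark
framework, including the metric layer on the published confusion counts of
the four methods compared in the original study (e.g. 217/47/76/845 →
precision 74%, recall 82%, accuracy 90%, FPR 8%).

## Command line

A thin CLI wraps the library:

```sh
remotethread fixtures --seed 0 --out fx/          # generate a synthetic study
remotethread search --fasta fx/proteome.fasta --profiles fx/profiles.tsv
remotethread run --fasta fx/proteome.fasta --profiles fx/profiles.tsv \
    --structlib fx/structures.tsv --structrefs fx/structure_refs.fasta \
    --structmap fx/structure_map.tsv --cdf fx/background_z.txt \
    --orthologs fx/orthologs.tsv --ortholog-seqs fx/ortholog_seqs.fasta \
    --out run/
remotethread bench --seed 0 --out bench/
```

`run/` receives a tab-separated call report (1-based inclusive coordinates,
stated in the header), a JSON twin, the summary counts and the full
configuration, so every run is reproducible from its output directory.

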