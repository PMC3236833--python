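# Methods

## Model and inference

The corpus is the set of per-drug ADR profiles: each drug's label sections
(BW, WP, AR) pooled, normalized and reduced to dictionary-term tokens.  LDA
is fitted by collapsed Gibbs sampling with symmetric Dirichlet priors:
document-topic concentration α and topic-word concentration β are
integrated out and each token's topic indicator is resampled from

    P(z_i = j | z_-i, w) ∝ (n_dj + α) · (n_jw + β) / (n_j + V·β)

with counts excluding the current token.  θ and φ are reported as averages
of the smoothed posterior-mean estimators (n_dj + α)/(len_d + Tα) and
(n_jw + β)/(n_j + Vβ) over post-burn-in sweeps spaced `thinning` apart —
lower-variance than a single final sample, and sufficient because the
downstream analysis only uses θ ranks (argmax) and φ orderings (top
terms).  Initialization assigns each token a uniformly random topic under
the run seed; fixed seed and schedule give bit-identical trajectories.
The collapsed log joint log P(w, z) is recorded every `thinning` sweeps as
a convergence diagnostic only; it is not used for model selection.

Defaults: T = 100 topics, α = 50/T, β = 0.01, 2000 sweeps with 1000
burn-in and thinning 10 — the classical collapsed-Gibbs conventions for
desk-scale corpora.  All are exposed in `LdaConfig` / `GibbsLDA`
parameters.  Empty documents (drugs whose labels matched no dictionary
term) are retained with uniform θ rows so drug indexing stays aligned, and
are flagged with a warning.

Documents are hard-assigned to argmax θ with ties broken to the smallest
topic index — a tie is a measure-zero event for real fits, but fixing the
rule keeps the indicator matrix deterministic and testable.  Topics with at
least 10 assigned drugs (inclusive) are retained for enrichment.

## Enrichment testing

For each retained topic a 2×2 table is built (in-topic vs rest of the
background, with vs without the attribute) and tested with Fisher's exact
test (scipy's implementation; two-sided by the minimum-likelihood rule,
with a one-sided option).  The default BW background is the union of drugs
assigned to the retained topics; drugs with unknown BW status are excluded.
For ATC, the background is the ATC-annotated drugs of the retained topics;
each topic is first assigned its top first-level letter (ties
alphabetical), purity is the fraction of the topic's annotated drugs
carrying it, and a drug with several letters counts toward each.  The
report highlights topics with attribute percentage strictly above 70% and
p < 0.05; no multiple-testing correction is applied by default (a
Benjamini–Hochberg option exists, off by default), matching the
original analysis convention of raw p-values.

### Reproducing the published Boxed-Warning table

The five published BW-dense topics come with printed per-topic counts
(21/15, 20/16, 19/14, 14/13, 11/9) and p-values (0.0121, 0.0014, 0.01,
2.38E-4, 0.0135).  The study also prints two candidate backgrounds: 455
drugs in retained topics with 188 BW, and a 794-drug cohort with 279 BW of
which 635 are ATC-defined.  No combination of {455/188, 794/279} ×
{one-, two-sided} × {topic excluded from, included in, the background
margins} reproduces the printed p-values (relative errors up to 70%, e.g.
the 13-of-14 topic gives 7.0E-5 under a two-sided 455/188 construction
versus the printed 2.38E-4).  A systematic search over table conventions
shows that exactly one convention matches all five values jointly (maximum
relative error 7.1%): a one-sided Fisher test of the topic row against the
whole cohort as the second row, with background margins 635 drugs / 279 BW
— both numbers printed in the original study.  The package documents and
uses this convention for the reference reproduction
(`adrtopics.evaluate.reference_bw_pvalues`); it is a reconstruction of the
original computation, not a claim about which convention is statistically
preferable.  The pipeline's own default for new analyses remains the
two-sided, topic-excluded, retained-topics-background test, which is the
cleaner construction; both are available through
`attribute_enrichment_pvalue`.

The published ATC table cannot be checked the same way: its percentage
column is inconsistent with its printed drug counts (e.g. 19 of 21 printed
as 96%), implying unprinted ATC-annotated denominators, so only structure
(top-category assignment, purity, Fisher testing) is reproduced for ATC.

## Synthetic test bed

The generator emulates the study's inputs with known ground truth:

* **Lexicon** — unique single- and multi-word terms built from syllable
  tokens; every term's leading token is unique, so no term is a
  token-prefix of another and the longest-match scan is unambiguous.
* **Ground truth** — φ rows ~ Dirichlet(0.05) (sparse, near-orthogonal
  topics, as dictionary-filtered safety language is), θ rows ~
  Dirichlet(0.1) (drugs dominated by one safety theme), or one-hot θ
  assigning document d to topic d mod K for exactly balanced planted
  topics.  The original study reports no document-length or
  vocabulary-usage statistics, so these scales are the package's own
  realistic choices, fixed once.
* **Corpus** — lengths Poisson(mean 50) truncated at ≥ 1; topic-then-word
  token sampling, with true token labels retained.
* **Rendering** — tokens written back as term strings with distractor
  words interleaved at a configurable rate and items split round-robin
  across BW/WP/AR; the distractor pool is checked disjoint from the
  lexicon's tokens, making the render → extract round trip exact.
* **Annotations** — BW rate 0.9 on planted topics vs 0.2 baseline; ATC
  coverage 0.8 with purity 0.9 toward the topic's mapped letter.

What the bed does *not* emulate: real SPL section structure, MedDRA's
hierarchy and scale (68k+ terms), misspellings/synonyms, section-spanning
or tabulated text, and correlated topic usage.  Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not performance on real labels.

## Evaluation experiments

* **Posterior exactness** — on a 4-token, 2-topic, 2-word corpus the
  posterior over all 2⁴ topic configurations is enumerated exactly;
  sampled token-topic marginals (20k post-burn-in sweeps) must agree
  within 3 standard errors, with SEs from 40-batch means to absorb chain
  autocorrelation.
* **Recovery** — K = 5 topics, V = 200, D = 300, mean length 50, φ
  concentration 0.05.  Fitted topics are matched to truth by Hungarian
  assignment on total-variation distance.  Fitting uses α = 0.5: the value
  the 50/T convention gives at the production default T = 100, and a
  weakly-informative level appropriate for 50-token documents (α = 10
  would smear short documents across topics; α ≲ 0.1 makes the chain
  prone to trapping in merged-topic modes).  The oracle-label TV floor —
  empirical word distributions computed from the *true* token labels —
  is ≈ 0.04 under these conditions; the fit attains ≈ 0.04–0.05.
* **Planted enrichment** — 10 balanced topics × 30 drugs, 2 planted BW
  topics (0.9 vs 0.2); detection = p < 0.05 and > 70% BW, over 100 seeds.
  Null calibration uses annotations independent of topics.  Note that in a
  *planted* scenario the non-planted topics are genuinely BW-depleted
  relative to the pooled background, so two-sided significance alone is
  not a false positive there; the highlight rule's percentage threshold is
  what keeps them out of the report.

## Numerical choices and limitations

* Fisher two-sided tie handling follows the minimum-likelihood rule with
  1e-7 relative tolerance on table-probability comparisons; degenerate
  tables with an all-zero margin return p = 1.
* Top-term and topic-size orderings break ties deterministically
  (vocabulary order, topic index).
* The sampler is single-chain and single-threaded; label switching is
  handled in evaluation by matching, never inside the sampler.
* Dates must be ISO-8601; records with unparseable dates are rejected
  per-record with a logged warning rather than aborting a run.
* Held-out inference (`GibbsLDA.transform` on new documents) folds
  documents in with φ fixed at its posterior mean, ignoring φ uncertainty;
  adequate for ranking topics of new drugs, not for full posterior
  inference.
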