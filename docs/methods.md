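# Methods

`mirsig` implements a desk pipeline for deriving a disease gene signature
from literature co-citation, a miRNA target set from consensus voting over
prediction tools, and their analytical integration into an overlap
signature with pathway attribution. This note describes the statistical
models, the synthetic study the package ships, and the numerical and
design choices a maintainer should know about.

## Co-citation association model

For a corpus of `N` articles, with `n` disease-relevant articles, `m`
articles mentioning gene *g*, and `k` articles mentioning both, the null
hypothesis is that the `m` gene articles are drawn without replacement
from the corpus independently of the disease labels. The co-mention count
then follows a hypergeometric distribution,

    p(i | n, m, N) = C(n, i) C(N−n, m−i) / C(N, m),

and the association evidence is the upper tail

    p = P(X ≥ k) = 1 − Σ_{i<k} p(i | n, m, N).

Conventions and numerics:

- **Upper-tail, inclusive at the observed count.** `k = 0` gives `p = 1`
  exactly; `k > min(n, m)` gives 0.
- **Log-gamma evaluation.** Binomial coefficients are computed via
  `gammaln` and the tail is summed from `k` upward with log-sum-exp, so
  corpora with millions of articles neither overflow nor lose the small
  tails to cancellation (summing the upper tail directly preserves
  relative accuracy where `1 − CDF` would not).
- **Document frequency, not token counts.** An article either mentions a
  gene or it does not; the hypergeometric model treats articles as the
  sampling units, so repeated mentions within one abstract carry no extra
  weight.
- **Screening.** `screen_genes(table, alpha, correction)` keeps genes with
  p ≤ α, sorted by ascending p with a lexicographic tie-break. No
  multiple-testing correction is applied by default; Benjamini–Hochberg is
  available behind a flag. Because the statistic is discrete and exact,
  the screen is conservative: its attained level is the largest achievable
  tail ≤ α given the realized margins, and at desk-scale margins
  (m ≈ 40, n/N ≈ 0.3) the average attained level at a nominal α = 0.05 is
  ≈ 0.036–0.041. The calibration tests therefore compare the observed
  null rejection fraction against this exact attained-level oracle rather
  than against the nominal α; the screen is required never to be
  anti-conservative.

## Gene mention tagging

Tagging is dictionary-based and deterministic: case-insensitive,
token-boundary-anchored, longest-match-first matching against a lexicon
of canonical symbols and synonyms (a synonym that is a prefix of a longer
matching synonym at the same position never fires). Slash conjunctions
with a shared stem — "Caspase3/7", "MAPK1/3" — are expanded into their
member names before lexicon lookup; hyphen ranges are deliberately not
expanded. Synonym collisions (one name mapping to two canonicals) are
rejected at lexicon load. Statistical named-entity recognition and
species disambiguation are out of scope: dictionary matching is the
testable core of the mention-counting step, and the co-citation model
only consumes per-article mention sets.

An article counts as disease-relevant when it carries an explicit flag or
matches a configured disease term; synthetic corpora provide both, real
corpora are expected to supply terms.

## Consensus target voting

Each prediction tool contributes a plain gene list; votes are boolean and
unweighted, and a gene enters the consensus set when at least `min_votes`
tools nominate it (inclusive threshold, default 4 — consistent with
requiring a gene to be nominated by at least four of eleven tools).
Output order is vote count descending, then symbol. The consensus size is
monotone non-increasing in the threshold; the maximum threshold yields the
intersection of all lists.

## Over-representation analysis

A query set is tested against named gene sets (three GO namespaces, or
pathways) with the same hypergeometric upper tail, drawing the query from
the annotation universe. This equals the one-sided Fisher exact test on
the 2×2 contingency table, which the tests verify to 1e-12. Choices:

- the universe is the set of all genes annotated in the loaded database;
  query genes outside it are dropped with a logged count;
- only over-representation is tested; categories with zero overlap are
  reported with p = 1;
- no GO-graph ancestor propagation — category sets are flat;
- raw p-values by default, BH behind a flag.

## Interaction network and hubs

Typed edges carry one of five relation classes — ECrel (enzyme–enzyme
succession), PPrel (protein–protein binding/modification), GErel
(transcription factor → target expression), PPI (experimental
protein–protein interaction), literature (significant gene–gene
co-citation) — and a provenance label (database / experiment /
literature). Literature edges apply the co-citation tail gene-vs-gene over
the mined per-article mention sets and keep pairs with k ≥ 1 and p ≤ α.

For connectivity the graph is undirected and simple: degree counts
distinct interaction partners, so multiple relation classes between the
same pair contribute one neighbor (the typed records are all retained for
export). GErel is conceptually directed but interaction partners are
counted symmetrically. The hub statistic is the degree standard score
z = (d − mean d)/sd d over all nodes (population sd) with a one-sided
upper normal tail; a degree-regular graph has sd 0 and is reported as
z = 0, p = 0.5 with a warning. This is a descriptive ranking statistic:
the normal reference is an approximation, degree distributions are not
normal in general, and hub p-values should be read as ordering scores,
not calibrated error rates.

## Overlap integration

The overlap signature is the exact set intersection of the screened
disease genes and the consensus targets, reported with each gene's
disease p-value and vote count. Attribution is pure set membership and
many-to-many: every overlap gene is listed under every significant
pathway containing it, genes in none are "unattributed", and the induced
subgraph of the interaction network on the overlap is exported alongside.

## Synthetic study design

The generator plants known structure so every stage has ground truth:

- **Corpus** (default 2000 articles): each article is disease-flagged
  independently with probability 0.3; gene g is mentioned with
  probability 0.02 in background articles and min(1, 0.02 × lift(g)) in
  disease articles, lift 5 on 20 planted genes of a 120-gene universe.
  A planted gene then appears in ≈ 88 articles with ≈ 60 disease
  co-mentions versus ≈ 26 expected under independence — a strong but
  finite signal, sized so that screening at α = 0.01 recovers the planted
  set with sensitivity ≥ 0.9 at empirical FDR ≤ 0.1.
- **Text** is a token stream: mention spellings alternate between the
  canonical symbol and a synonym alias, adjacent shared-stem mentions are
  merged into slash conjunctions at rate 0.25, and disease articles embed
  the disease term. Tagging the generated text reproduces the planted
  mention sets exactly (verified per article in the tests); there is no
  attempt at natural-language realism beyond lexicon-matchable tokens.
- **Predictions**: 11 tools, per-tool sensitivity 0.8 on 30 planted
  targets and false-positive rate 0.05 elsewhere, all independent, so
  planted-target recovery at the vote-4 threshold follows the binomial
  tail P(Bin(11, 0.8) ≥ 4) ≈ 0.99976.
- **Annotations**: planted pathway memberships padded with non-target
  decoys to the configured sizes. One planted pathway is target-enriched
  by design (six of eight members are planted targets, giving an
  enrichment tail ≈ 0.003–0.009 against the 120-gene universe); the
  others sit at background level, so the significance cut separates them.
- **Edges**: planted typed edges plus Erdős–Rényi background at density
  0.01, no self-loops, unordered pairs unique within a relation class.

One global seed spawns four independent sub-streams (corpus, predictions,
annotations, edges) via `numpy.random.SeedSequence`, so the generators are
individually and jointly byte-reproducible and changing one stage's
parameters does not perturb the others' draws.

What the synthetic study does *not* emulate: real abstract language and
tagging ambiguity, correlated tool errors (prediction tools share seed-
match logic and are not independent in reality), literature citation bias
(genes are mentioned because they are studied, not only because they are
associated), and realistic scale-free interaction topology. Passing tests
demonstrate correctness of the statistics and plumbing under the stated
model, not performance on real corpora.

## Problem sizes in the shipped checks

The repeated-simulation suites use 2000-article corpora over a 120-gene
universe with 20–50 replicate seeds, and consensus recovery uses 60
planted targets over 40 seeds (2400 Bernoulli trials); these sizes put
Monte-Carlo error well below the tested effect sizes while keeping the
whole suite fast. Exhaustive enumeration oracles cover every co-citation
configuration with N ≤ 25 and every enrichment table with universe ≤ 20.

## Known limitations

- The hub z-test's normal null is heuristic (see above).
- The conjunction expander handles shared-stem slash lists only.
- The literature-edge pass is O(pairs per article) and intended for
  gene universes of a few thousand, not genome-wide mention sets.
- Discreteness makes every exact tail test conservative at small margins;
  users comparing rejection rates against nominal α should use the
  attained-level oracle pattern from the calibration tests.
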