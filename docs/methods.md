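# Methods

This note documents the models and procedures implemented in `hospmine`,
the defaults and why they were chosen, what the synthetic corpus does and
does not emulate, and the package's known limitations.

## Problem setting

Online health communities organize content in three levels: *threads* (a
titled discussion), *messages* (individual posts, usually a handful per
thread), and *sentences*. Messages about hospitals are informal: hospital
names appear as acronyms, abbreviations and misspellings; spacing and
casing are erratic; praise and complaint often coexist in one post. The
pipeline extracts, per message, (a) which hospital is discussed, (b) which
service-quality aspects are mentioned, and (c) whether the post recommends
the hospital.

## Text normalization

All dictionary matching operates on normalized text: Unicode casefold,
whitespace runs collapsed to single spaces, leading/trailing whitespace
removed. An offset map projects normalized spans back to raw-text spans
(`offsets[i]` = raw index of the character that produced normalized
character `i`). Normalization is idempotent and is applied identically to
lexicon entries at load time and to message text at query time, so matching
is insensitive to case and spacing noise — the dominant error source in
community text.

Sentence splitting uses the delimiter set `{., !, ?, newline}` with the
delimiter(s) attached to the preceding sentence and no abbreviation
handling; community messages are short and rarely contain formal prose, so
a rule-based splitter is adequate and fully auditable. Tokens are maximal
runs of Unicode letters/digits with 0-based half-open offsets.

Morphological analysis is deliberately out of core: `normalize_text` is a
hook with the signature `text -> (normalized, offset_map)`, so a
language-specific analyzer (e.g. for Korean spacing correction or particle
stripping) can be plugged in without changing any downstream module. The
default normalize-and-substring-match strategy is the fallback it wraps.

## Hospital name normalization

The hospital dictionary maps a canonical id to a canonical name, a region,
and a set of alias surface forms. A candidate span is resolved stepwise:

1. **exact** — equality with a canonical name (distance 0);
2. **alias** — equality with any alias (distance 0);
3. **fuzzy** — minimum Levenshtein distance *d* over all aliases, accepted
   iff `d ≤ max(1, ⌊ρ·|alias|⌋)` with relative tolerance `ρ = 0.25`
   (config-exposed). Every alias tolerates at least one edit; a 12-character
   alias tolerates three.

The first successful step wins and is recorded with the mention. Fuzzy ties
are broken by smallest distance, then same-region preference when the
message's region is known, then longest alias, then lexicographically
smallest canonical id. If, after the region preference, two or more
distinct hospitals remain tied at the minimal distance, the candidate is
flagged **ambiguous**; the message filter retains only messages with at
least one mention and no ambiguous candidate, since a human reader could
not tell which hospital such a message means either.

Candidate spans are token n-grams up to 5 tokens (hospital names are
multiword; scanning all substrings would add quadratic cost without
benefit). Overlaps are resolved by a two-class rule: distance-0 matches
(exact/alias) outrank fuzzy matches, and within each class the longest
span wins, then the leftmost, then the cheapest. The class rule prevents a
loose fuzzy budget on a long alias from absorbing a verbatim alias plus a
neighboring junk token; conversely a typo-corrupted long name still beats
its shorter sub-matches when nothing in it matches exactly.

Edit distance is unit-cost Levenshtein, computed with `edlib` (verified in
the test suite against an independent brute-force recursion on all short
string pairs, and for metric axioms by property tests).

## Quality-factor detection

The six-factor taxonomy — service, professionalism, process, environment
(functional, subcategory codes `f1–f29`) and impression, popularity
(emotional, `e1–e10`) — is realized as a keyword lexicon; each keyword
carries its factor, subcategory, and optional equivalent surface forms that
resolve to the same entry. Detection is per sentence: longest-match-first,
non-overlapping, token-boundary-aligned substring matching on normalized
text ("waiting time" beats "waiting"; "waitingroom" fires nothing). No
stemming or compound-noun decomposition is attempted; unsplit compounds and
homonyms are the known, accepted failure modes of a keyword mechanism.

The f/e-code pairing rule (functional codes only on the four functional
factors, emotional codes only on impression/popularity) is validated at
load time, as is the uniqueness of `(keyword, factor, subcategory)` and
the disjointness of positive and negative sentiment cues. Cross-lexicon
surface collisions (a hospital alias equal to a factor keyword or cue) are
reported as warnings, not errors.

The bundled lexicons (`hospmine/data/*.tsv`) are small English stand-ins —
tens of keywords per factor, 22 hospitals across six regions — sized for
tests and demonstrations. Production taxonomies of this kind run to
roughly a thousand keywords per factor; the lexicon files are
configuration, not code, and scale without changes.

## Recommendation classification (mood flow)

Sentence polarity is `sign(positive cue count − negative cue count)` over
token-boundary cue matches; a cue within `k = 2` tokens after a negation
marker flips sign (the default marker set is empty — the bundled cue list
encodes negated cues like "not recommend" directly). A tied sentence is
neutral: symmetric, and avoids a systematic positive bias.

The *mood flow* of a message is its ordered sentence-polarity sequence,
e.g. `0+-`. The four-class label is presence-based: some positive and no
negative sentence → **positive**; the reverse → **negative**; both →
**bilateral** (a within-message polarity transition); neither →
**neutral**. An alternative `mode="last"` lets the final polarized sentence
decide, for corpora where writers close with their verdict; the
presence-based rule is the default because it is order-invariant and
directly testable. The binary reduction maps bilateral to negative — when
praise and complaint coexist, misreading a complaint as a recommendation is
the costlier error — and excludes neutral messages.

Factor instances inherit polarity sentence-first: a mention in a polarized
sentence takes that sentence's sign; a mention in a neutral sentence falls
back to the message's four-class label. This keeps a bilateral message's
positive aspects positive and negative aspects negative.

## Evaluation

Precision, recall and `F1 = 2PR/(P+R)` are reported as percentages per
region plus a macro-average row (arithmetic mean over regions, each region
weighted equally). Presentation rounding is round-half-up to integer
percent; edge conventions: empty-vs-empty scores 100, empty predictions
against nonempty gold score 0, and F1 is 0 when P+R = 0.

Match keys: hospital-name evaluation uses `(message_id, canonical_id)`
pairs — message-level, the weakest assumption about annotation granularity;
factor detection uses `(message_id, factor)`; recommendation uses the
binary label per message and reports precision only.

## Analytics

All aggregations run over a flat instance table (one row per polarized
factor instance with region/year/month metadata). Factor-share
distributions satisfy `share(factor | group) = 100·count(factor, group) /
count(group)` and sum to 100 within every group. The default denominator is
*classified* instances (neutral-message instances excluded); an
`include_neutral` switch uses all instances — both conventions are
plausible for summary shares, so the choice is explicit. Percentages are
kept at two decimals internally; coarser rounding is presentation-layer
only.

A thread is **negatively opinionated** iff at least one member message is
binary-negative and none is binary-positive (package definition; thread
roll-up is not standardized anywhere). Term–hospital co-occurrence is then
`100 · |negative threads containing term and hospital| / |negative threads
containing term|`, with the denominator recorded in the table metadata.
The recommendation share is `100 · positive instances / all four-class
instances` (neutral included in the denominator, since every instance
carries a four-class label).

## Synthetic corpus generator

The generator emulates the *structural and statistical* properties the
pipeline consumes, with ground truth known by construction:

- threads of `1 + Poisson(mean − 1)` messages (default mean **5.59**
  messages/thread), one of six regions, one posting month drawn from an
  April 2007 – May 2013 window;
- messages of 1–5 sentences of filler-vocabulary words with random casing
  noise (offsets unaffected);
- a hospital mention in a message with probability **0.8** (no published
  figure exists for this rate; the default keeps most messages retained so
  downstream stages see realistic volume), written as a uniformly drawn
  alias, corrupted at `typo_rate` with up to `max_edit_ops` character edits
  capped at the fuzzy threshold, and re-verified to still resolve uniquely
  to its hospital (unresolvable corruptions fall back to the clean alias,
  logged);
- factor keywords in **18.45%** of messages (1–3 mentions, equivalents with
  probability 0.25), with optional per-keyword weights for planting chosen
  share shapes;
- a four-class mixture of **36%** positive and **8%**
  negative-or-bilateral, split 5% negative / 3% bilateral (the split is not
  separately published; explicit transitions are rarer than plain
  complaints), remainder neutral. Sentiment cues are planted to realize the
  planned per-sentence polarities; bilateral messages get at least one
  positive and one negative sentence.

By default, factor keywords are planted in sentences whose *inherited*
polarity equals the message's four-class label (for bilateral messages:
neutral sentences, which exist by construction), so the instance-level
polarity mixture equals the message-level mixture and share-recovery tests
are unbiased. A `plant_in_polarized` flag instead places keywords uniformly
and computes the gold instance polarity by the inheritance rule, which
exercises sentence-first inheritance directly.

The filler vocabulary is deliberately long-worded and unrelated to the
bundled lexicons; the test suite verifies that no filler 1- or 2-gram
falls within the fuzzy threshold of any hospital alias. That guarantee is
what makes the noise-free closure properties exact: precision can only drop
via planted distractors, never via background text.

One seeded `numpy` generator drives the whole corpus; the same seed
reproduces it byte for byte. What the generator does **not** emulate:
linguistic realism (syntax, discourse, Korean orthography), portal HTML
layouts, coreference ("that hospital"), sarcasm, or topic drift. Passing
tests on synthetic data therefore demonstrate the correctness of the
mechanics — matching, normalization, classification rules, aggregation
arithmetic — not real-world extraction accuracy, which depends on lexicon
coverage and language-specific preprocessing.

## Numerical and procedural choices

- Offsets are 0-based half-open everywhere; mention spans live in
  normalized text with projection to raw text available.
- Fuzzy scanning prunes alias comparisons whose length difference already
  exceeds the distance budget.
- Thread titles are not matched by default; `include_titles` prepends the
  title to the thread's first message for detection.
- The pipeline is a pure function of (corpus, lexicons, config): re-running
  with the same inputs is bit-identical, and the manifest records a config
  digest plus per-stage counts (messages in, retained, factor mentions,
  instances, per-class label counts).
- Evaluation problem sizes in the acceptance script (~2000 messages for
  closure, ~5000 for share recovery, 800 threads for co-occurrence) were
  chosen so that 3-standard-error bands on the recovered shares are a few
  percentage points wide at most.

## Limitations

- Keyword detection cannot split compounds or disambiguate homonyms; recall
  on real agglutinative-language text requires a plugged-in morphological
  normalizer and a richer equivalent-term list.
- The ambiguity rule is tie-based only; context-based disambiguation and
  coreference are out of scope.
- The bundled lexicons are illustrative stand-ins, not a usable production
  taxonomy.
- Thread-level negativity and the distribution denominators are package
  definitions (documented above); alternative conventions change the
  absolute percentages but not the machinery.
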