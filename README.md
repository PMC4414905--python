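# hospmine

Text mining of **hospital service quality** from online health-community
posts.

Parents and caregivers discuss pediatric hospitals in forum threads: which
clinic they recommend, how long the wait was, whether the doctor was kind.
`hospmine` turns such threads into structured, analyzable signals. It is
aimed at health-informatics researchers and analysts who want to measure
hospital reputation from user-generated text rather than from surveys.

## What it computes

The pipeline runs five text-mining stages over a corpus of
threads → messages → sentences:

1. **Preprocessing** — HTML stripping, Unicode casefolding, whitespace
   normalization (with an offset map back to the raw text), sentence
   splitting, tokenization. A pluggable normalizer hook lets you insert a
   morphological analyzer for agglutinative languages.
2. **Hospital NER** — dictionary-based extraction of hospital mentions with
   a stepwise normalization of surface forms to canonical names:
   *exact* canonical match → *alias* match (acronyms, abbreviations) →
   *fuzzy* match by Levenshtein distance *d*, accepted when
   `d ≤ max(1, ⌊0.25·|alias|⌋)`.
3. **Filtering** — messages with no hospital mention, or whose best fuzzy
   candidate ties between distinct hospitals (ambiguous), are dropped.
4. **Quality-factor detection** — keyword matching against a six-factor
   taxonomy of hospital service quality: **service**, **professionalism**,
   **process**, **environment** (functional subcategories `f1–f29`) and
   **impression**, **popularity** (emotional subcategories `e1–e10`).
5. **Recommendation classification** — lexicon-based sentiment with *mood
   flow*: each sentence gets polarity `sign(#pos − #neg)` over cue phrases;
   the ordered polarity sequence yields a four-class message label
   (*positive*, *neutral*, *bilateral*, *negative*), reduced to binary with
   bilateral → negative. Every detected factor instance inherits a polarity
   (its sentence's, falling back to the message's).

On top of that: precision/recall/F1 evaluation against gold labels
(per region, macro-averaged, `F1 = 2PR/(P+R)`), and analytics — factor
share distributions by region/month/year, negative-attitude trends,
within-factor item shares, and term–hospital co-occurrence in negatively
opinionated threads.

Because no corpus of this kind is publicly available, the package includes
a **synthetic gold-corpus generator** that emulates the structural
statistics of such communities (≈5.6 messages per thread, ≈18.5% of
messages containing factor keywords, ≈36% positive and ≈8%
negative-or-bilateral messages) with known ground truth, so every stage is
testable end to end.

## Worked example

```python
import datetime
from hospmine.corpus import Message
from hospmine.synthetic import default_lexicons
from hospmine.hospital_ner import extract_hospital_mentions
from hospmine.factor_detect import detect_factor_mentions
from hospmine.recommend import mood_flow_classify, assign_factor_polarity

hospitals, factors, sentiment = default_lexicons()
msg = Message("m1", "t1", "Seoul", datetime.date(2009, 11, 2),
    "We went to sunrize kids yesterday. Kind nurse, we are satisfied. "
    "But the waiting time was terrible experience.")

for m in extract_hospital_mentions(msg, hospitals):
    print("hospital:", repr(m.surface), "->", m.canonical_id, m.match_step, "distance", m.distance)
mentions = detect_factor_mentions(msg, factors)
label = mood_flow_classify(msg, sentiment)
print("label:", label.four_class, "| binary:", label.binary, "| flow:", label.flow)
for inst in assign_factor_polarity(mentions, label):
    print("instance:", inst.mention.matched_keyword, "->", inst.polarity)
```

prints

```
hospital: 'sunrize kids' -> SEO1 fuzzy distance 1
label: bilateral | binary: negative | flow: 0+-
instance: kind nurse -> positive
instance: waiting time -> negative
```

The misspelled alias `sunrize kids` is normalized to hospital `SEO1` at the
fuzzy step (one edit). The mood flow `0+-` — a neutral sentence, then a
positive one, then a negative one — makes the message *bilateral*
(conflicting), which the binary reduction treats as a non-recommendation;
the `kind nurse` (service/f1) instance keeps its positive sentence's
polarity while `waiting time` (process/f15) is negative.

At corpus scale, the same machinery runs end to end:

```python
from hospmine.synthetic import GeneratorConfig, generate_corpus
from hospmine.pipeline import run_stages
from hospmine import analytics

threads, messages, gold = generate_corpus(
    GeneratorConfig(seed=42, n_threads_per_region=30, typo_rate=0.3),
    hospitals, factors, sentiment)
result = run_stages(threads, messages, hospitals, factors, sentiment)
print(result.manifest["labels"])
print(analytics.recommendation_share(result.instance_table))
```

```
{'positive': 265, 'neutral': 441, 'bilateral': 23, 'negative': 35}
38.89
```

## Command line

All stages are also exposed as subcommands of one executable:

```bash
hospmine gen-corpus --seed 1 --out corpus.jsonl --gold gold.tsv
hospmine lexicon validate --hospitals h.tsv --factors f.tsv --sentiment s.tsv
hospmine corpus stats corpus.jsonl          # per-region thread/message table
hospmine extract corpus.jsonl               # hospital mentions TSV
hospmine detect-factors corpus.jsonl
hospmine classify corpus.jsonl
hospmine evaluate --predictions p.tsv --gold g.tsv --task hospital_name
hospmine run --config pipeline.yaml         # all stages + manifest
hospmine trends out/instances.csv --by region,year
hospmine cooccur --config pipeline.yaml --term emergency
```

Lexicons are UTF-8 TSV with a header row; multi-valued cells are
pipe-delimited:

| file | columns |
|---|---|
| `hospitals.tsv` | `canonical_id`, `canonical_name`, `region`, `aliases` |
| `factors.tsv` | `keyword`, `factor`, `subcategory`, `equivalents` |
| `sentiment.tsv` | `cue`, `polarity` (positive / negative / negation) |

The corpus format is JSON Lines with `kind: thread` and `kind: message`
records. Small stand-in lexicons ship with the package
(`hospmine/data/*.tsv`); real deployments supply their own.

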