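# Methods

This note documents the models, conventions and design choices behind
`phenoprio`, in the order the pipeline applies them.

## The task

Each evaluation case pairs a phenotype profile $P = (P_1,\dots,P_m)$
with an ordered candidate gene list $G = (G_1,\dots,G_n)$ containing
exactly one causative gene. A ranker receives a natural-language prompt
carrying both and returns free text from which an ordered gene list is
recovered. The sole quantity evaluated is the 1-based rank $r$ of the
causative gene among the *input* genes in that list.

## Case construction

Decoys are drawn uniformly without replacement from a configurable gene
pool (the knowledge-base genes, or any explicit universe) excluding the
causative gene. Two conventions matter:

* **Causative position is randomized.** The combined list is uniformly
  shuffled per case, so no ranker can exploit list position. A
  chi-square test over ≥1,000 generated cases verifies uniformity.
* **Decoy draws are nested across sizes.** Each record receives one
  random permutation of its decoy universe; the case of size $n$ uses
  the first $n-1$ entries. Size comparisons are therefore *paired*: the
  $n=5$ candidate set is a subset of the $n=100$ set for the same
  record. For any deterministic ranker this makes performance
  degradation with list size a structural fact — removing candidates
  can only improve the causative gene's rank — rather than a property
  that holds only in expectation. The marginal distribution of each
  decoy set is unchanged (a prefix of a uniform permutation is a
  uniform draw without replacement). Independent re-sampling per size
  was considered and rejected: with realistic cohort sizes the
  adjacent-size performance differences (2–4 percentage points) are
  smaller than binomial sampling jitter, so the expected monotone
  degradation would be visible only on average, not in each run.

Per-case seeds derive from SHA-256 of (master seed, record id, size),
so extending a run never perturbs existing cases.

The calendar-window filter on `date_added` is closed on both ends;
records without a date are dropped with a warning, since they cannot be
shown to postdate a training cutoff.

## Prompt templates

Seven templates are stored as versioned text files with literal
placeholders (`[phenotypes]`, `[genes]`, `[male/female]`,
`[mode of inheritance/genetic]`). Rendering is pure string
substitution; phenotype labels and gene symbols are joined with `", "`
(the join rule is a package convention; prompts display comma-separated
lists). Conventions:

* Templates requiring sex fail loudly when the case lacks it; defaults
  are never invented. A missing mode of inheritance substitutes the
  literal token `genetic`.
* No grammatical correction is applied around substitutions ("a
  autosomal recessive disease"); byte fidelity to the stored template
  outweighs grammar, and the golden-file tests pin the exact bytes.
* The one-shot template (Q4) carries a system-role preamble fixing the
  output format (`"Ranked List:" 1. Gene1 2. Gene2 ...`) and
  instructing that genes without evidence be placed on the last rank.
  The in-context example inside the preamble is kept generic — its
  placeholders are *not* substituted — so each candidate gene appears
  exactly once in the user text and the example never leaks case
  content.
* The wording variants (`Q2_sign`, `Q2_pheno`) replace every occurrence
  of the token "symptoms" in the base template; `Q2_fullnames` renders
  full gene names from a caller-supplied mapping that must cover every
  candidate.
* The fallback protocol issues a primary template and, only when the
  parsed response contains no recoverable ranked list, one secondary
  template. A partial list (some genes missing) counts as a valid
  parse, not a failure; the missing genes are hallucination data.

## Ontology handling

OBO files are parsed with `obonet`; only `is_a` edges are used.
Construction validates resolvable parents, acyclicity, and uniqueness
of the normalized label/synonym index (lowercase, trim, collapse
internal whitespace). Lookup of free text against that index is exact —
no stemming, no fuzzy matching — because a dictionary that guesses
would silently change which profile terms are perturbable. Obsolete
terms are loaded (identifiers stay resolvable) but excluded from the
lookup index and all candidate pools.

## Noise scenarios

Four perturbations are applied to a profile of size $m$ at proportion
$p$, altering $k = \lfloor p \cdot m \rfloor$ terms selected uniformly
without replacement (each term altered at most once). The floor is
computed as `floor(p*m + 1e-9)`; the epsilon guards against binary
representation error in products like $0.1 \times 10$ and cannot
promote a genuinely fractional value. Profiles with $m \le 1$ are
passed through unaltered and flagged.

* *remove* deletes $k$ terms; *add* appends $k$ non-root, non-obsolete
  ontology terms not already present (the pool is the whole ontology by
  default; a subtree restriction can be imposed by the caller through
  the graph).
* *generalize*/*specialize* replace a term by a uniformly chosen direct
  parent/child. A replacement that would duplicate an existing profile
  term triggers a re-draw among remaining candidates; if every
  candidate collides the term is kept (logged), so `altered_count`
  reports actual alterations. Generalization prefers non-root parents
  and falls back to the root only when no other parent exists — a root
  term carries no information, but it is still a direct parent when it
  is the only one.
* Profile entries that fail dictionary mapping (free-text labels) are
  eligible for removal, never for replacement (their neighbors are
  unknown), and are reported in `unmapped_labels`.

When fewer eligible terms exist than $k$, as many as possible are
altered with a warning — noise application is best-effort, not an
error.

## Offline rankers

The **simulator** emits the `Ranked List:` numbered format. Its quality
knob $q$ is the probability of placing the causative gene first;
otherwise the gene falls uniformly on a later rank (the assumption-free
choice absent any model of partial knowledge). Hallucinations are
generated independently: per-gene omission with probability `p_drop`,
one out-of-list symbol per prompt with `p_extra`, one duplicated line
with `p_dup`. `force_last` pins the causative gene to the final rank —
the adversarial floor. Per-call RNGs derive from (seed, case id,
template id), making the backend stateless and replayable.

The **knowledge-base ranker** scores each candidate gene by the Jaccard
similarity between the `is_a` ancestor closures of the case phenotypes
and of the gene's knowledge-base phenotypes, with ties broken
lexicographically. It is a minimal, fully deterministic representative
of the classical ontology-similarity family, built for sweep
experiments — it is not a re-implementation of any published tool.
Chat-completion API adapters fit behind the same one-method contract
but are deliberately out of the tested surface; nothing in the package
performs network calls.

## Parsing

The parser looks for numbered items (line-based or inline), grouping
them into runs that restart at item number 1; explanation sentences
between items do not break a run. When several runs exist, the one
nearest after a "Ranked List" marker wins, else the longest. Bulleted
lists and a comma list after the marker are fallbacks. Tokens are
normalized (parentheticals dropped, explanation cut at the first colon
or spaced dash, markdown and surrounding punctuation stripped, first
whitespace token kept, uppercased) and optionally alias-mapped;
duplicates keep the first occurrence. Matching against the input genes
is case-insensitive exact — fuzzy matching would award credit for
symbols the model never produced. A response with no recoverable list
is `failed`; all pathologies are data, not exceptions.

## Metrics

With a single positive among $n$ candidates: $\text{AUC} =
(n-r)/(n-1)$ (fraction of negatives ranked below the positive) and
$\text{AP} = 1/r$ (the single step of the precision–recall curve).
Both closed forms are verified against brute-force oracles — explicit
pair counting with ties halved, and explicit PR-step integration — to
$10^{-12}$, and independently against scikit-learn.

Conventions:

* An omitted causative gene (or a failed/refused parse) scores the
  pessimistic last rank $r = n$, the same convention the one-shot
  prompt instructs; such a case never counts as a hit at any depth.
* Extra (non-input) symbols are excluded before computing $r$: they are
  not candidates.
* Aggregation is **macro**: AUC and AP are averaged per case within
  each (dataset, template, size) cell, so every case weighs equally
  regardless of $n$.
* Hits@$k$ with $k > n$ caps at $k = n$.
* $n = 1$ leaves AUC undefined ($0/0$); the implementation returns 1.0
  with a logged note.
* Hallucination rates are fractions of *all* prompts (failed ones
  included) whose parse has non-empty `missing` or `extra`, pooled
  across sizes.
* Repetition summaries use the sample standard deviation ($n-1$); a
  single repetition reports no SD.
* The cohort overlap percentage uses the union denominator
  $|A| + |B| - |A \cap B|$; the sum denominator is also exposed since
  aggregate counts alone cannot always reconstruct a published
  percentage.

## Repetition semantics

Repetitions re-issue the *same* queries: cases are held fixed and only
the backend seed varies per repetition. The resulting spread measures
response stability, so a deterministic backend has SD = 0 by
construction, and a stochastic one exposes its variance.

## Synthetic data: what it emulates, and what it does not

The generator produces a single-rooted random DAG (term $i$ draws 1 to
`max_parents` parents among earlier terms, guaranteeing acyclicity and
root reachability), a knowledge base of 200 synthetic genes with 8
distinct non-root phenotype terms each, and patient cohorts whose
observed profile is the causative gene's KB profile under observation
noise: 30% per-term dropout, generalization of 20% of surviving terms
to a direct parent, and Poisson(0.3·m) spurious additions. These rates
encode that clinical phenotyping records only part of a curated profile,
at coarser granularity, plus incidental findings; they were fixed as the
package's study conditions and give the deterministic ranker headroom to
degrade measurably under list-size growth and injected noise. Patient
sex, mode of inheritance (from a fixed four-token vocabulary whose
fallback member is `genetic`), and submission dates spanning a
three-month window are drawn uniformly.

What passing tests on this synthetic world do **not** show: anything
about real gene–phenotype biology (symbols are synthetic, term
co-occurrence is uniform rather than correlated), about real LLM
behavior (the simulator's hallucinations are independent coin flips,
real ones are not), or about free-text phenotype variability (labels
are generated, so dictionary mapping always succeeds unless noise is
injected deliberately). The harness validates the *measurement
machinery* — construction, perturbation, parsing, scoring — not any
particular ranker's clinical merit.

## Problem sizes

Default experiment cells use 100 patients over a 200-gene knowledge
base and a 300-term ontology, with 500 cases per sweep and 1,000
prompts per hallucination-recovery estimate; perturbation exactness is
checked on 1,000 random profiles per scenario/proportion. These sizes
give 3-standard-error Monte-Carlo bounds a few percentage points wide
while keeping any single experiment in the seconds range.

## Known limitations

* The ancestor-closure Jaccard ranker ignores term specificity
  (information content); it is a baseline, not a competitive method.
* The parser extracts only the final list structure it finds; a
  response that revises its own ranking mid-text is read at the last
  "Ranked List" marker.
* Perturbation applies one scenario at a time; mixed-noise profiles are
  out of scope.
* The evaluation assumes exactly one causative gene per case;
  oligogenic cases are not modeled.
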