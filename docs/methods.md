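# Methods

This note documents the design of `forumscrape`: the crawling and
extraction procedure, the graph and anonymization models, the synthetic
sites used for validation, and the numerical/engineering choices made where
the design was genuinely open.

## Crawl model and politeness

The crawler simulates a reader's navigation over the canonical forum
layout: a site hosts boards, a board lists threads across one or more
pages, a thread lists posts across one or more pages, and "next page" is a
single configured link. The traversal order is: all thread-list pages of a
board, then every thread of that board to completion, then the next board.

Three mechanisms keep the crawl polite and duplicate-free:

* **Delay floor.** A network request may start no earlier than
  `min_delay_s` (default 0.330 s) after the previous one, extended to
  `busy_delay_s` (default 2 s) when local time falls inside the busy
  window (default 08:00–18:00, overridable, `None` to disable; windows may
  wrap midnight). Cache hits consume no delay — the floor protects the
  remote server, not the local disk.
* **Cache.** An append-only JSONL file keyed on the exact URL (fragment
  stripped, no other normalization — no canonicalization rule is safe
  across arbitrary forum software). The first retrieved copy wins; a
  reopened cache resolves all previously fetched URLs with zero network
  requests.
* **Visited log.** One URL per line, appended after a page's records have
  been extracted. Within a run, an in-memory visited set prevents
  re-scraping (shared threads, cyclic next links). Across runs the log
  marks pages whose network fetch completed: a restarted crawl re-reads
  them from the cache — so an interrupted run converges to the same record
  multiset as an uninterrupted one — while a page killed mid-extraction is
  absent from the log and genuinely retried. The log and cache jointly
  guarantee at most one network request per URL, ever.

Ordering choice: the visited-log check happens before a fetch is enqueued,
and the log write happens only after successful extraction, so a crash
between fetch and extraction costs one cached re-read, never data loss.

Failure policy is skip-and-log: a page that 404s or times out ends the walk
of its container (without the body the next link is unknowable) but never
aborts the crawl. There are no automatic retries; the timeout is 30 s.

## Configuration dialect

The per-site configuration is an INI-like document with top-level
`proxy`/`dateFormat` keys and `[Files_Info]`, `[Threads_Info]`,
`[Messages_Info]` sections. Property lines follow
`predicate = 'xpath'::annotation`. Points the published dialect leaves
open, decided here:

* **Quoting.** Values nest single quotes inside single-quoted XPaths with
  no escape syntax; the value is therefore delimited by the *first* quote
  after `=` and the *last* quote before the annotation separator, inner
  quotes preserved verbatim. ASCII and typographic quotes are accepted
  interchangeably, and whitespace around `=`, `::` and inside CURIE tokens
  is stripped, so published-style listings parse as printed.
* **Annotation partition.** `id` → identifier; a token prefixed `xsd:` or
  `rdf:` → datatype; a bare 2–3 lowercase-letter token → language tag;
  anything else is a dialect error. Each token has exactly one reading.
* **Extra keys.** `invalidAuthors` (comma-separated marker strings,
  default `Unknown, Deleted profile`), `minDelaySeconds`,
  `busyDelaySeconds`, `busyWindow` and an optional `[Namespaces]` section
  give explicit homes to parameters that otherwise exist only in prose.
  Validation requires `busy_delay_s >= min_delay_s >= 0` and that every
  prefix used by a predicate or datatype is declared (seven vocabularies
  are pre-declared: sioc, dc, foaf, rdf, owl, xsd, nie).
* Missing mandatory elements (`sioc:Thread`, `sioc:Post`, either
  `nextPage`) are all collected and reported together, not one at a time.

## Extraction

Pages are parsed with lxml's tolerant HTML parser; extraction is a pure
function of (page body, section spec). The identifier XPath yields `n`
nodes in document order; identifier values resolve attribute → `href` →
text, then against the page URL to an absolute URL. Each property XPath
must match exactly `n` nodes; on any other count the property is dropped
*for that page* with a warning. Dropping (rather than truncating or
erroring) keeps identifiers authoritative when a site intersperses
unexpected markup; truncation could silently misalign authors with posts,
which is the worst failure mode for this data. Text values are
whitespace-normalized (runs collapsed, ends stripped) except `rdf:HTML`
values, which keep the node's inner markup verbatim.

**Date patterns.** `d m Y H i s` capture 1–2/1–2/4/2/2/2 digits; any other
character is a literal, with two extensions: `*` lazily skips any run and
`?` makes the preceding element optional (a `?` following an already
optional element is inert, so doubled `??` in published patterns parses
harmlessly). A literal space matches any whitespace run, absorbing the
spurious spacing seen in printed patterns. Matching is anchored at both
ends; a match must produce a valid calendar date (month 13 fails) with
day, month and year present; missing time components default to 00:00:00.
On success the value becomes `YYYY-MM-DDTHH:MM:SS` typed `xsd:dateTime`;
on failure (or an empty pattern) the raw string is emitted untyped —
standardization never destroys data it cannot interpret.

## Graph model

The RDF layer is a triple *multiset* with insertion-order N-Triples
serialization, so identical inputs yield bit-identical files and the line
count equals the triple count. Literal escaping covers the N-Triples
grammar plus all control and Unicode line-separator characters, keeping
one statement per line for arbitrary content. Graph comparison is multiset
equality; `isomorphic()` additionally admits blank-node relabeling via
color refinement with brute force over residual color classes (blank
population in these graphs is tiny — one per unknown author).

Structural triples: one `rdf:type` per entity (deduplicated — a thread
listed under two boards is typed once but keeps both containment edges),
`sioc:has_container` for post→thread and thread→forum, `sioc:has_host`
for forum→site. SIOC's own containment terms are used because the layout
draws these edges without naming predicates. The creator predicate is
whatever the configuration declares (`dc:creator` and `sioc:creator` are
both recognized as creator-like).

Unknown authors get the deterministic node
`urn:<site-host>:author:<percent-encoded nickname>` — collision-free per
site without inventing state — and a blank profile node whose label is
derived from the author node's SHA1, so reruns are bit-identical. One
author node exists per distinct (nickname, profile URL) pair per site,
which preserves linkability across posts.

## Anonymization

`pseudonym_urn(v) = "urn:vigi4med:" + sha1hex(utf8(v))`, full 40-hex
digest. SHA1 is retained for fidelity to the original scheme despite its
cryptographic weakness; the `algorithm` parameter accepts any hashlib
digest without changing the data model. Identifying nodes are those typed
`sioc:Post/Thread/Forum/Site`, author nodes, profile URLs and nicknames.
Dates and free-text content are left in clear: the scheme targets
identifiers, not free-text de-identification.

The split is: author type triples stay in the anonymized graph with URN
subjects; author `owl:sameAs` and `foaf:nick` triples move to the key
graph; every other identifying node contributes a
`(urn, owl:sameAs, original)` key entry. Values already carrying the URN
prefix map to themselves and generate no keys, making the operation
idempotent (no double hashing). Invalid authors — normally absent, since
graph building drops them — are swept out defensively together with
creator edges pointing at them.

Reversal substitutes every URN by its key-graph original and reattaches
the held-back author triples. An unknown author's synthetic node is not
recorded in the keys (they hold only the blank profile and the nickname);
it is reconstructed from the restored nickname and restored site host by
the same rule the builder uses. URNs with no key are reported unresolved
and left as-is.

## Synthetic sites and what they do (not) show

The fixture generator builds ground truth first and renders HTML from it,
so crawl/extraction/graph checks are exact equalities, not similarity
scores. Default geometry: 2 forums × 3 threads × 4 posts, two entries per
page (16 pages) — small enough that the throttled live-HTTP acceptance
crawl finishes in seconds, large enough to exercise pagination on both
levels. The author pool (3 known / 2 unknown / 1 invalid) cycles through
thread and post author cells, guaranteeing all three classes appear;
nicknames are ≥ 6 seeded characters so substring leak checks are
meaningful. Dates render in a French-style `le d-m-Y a H:i:s` form matched
by the emitted `dateFormat`; ad blocks are injected at a configurable rate
and share no attributes with the configured XPaths.

Passing against these fixtures demonstrates the machinery — pagination,
alignment, dedup, recovery, typing, anonymization — under clean,
structurally regular HTML. It does not demonstrate robustness to the
things real forums add: layout drift over time, authenticated or
script-generated content, encodings beyond UTF-8, or XPaths that
mis-select on pathological markup. Those remain the responsibility of the
person writing a site's configuration.

## Known limitations

* No JavaScript execution, authentication, or robots.txt handling; live
  crawling is deliberately gated behind an explicit host allowlist.
* Sequential fetching only; politeness is defined per-process.
* Blank-node isomorphism falls back to permutation search within color
  classes; adversarial automorphic graphs could make it slow (never
  encountered in this domain's graphs).
* The date-pattern `?` semantics are this package's pinned reading of an
  ambiguous published convention; they are documented and test-covered
  rather than claimed canonical.
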