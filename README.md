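# forumscrape

Configuration-driven extraction of structured data from web forums into
anonymized RDF graphs.

Patient discussions on health forums are a rich, under-reported source of
adverse-drug-reaction signals, but mining them raises two hard constraints
that generic crawlers ignore: the privacy of the people writing, and the
load placed on the servers hosting the forums. `forumscrape` addresses the
collection step under both constraints. Given a small per-site
configuration file, it crawls a forum the way a reader would — board pages,
thread pages, "next page" links — extracts exactly the page fragments the
configuration names via XPath, represents them as an RDF graph in community
vocabularies (SIOC, Dublin Core, FOAF, NIE), and pseudonymizes every
identifying node reversibly into a data graph plus a separate key graph.

## How it works

**Crawling.** The unit of configuration is one website. A plain-text list
of board URLs seeds the crawl; each board's thread list is walked page by
page following the configured `nextPage` XPath, thread URLs are collected,
and each thread's posts are scraped the same way before the next board is
touched. Page-flipping keeps a logical container across its physical pages:
every record carries the URL of the board or thread it belongs to. A
persistent visited-URL log plus a cache-first proxy layer guarantee that no
URL is requested from the network twice — duplicate listings (a thread
filed under two boards) are scraped once, and a crashed crawl restarted
against the same cache re-reads completed pages locally with zero network
traffic. Between any two network requests the fetcher enforces a minimum
delay of 0.330 s, extended to 2 s inside a configurable busy window
(08:00–18:00 local time by default).

**Extraction.** Each fetched page is parsed tolerantly into a DOM and
queried with XPath 1.0. The identifier XPath (`sioc:Thread` / `sioc:Post`,
annotated `::id`) determines how many entities the page holds; every other
configured property must match exactly that many nodes and is aligned
index-to-index. Ads and navigation chrome match no configured XPath and
contribute nothing. Property lines follow

    RDF_Predicate_name = 'XPath_address'::annotation

where the optional annotation is a datatype CURIE (`xsd:integer`,
`rdf:HTML`), a language tag (`fr`), or `id`. Date strings are standardized
to `xsd:dateTime` through a site-specific pattern over the tokens
`d m Y H i s` with `*` (skip any run) and `?` (previous element optional).

**Graph building.** Threads and posts become typed nodes
(`sioc:Thread`/`sioc:Post`) linked by `sioc:has_container` to their thread,
forum and — via `sioc:has_host` — site. Authors are classified as *known*
(profile link), *unknown* (bare nickname; the missing profile page becomes
a blank node) or *invalid* (site-wide markers such as "Unknown" or
"Deleted profile", which denote many people and therefore produce no
creator triple at all). Each valid author carries exactly three triples:
`rdf:type foaf:Person`, `owl:sameAs` its profile, `foaf:nick` its nickname.

**Anonymization.** Every identifying node — post/thread/forum/site URLs,
author nodes, profile URLs, nicknames — is replaced by
`urn:vigi4med:<sha1-hex-of-value>`. The anonymized graph keeps content,
dates and counts with pseudonymized subjects; the mapping back to the
originals lives in a *separate* key graph (`owl:sameAs` for IRIs,
`foaf:nick` for nicknames), so concatenating the two files reverses the
process while the data file alone leaks nothing.

A deterministic synthetic-forum generator (`forumscrape.fixture`) stands in
for live websites: it builds ground-truth records first and renders the
HTML from them, so every stage can be checked for exact equality offline.

## Worked example

```python
import dataclasses
from forumscrape import (CacheStore, CrawlState, Fetcher, anonymize,
                         build_graph, deanonymize, isomorphic, run_scrape)
from forumscrape.fixture import FixtureParams, fixture_backend, generate_site

fixture = generate_site(FixtureParams(seed=42, noise=0.0))
cfg = dataclasses.replace(fixture.config, min_delay_s=0.0, busy_delay_s=0.0)
backend = fixture_backend(fixture)
fetcher = Fetcher(CacheStore(), cfg, backend)
threads, posts, site_id = run_scrape(cfg, fetcher, CrawlState(),
                                     forum_urls=fixture.forum_list)
print(f"site {site_id}: {len(threads)} threads, {len(posts)} posts "
      f"from {len(backend.request_counts)} pages")

graph = build_graph(threads, posts, site_id, cfg)
print(f"data graph: {len(graph)} triples")
print(graph.serialize().splitlines()[1])

result = anonymize(graph, invalid_strings=cfg.invalid_author_strings)
print(f"anonymized: {len(result.anon_graph)} triples, "
      f"keys: {len(result.key_graph)} triples")
print(result.key_graph.serialize().splitlines()[0])
restored = deanonymize(result.anon_graph, result.key_graph)
print("round-trip isomorphic:", isomorphic(restored.graph, graph))
```

prints

```
site http://forum.example: 6 threads, 24 posts from 16 pages
data graph: 195 triples
<http://forum.example/forum1> <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://rdfs.org/sioc/ns#Forum> .
anonymized: 185 triples, keys: 43 triples
<urn:vigi4med:78695b9a4e0062f5428011ab2fc9b59e8f0ef7a8> <http://www.w3.org/2002/07/owl#sameAs> <http://forum.example/profil/tasucu64> .
round-trip isomorphic: True
```

The synthetic site (2 forums × 3 threads × 4 posts, paginated two entries
per page) yields 6 thread and 24 post records from 16 pages, each page
requested exactly once. The data graph holds 195 triples; anonymization
moves the 10 author profile/nickname triples plus the identifier mappings
into a 43-triple key graph, and combining the two files restores a graph
isomorphic to the original.

The same pipeline is available from a shell:

```
forumscrape gen-fixture --seed 42 --out site/        # write a synthetic site
forumscrape scrape --config site.cfg                 # crawl -> site.n3 + log
forumscrape anonymize --in site.n3 --out anon.n3 --keys keys.n3
forumscrape deanonymize --in anon.n3 --keys keys.n3 --out restored.n3
```

Live crawling refuses hosts that are not explicitly allowlisted with
`--allow-host`; only local addresses are permitted by default.

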