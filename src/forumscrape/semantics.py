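"""From extracted records to an RDF graph.

Each thread and post becomes a typed node (``sioc:Thread`` / ``sioc:Post``)
linked to its container: posts to their thread, threads to their forum
(``sioc:has_container``), forums to the site (``sioc:has_host``).  Extracted
property values become literals, typed or language-tagged according to the
configuration's annotations.  Authors fall into three classes:

* known — the creator cell links to a profile page; the author node is the
  profile URL itself;
* unknown — a bare nickname; the author node is a deterministic per-site URN
  and the missing profile page is represented by a blank node;
* invalid — the cell carries a site-wide marker such as "Unknown" or
  "Deleted profile"; such posts get no creator triple at all, because a
  shared marker string does not identify one person.

Every valid author carries exactly three triples: type (``foaf:Person``),
profile link (``owl:sameAs``) and nickname (``foaf:nick``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from urllib.parse import quote, urlsplit

from .config import ScrapeConfig
from .extract import AuthorCell, DatePattern, EntityRecord, normalize_ws
from .ntriples import Graph, Term, Triple, blank, iri, literal

SIOC = "http://rdfs.org/sioc/ns#"
DC = "http://purl.org/dc/elements/1.1/"
FOAF = "http://xmlns.com/foaf/0.1/"
RDFNS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
OWL = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"

RDF_TYPE = iri(RDFNS + "type")
OWL_SAMEAS = iri(OWL + "sameAs")
FOAF_PERSON = iri(FOAF + "Person")
FOAF_NICK = iri(FOAF + "nick")
SIOC_SITE = iri(SIOC + "Site")
SIOC_FORUM = iri(SIOC + "Forum")
SIOC_THREAD = iri(SIOC + "Thread")
SIOC_POST = iri(SIOC + "Post")
SIOC_HAS_CONTAINER = iri(SIOC + "has_container")
SIOC_HAS_HOST = iri(SIOC + "has_host")
XSD_DATETIME = XSD + "dateTime"

ENTITY_TYPES = {"thread": SIOC_THREAD, "post": SIOC_POST}


@dataclass(frozen=True)
class AuthorProfile:
    """Author classification plus the data needed to emit its triples."""

    classification: str  # "known" | "unknown" | "invalid"
    nickname: str = ""
    profile_url: str | None = None


def classify_author(cell: AuthorCell | None,
                    invalid_strings: tuple[str, ...]) -> AuthorProfile:
    """Apply the known/unknown/invalid rules to a raw creator cell.

    The invalid-marker comparison is case-insensitive and ignores
    surrounding whitespace; an empty cell is invalid too.
    """
    if cell is None:
        return AuthorProfile("invalid")
    nickname = normalize_ws(cell.text)
    if not nickname:
        return AuthorProfile("invalid")
    markers = {normalize_ws(s).lower() for s in invalid_strings}
    if nickname.lower() in markers:
        return AuthorProfile("invalid")
    if cell.href:
        return AuthorProfile("known", nickname, cell.href)
    return AuthorProfile("unknown", nickname)


def site_host(site_id: str) -> str:
    return urlsplit(site_id).netloc or site_id


def unknown_author_iri(host: str, nickname: str) -> str:
    """Deterministic, collision-free per-site node for a profile-less
    nickname."""
    return f"urn:{host}:author:{quote(nickname, safe='')}"


def _profile_blank(author_iri: str) -> Term:
    digest = hashlib.sha1(author_iri.encode("utf-8")).hexdigest()[:24]
    return blank("id" + digest)


def author_node(profile: AuthorProfile, host: str) -> Term:
    if profile.classification == "known":
        return iri(profile.profile_url)
    if profile.classification == "unknown":
        return iri(unknown_author_iri(host, profile.nickname))
    raise ValueError("invalid authors have no node")


def author_triples(profile: AuthorProfile, host: str) -> list[Triple]:
    """The three author-describing triples: type, profile page, nickname.

    For an unknown author the profile object is a blank node whose label is
    derived deterministically from the author node, so reruns emit
    bit-identical output.
    """
    if profile.classification == "invalid":
        raise ValueError("invalid authors carry no triples")
    node = author_node(profile, host)
    same_as = (iri(profile.profile_url) if profile.classification == "known"
               else _profile_blank(node.value))
    return [
        Triple(node, RDF_TYPE, FOAF_PERSON),
        Triple(node, OWL_SAMEAS, same_as),
        Triple(node, FOAF_NICK, literal(profile.nickname)),
    ]


class _GraphBuilder:
    """Accumulates triples while deduplicating exact repeats, so a thread
    listed under two forums keeps one type triple (and both containment
    edges, which differ)."""

    def __init__(self, cfg: ScrapeConfig):
        self.graph = Graph(namespace_map=cfg.namespaces)
        self._seen: set[Triple] = set()

    def add(self, s: Term, p: Term, o: Term) -> None:
        t = Triple(s, p, o)
        if t not in self._seen:
            self._seen.add(t)
            self.graph.add(t)


def build_graph(thread_records: list[EntityRecord],
                post_records: list[EntityRecord],
                site_id: str, cfg: ScrapeConfig) -> Graph:
    """Assemble the full site graph from thread and post records.

    Deterministic given the records: nodes and triples are emitted in record
    order, author identities are deduplicated on (nickname, profile URL).
    """
    builder = _GraphBuilder(cfg)
    host = site_host(site_id)
    date_pattern = DatePattern(cfg.date_format)
    site_node = iri(site_id)
    builder.add(site_node, RDF_TYPE, SIOC_SITE)

    authors_emitted: set[tuple[str, str | None]] = set()

    def emit_author(profile: AuthorProfile) -> Term | None:
        if profile.classification == "invalid":
            return None
        node = author_node(profile, host)
        key = (profile.nickname, profile.profile_url)
        if key not in authors_emitted:
            authors_emitted.add(key)
            for t in author_triples(profile, host):
                builder.add(t.subject, t.predicate, t.object)
        return node

    def emit_record(record: EntityRecord, container: Term) -> None:
        node = iri(record.id_url)
        builder.add(node, RDF_TYPE, ENTITY_TYPES[record.entity_kind])
        builder.add(node, SIOC_HAS_CONTAINER, container)
        for spec, value in record.values:
            predicate = iri(cfg.expand_curie(spec.predicate))
            if spec.is_creator:
                profile = classify_author(record.author_cell,
                                          cfg.invalid_author_strings)
                author = emit_author(profile)
                if author is not None:
                    builder.add(node, predicate, author)
                continue
            if spec.datatype == "xsd:dateTime":
                dt = date_pattern.match(value)
                if dt is None:
                    obj = literal(value)
                else:
                    obj = literal(dt.strftime("%Y-%m-%dT%H:%M:%S"),
                                  datatype=XSD_DATETIME)
            elif spec.annotation.kind == "datatype":
                obj = literal(value, datatype=cfg.expand_curie(spec.datatype))
            elif spec.annotation.kind == "language":
                obj = literal(value, language=spec.language)
            else:
                obj = literal(value)
            builder.add(node, predicate, obj)

    forums_seen: set[str] = set()
    for record in thread_records:
        if record.container_id not in forums_seen:
            forums_seen.add(record.container_id)
            forum_node = iri(record.container_id)
            builder.add(forum_node, RDF_TYPE, SIOC_FORUM)
            builder.add(forum_node, SIOC_HAS_HOST, site_node)
        emit_record(record, iri(record.container_id))

    for record in post_records:
        emit_record(record, iri(record.container_id))

    return builder.graph
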