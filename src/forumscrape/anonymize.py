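"""Reversible pseudonymization of identifying graph nodes.

Identifiers — post/thread/forum/site URLs, author nodes, profile URLs and
nicknames — are replaced throughout the data graph by URNs built from a
cryptographic digest of the original value (SHA1 by default, kept for
fidelity to the original deployment despite its known weakness; any hashlib
algorithm can be substituted without changing the data model).  The mapping
back to the originals is written to a *separate* key graph, so that
concatenating the two files lets any RDF parser undo the pseudonymization,
while the anonymized file alone leaks nothing.

Author handling follows the three-class scheme: a valid author keeps only
its ``foaf:Person`` type triple in the anonymized graph; the profile link
(``owl:sameAs``, a blank node for unknown authors) and the nickname
(``foaf:nick``) move to the key graph.  Invalid authors are removed entirely,
together with any creator edge pointing at them.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from urllib.parse import urlsplit

from .ntriples import Graph, Term, Triple, iri, literal
from .semantics import (FOAF_NICK, FOAF_PERSON, OWL_SAMEAS, RDF_TYPE,
                        SIOC_FORUM, SIOC_POST, SIOC_SITE, SIOC_THREAD,
                        unknown_author_iri)

logger = logging.getLogger(__name__)

DEFAULT_URN_PREFIX = "vigi4med"
DEFAULT_ALGORITHM = "sha1"

_IDENTIFYING_TYPES = (SIOC_POST, SIOC_THREAD, SIOC_FORUM, SIOC_SITE)


def pseudonym_urn(value: str, urn_prefix: str = DEFAULT_URN_PREFIX,
                  algorithm: str = DEFAULT_ALGORITHM) -> str:
    """``urn:<prefix>:`` + lowercase hex digest of the UTF-8 bytes of
    *value*."""
    if not value:
        raise ValueError("cannot pseudonymize an empty value")
    digest = hashlib.new(algorithm, value.encode("utf-8")).hexdigest()
    return f"urn:{urn_prefix}:{digest}"


@dataclass
class AnonymizationResult:
    anon_graph: Graph
    key_graph: Graph


@dataclass
class DeanonymizedGraph:
    graph: Graph
    unresolved: list[str] = field(default_factory=list)


def _author_subjects(g: Graph) -> list[str]:
    out: dict[str, None] = {}
    for t in g:
        if t.predicate == RDF_TYPE and t.object == FOAF_PERSON:
            out.setdefault(t.subject.value, None)
    return list(out)


def _matches_invalid(nick: str, invalid_strings) -> bool:
    markers = {" ".join(s.split()).lower() for s in invalid_strings}
    return " ".join(nick.split()).lower() in markers


def anonymize(g: Graph, invalid_strings: tuple[str, ...] = (),
              urn_prefix: str = DEFAULT_URN_PREFIX,
              algorithm: str = DEFAULT_ALGORITHM) -> AnonymizationResult:
    """Split *g* into an anonymized graph and a key graph.

    Idempotent on its own output: values already carrying the URN prefix map
    to themselves and produce no key entries, so a double run never
    double-hashes.
    """
    urn_marker = f"urn:{urn_prefix}:"

    authors = set(_author_subjects(g))
    # Defensive sweep: invalid authors should never have entered the graph,
    # but an externally supplied graph may still contain them.
    dropped_authors = {
        a for a in authors
        for t in g
        if t.subject.value == a and t.subject.kind == "iri"
        and t.predicate == FOAF_NICK and t.object.kind == "literal"
        and _matches_invalid(t.object.value, invalid_strings)
    }
    authors -= dropped_authors

    typed_nodes: list[str] = []
    seen_typed: set[str] = set()
    for t in g:
        if (t.predicate == RDF_TYPE and t.object in _IDENTIFYING_TYPES
                and t.subject.kind == "iri"
                and t.subject.value not in seen_typed):
            seen_typed.add(t.subject.value)
            typed_nodes.append(t.subject.value)

    def urn_for(value: str) -> str:
        if value.startswith(urn_marker):
            return value
        return pseudonym_urn(value, urn_prefix, algorithm)

    mapping: dict[str, str] = {}
    for value in typed_nodes + sorted(authors):
        mapping[value] = urn_for(value)
    # Profile URLs of known authors coincide with the author node, but any
    # sameAs IRI object hanging off an author is identifying regardless.
    for t in g:
        if (t.subject.value in authors and t.predicate == OWL_SAMEAS
                and t.object.kind == "iri"):
            mapping.setdefault(t.object.value, urn_for(t.object.value))

    def rewrite(term: Term) -> Term:
        if term.kind == "iri" and term.value in mapping:
            return iri(mapping[term.value])
        return term

    anon = Graph(namespace_map=g.namespace_map)
    keys = Graph(namespace_map=g.namespace_map)
    keyed: set[str] = set()

    def emit_key(original: str) -> None:
        if original in keyed or original.startswith(urn_marker):
            return
        keyed.add(original)
        keys.add(Triple(iri(mapping[original]), OWL_SAMEAS, iri(original)))

    for t in g:
        subject_value = t.subject.value if t.subject.kind == "iri" else None
        if subject_value in dropped_authors:
            continue
        if t.object.kind == "iri" and t.object.value in dropped_authors:
            continue  # creator edges to removed authors
        if subject_value in authors:
            urn_subject = iri(mapping[subject_value])
            if t.predicate == RDF_TYPE:
                anon.add(Triple(urn_subject, t.predicate, t.object))
            elif t.predicate == OWL_SAMEAS or t.predicate == FOAF_NICK:
                keys.add(Triple(urn_subject, t.predicate, t.object))
            else:
                anon.add(Triple(urn_subject, t.predicate, rewrite(t.object)))
            continue
        anon.add(Triple(rewrite(t.subject), t.predicate, rewrite(t.object)))

    for value in typed_nodes:
        if value not in authors:
            emit_key(value)

    return AnonymizationResult(anon_graph=anon, key_graph=keys)


def deanonymize(anon_graph: Graph, key_graph: Graph,
                urn_prefix: str = DEFAULT_URN_PREFIX) -> DeanonymizedGraph:
    """Reverse the pseudonymization given the key graph.

    IRI mappings come from the key graph's ``owl:sameAs`` entries.  Unknown
    authors have no IRI key (their profile is a blank node); their original
    node is reconstructed from the restored nickname and the restored site
    host using the same deterministic rule the graph builder applies.  URNs
    with no key are reported in ``unresolved`` and left as-is.
    """
    urn_marker = f"urn:{urn_prefix}:"

    iri_map: dict[str, str] = {}
    author_keys: dict[str, dict] = {}
    for t in key_graph:
        urn = t.subject.value
        if t.predicate == OWL_SAMEAS and t.object.kind == "iri":
            iri_map[urn] = t.object.value
        info = author_keys.setdefault(urn, {})
        if t.predicate == FOAF_NICK and t.object.kind == "literal":
            info["nick"] = t.object.value
        if t.predicate == OWL_SAMEAS:
            info["same_as"] = t.object

    # Site host, for reconstructing unknown-author nodes.
    host = None
    for t in anon_graph:
        if t.predicate == RDF_TYPE and t.object == SIOC_SITE:
            original = iri_map.get(t.subject.value)
            if original:
                host = urlsplit(original).netloc or original
            break

    mapping: dict[str, str] = dict(iri_map)
    for urn, info in author_keys.items():
        if urn in mapping or "nick" not in info:
            continue
        if host is not None:
            mapping[urn] = unknown_author_iri(host, info["nick"])

    unresolved: list[str] = []

    def restore(term: Term) -> Term:
        if term.kind == "iri" and term.value.startswith(urn_marker):
            original = mapping.get(term.value)
            if original is None:
                if term.value not in unresolved:
                    unresolved.append(term.value)
                return term
            return iri(original)
        return term

    restored = Graph(namespace_map=anon_graph.namespace_map)
    for t in anon_graph:
        restored.add(Triple(restore(t.subject), t.predicate,
                            restore(t.object)))

    # Reattach the author triples held back in the key graph.  Only entries
    # carrying a nickname are author keys; bare sameAs entries are plain
    # identifier mappings and contribute nothing beyond the substitution.
    for urn, info in author_keys.items():
        if "nick" not in info:
            continue
        subject = restore(iri(urn))
        if "same_as" in info:
            restored.add(Triple(subject, OWL_SAMEAS, info["same_as"]))
        restored.add(Triple(subject, FOAF_NICK, literal(info["nick"])))

    for urn in unresolved:
        logger.warning("no anonymization key for %s; left as-is", urn)
    return DeanonymizedGraph(graph=restored, unresolved=unresolved)
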