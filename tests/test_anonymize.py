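"""Pseudonymization: URN construction, graph splitting, leak-freedom and
reversal."""

import hashlib
import struct

import pytest

from forumscrape import (Graph, Triple, anonymize, build_graph, deanonymize,
                         iri, isomorphic, literal, pseudonym_urn)
from forumscrape.semantics import (FOAF_NICK, FOAF_PERSON, OWL_SAMEAS,
                                   RDF_TYPE)

from conftest import scrape_fixture


def reference_sha1(data: bytes) -> str:
    """Independent SHA1: direct implementation of the digest's round
    function, used only as an oracle."""
    h = [0x67452301, 0xEFCDAB89, 0x98BADCFE, 0x10325476, 0xC3D2E1F0]
    ml = len(data) * 8
    data += b"\x80" + b"\x00" * ((55 - len(data)) % 64) + struct.pack(">Q", ml)

    def rol(x, n):
        return ((x << n) | (x >> (32 - n))) & 0xFFFFFFFF

    for chunk_start in range(0, len(data), 64):
        w = list(struct.unpack(">16I", data[chunk_start:chunk_start + 64]))
        for i in range(16, 80):
            w.append(rol(w[i - 3] ^ w[i - 8] ^ w[i - 14] ^ w[i - 16], 1))
        a, b, c, d, e = h
        for i in range(80):
            if i < 20:
                f, k = (b & c) | (~b & d), 0x5A827999
            elif i < 40:
                f, k = b ^ c ^ d, 0x6ED9EBA1
            elif i < 60:
                f, k = (b & c) | (b & d) | (c & d), 0x8F1BBCDC
            else:
                f, k = b ^ c ^ d, 0xCA62C1D6
            a, b, c, d, e = ((rol(a, 5) + f + e + k + w[i]) & 0xFFFFFFFF,
                             a, rol(b, 30), c, d)
        h = [(x + y) & 0xFFFFFFFF for x, y in zip(h, (a, b, c, d, e))]
    return "".join(f"{x:08x}" for x in h)


def test_reference_sha1_agrees_with_hashlib():
    for value in (b"", b"abc", b"XYZ", "héllo forum".encode(),
                  b"x" * 200):
        assert reference_sha1(value) == hashlib.sha1(value).hexdigest()


@pytest.mark.parametrize("value", ["XYZ", "http://s/thread1_1", "mimi76"])
def test_pseudonym_urn_is_prefixed_sha1(value):
    assert pseudonym_urn(value) == \
        "urn:vigi4med:" + reference_sha1(value.encode("utf-8"))


def test_pseudonym_determinism_and_distinctness():
    assert pseudonym_urn("XYZ") == pseudonym_urn("XYZ")
    assert pseudonym_urn("marodil42") != pseudonym_urn("beluga77")
    with pytest.raises(ValueError):
        pseudonym_urn("")


def unknown_author_graph():
    """The three triples of an unknown author 'XYZxyz'."""
    from forumscrape.semantics import AuthorProfile, author_triples
    return Graph(author_triples(AuthorProfile("unknown", "XYZxyz"),
                                "forum.example"))


def test_unknown_author_split_between_graphs():
    g = unknown_author_graph()
    result = anonymize(g)
    urn = pseudonym_urn(list(g)[0].subject.value)
    assert result.anon_graph.counter() == Graph(
        [Triple(iri(urn), RDF_TYPE, FOAF_PERSON)]).counter()
    key_preds = sorted(t.predicate.value for t in result.key_graph)
    assert len(result.key_graph) == 2
    assert key_preds == sorted([OWL_SAMEAS.value, FOAF_NICK.value])
    same_as = [t for t in result.key_graph if t.predicate == OWL_SAMEAS]
    assert same_as[0].object.kind == "blank"
    nick = [t for t in result.key_graph if t.predicate == FOAF_NICK]
    assert nick[0].object == literal("XYZxyz")


@pytest.fixture(scope="module")
def anonymized(request):
    site = request.getfixturevalue("site")
    threads, posts, site_id, _ = scrape_fixture(site)
    g = build_graph(threads, posts, site_id, site.config)
    result = anonymize(g, invalid_strings=site.config.invalid_author_strings)
    return site, g, result


def test_literals_survive_with_rewritten_subjects(anonymized):
    site, g, result = anonymized
    views_before = sorted(t.object.value for t in g
                          if t.predicate.value.endswith("num_views"))
    views_after = sorted(t.object.value for t in result.anon_graph
                         if t.predicate.value.endswith("num_views"))
    assert views_before == views_after
    for t in result.anon_graph:
        if t.predicate.value.endswith("num_views"):
            assert t.subject.value.startswith("urn:vigi4med:")


def test_anonymized_graph_leaks_nothing(anonymized):
    site, g, result = anonymized
    text = result.anon_graph.serialize()
    markers = {s.lower() for s in site.config.invalid_author_strings}
    for record in site.truth_records:
        assert record.id_url not in text
        nick = record.author_cell.text
        if nick.lower() not in markers:
            assert nick not in text
    assert site.site_id not in text
    for url in site.forum_list:
        assert url not in text


def test_key_graph_contains_only_mapping_triples(anonymized):
    _, _, result = anonymized
    for t in result.key_graph:
        assert t.subject.value.startswith("urn:vigi4med:")
        assert t.predicate in (OWL_SAMEAS, FOAF_NICK)


def test_linkability_preserved(anonymized):
    """Two posts by the same author share one pseudonymized creator node."""
    site, g, result = anonymized
    creator = iri("http://purl.org/dc/elements/1.1/creator")
    originals = {}
    for t in g:
        if t.predicate == creator:
            originals.setdefault(t.object.value, set())
    anon_creators = {t.object.value for t in result.anon_graph
                     if t.predicate == creator}
    assert len(anon_creators) == len(originals)


def test_round_trip_restores_original_graph(anonymized):
    site, g, result = anonymized
    restored = deanonymize(result.anon_graph, result.key_graph)
    assert restored.unresolved == []
    assert isomorphic(restored.graph, g)


def test_without_keys_nothing_is_recoverable(anonymized):
    site, g, result = anonymized
    text = result.anon_graph.serialize()
    identifying = {r.id_url for r in site.truth_records}
    identifying |= {r.author_cell.text for r in site.truth_records
                    if r.author_cell.href}
    assert not any(value in text for value in identifying)


def test_anonymize_is_idempotent(anonymized):
    _, _, result = anonymized
    again = anonymize(result.anon_graph)
    assert again.anon_graph == result.anon_graph
    assert len(again.key_graph) == 0  # urns are never re-hashed


def test_invalid_only_graph_has_no_person_triples():
    from forumscrape.semantics import AuthorProfile, author_triples
    g = Graph(author_triples(AuthorProfile("unknown", "Deleted profile"),
                             "forum.example"))
    g.add(Triple(iri("http://s/post1"),
                 iri("http://purl.org/dc/elements/1.1/creator"),
                 list(g)[0].subject))
    result = anonymize(g, invalid_strings=("Deleted profile",))
    assert all(t.object != FOAF_PERSON for t in result.anon_graph)
    creator_edges = [t for t in result.anon_graph
                     if t.predicate.value.endswith("creator")]
    assert creator_edges == []


def test_rerun_emits_bit_identical_files(anonymized):
    site, g, result = anonymized
    second = anonymize(g, invalid_strings=site.config.invalid_author_strings)
    assert second.anon_graph.serialize() == result.anon_graph.serialize()
    assert second.key_graph.serialize() == result.key_graph.serialize()
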