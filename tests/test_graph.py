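"""Semantic graph construction and N-Triples round-trips."""

import pytest
from hypothesis import given, strategies as st

from forumscrape import (AuthorCell, AuthorProfile, Graph, Triple,
                         author_triples, blank, build_graph, classify_author,
                         iri, isomorphic, literal, parse_ntriples,
                         serialize_ntriples)
from forumscrape.ntriples import NTriplesParseError
from forumscrape.semantics import (FOAF_NICK, FOAF_PERSON, OWL_SAMEAS,
                                   RDF_TYPE, SIOC_FORUM, SIOC_HAS_CONTAINER,
                                   SIOC_HAS_HOST, SIOC_POST, SIOC_SITE,
                                   SIOC_THREAD, XSD_DATETIME)

from conftest import scrape_fixture

INVALID = ("Unknown", "Deleted profile")


class TestClassifyAuthor:
    def test_anchor_with_href_is_known(self):
        cell = AuthorCell(text="Marie", href="http://s/profil/marie")
        profile = classify_author(cell, INVALID)
        assert profile == AuthorProfile("known", "Marie",
                                        "http://s/profil/marie")

    def test_bare_text_is_unknown(self):
        assert classify_author(AuthorCell(text="mimi76"), INVALID) == \
            AuthorProfile("unknown", "mimi76")

    @pytest.mark.parametrize("text", ["Unknown", "unknown  ",
                                      "Profil supprimé", ""])
    def test_marker_strings_and_empty_cells_are_invalid(self, text):
        invalid = INVALID + ("Profil supprimé",)
        profile = classify_author(AuthorCell(text=text), invalid)
        assert profile.classification == "invalid"

    def test_missing_cell_is_invalid(self):
        assert classify_author(None, INVALID).classification == "invalid"


class TestAuthorTriples:
    def test_known_author_three_triples_sameas_profile(self):
        profile = AuthorProfile("known", "Marie", "http://s/profil/marie")
        triples = author_triples(profile, "s")
        assert len(triples) == 3
        node = iri("http://s/profil/marie")
        assert Triple(node, RDF_TYPE, FOAF_PERSON) in triples
        assert Triple(node, OWL_SAMEAS, iri("http://s/profil/marie")) in triples
        assert Triple(node, FOAF_NICK, literal("Marie")) in triples

    def test_unknown_author_sameas_is_a_blank_node(self):
        triples = author_triples(AuthorProfile("unknown", "XYZ"), "s")
        assert len(triples) == 3
        same_as = [t for t in triples if t.predicate == OWL_SAMEAS]
        assert same_as[0].object.kind == "blank"
        # deterministic: a rerun emits the identical blank label
        again = author_triples(AuthorProfile("unknown", "XYZ"), "s")
        assert triples == again

    def test_invalid_author_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            author_triples(AuthorProfile("invalid"), "s")


class TestBuildGraph:
    def test_truth_graph_reproduced_from_scrape(self, site):
        threads, posts, site_id, _ = scrape_fixture(site)
        g = build_graph(threads, posts, site_id, site.config)
        assert g == site.truth_graph

    def test_every_entity_has_exactly_one_type_triple(self, noisy_shared_site):
        site = noisy_shared_site
        g = site.truth_graph
        for record in site.truth_records:
            types = g.objects(subject=iri(record.id_url), predicate=RDF_TYPE)
            assert len(types) == 1

    def test_containment_chain_post_thread_forum_site(self, site):
        g = site.truth_graph
        for record in site.truth_posts:
            containers = g.objects(subject=iri(record.id_url),
                                   predicate=SIOC_HAS_CONTAINER)
            assert len(containers) == 1
            thread = containers[0]
            assert SIOC_THREAD in g.objects(subject=thread,
                                            predicate=RDF_TYPE)
            forum = g.objects(subject=thread,
                              predicate=SIOC_HAS_CONTAINER)[0]
            assert SIOC_FORUM in g.objects(subject=forum, predicate=RDF_TYPE)
            host = g.objects(subject=forum, predicate=SIOC_HAS_HOST)[0]
            assert SIOC_SITE in g.objects(subject=host, predicate=RDF_TYPE)

    def test_typed_and_tagged_literals(self, site):
        g = site.truth_graph
        content = [t.object for t in g
                   if t.predicate.value.endswith("sioc/ns#content")]
        assert content and all(o.language == "fr" for o in content)
        views = [t.object for t in g
                 if t.predicate.value.endswith("num_views")]
        assert views and all(
            o.datatype.endswith("XMLSchema#integer") and o.value.isdigit()
            for o in views)
        dates = [t.object for t in g
                 if t.predicate.value.endswith("elements/1.1/date")]
        assert dates and all(o.datatype == XSD_DATETIME for o in dates)
        # normalization really ran: values are ISO, not the page rendering
        assert all(o.value[4] == "-" and "T" in o.value for o in dates)

    def test_invalid_author_posts_have_no_creator_triple(self, site):
        invalid_markers = {s.lower()
                           for s in site.config.invalid_author_strings}
        invalid_posts = [r for r in site.truth_posts
                         if r.author_cell.text.lower() in invalid_markers]
        assert invalid_posts  # the default author pool includes one
        g = site.truth_graph
        creator = "http://purl.org/dc/elements/1.1/creator"
        for record in invalid_posts:
            assert g.objects(subject=iri(record.id_url),
                             predicate=iri(creator)) == []

    def test_same_nickname_shares_one_author_node(self, site):
        g = site.truth_graph
        creator = iri("http://purl.org/dc/elements/1.1/creator")
        by_nick = {}
        for record in site.truth_posts:
            nodes = g.objects(subject=iri(record.id_url), predicate=creator)
            if nodes:
                by_nick.setdefault(record.author_cell.text, set()).update(
                    n.value for n in nodes)
        repeated = [n for n, nodes in by_nick.items() if len(nodes) > 1]
        assert repeated == []


class TestNTriples:
    def test_type_triple_shape(self):
        g = Graph([Triple(iri("http://u"), RDF_TYPE, FOAF_PERSON)])
        assert serialize_ntriples(g) == (
            "<http://u> "
            "<http://www.w3.org/1999/02/22-rdf-syntax-ns#type> "
            "<http://xmlns.com/foaf/0.1/Person> .\n")

    def test_empty_graph_serializes_empty(self):
        assert serialize_ntriples(Graph()) == ""

    def test_newline_literal_stays_on_one_line(self):
        g = Graph([Triple(iri("http://u"), iri("http://p"),
                          literal("line1\nline2\t\"quoted\""))])
        text = serialize_ntriples(g)
        assert text.count("\n") == 1
        assert "\\n" in text and '\\"' in text
        assert parse_ntriples(text) == g

    def test_line_count_equals_triple_count(self, site):
        text = serialize_ntriples(site.truth_graph)
        assert len(text.splitlines()) == len(site.truth_graph)

    def test_malformed_line_reports_line_number(self):
        text = "<http://u> <http://p> <http://o> .\nnot a triple\n"
        with pytest.raises(NTriplesParseError, match="line 2"):
            parse_ntriples(text)

    def test_rdflib_parses_our_serialization_identically(self, site):
        """Independent conformance oracle: rdflib must read our N-Triples
        output and agree on the triple set."""
        rdflib = pytest.importorskip("rdflib")
        from rdflib.compare import isomorphic as rdflib_isomorphic

        text = serialize_ntriples(site.truth_graph)
        parsed = rdflib.Graph()
        parsed.parse(data=text, format="nt")
        assert len(parsed) == len(set(site.truth_graph.triples))

        def to_rdflib(term):
            if term.kind == "iri":
                return rdflib.URIRef(term.value)
            if term.kind == "blank":
                return rdflib.BNode(term.value)
            return rdflib.Literal(term.value, lang=term.language,
                                  datatype=term.datatype)

        constructed = rdflib.Graph()
        for t in site.truth_graph:
            constructed.add((to_rdflib(t.subject), to_rdflib(t.predicate),
                             to_rdflib(t.object)))
        assert rdflib_isomorphic(parsed, constructed)


_terms = st.deferred(lambda: st.one_of(
    st.sampled_from([iri("http://a/x"), iri("http://a/y"), iri("urn:z:1")]),
    st.builds(blank, st.sampled_from(["b0", "b1", "b2", "idabc123"])),
    st.one_of(
        st.text(max_size=12).map(literal),
        st.text(max_size=8).map(
            lambda v: literal(v, datatype="http://www.w3.org/2001/"
                                          "XMLSchema#string")),
        st.text(max_size=8).map(lambda v: literal(v, language="fr")),
    ),
))

_subjects = st.one_of(st.sampled_from([iri("http://a/x"), iri("http://a/y")]),
                      st.builds(blank, st.sampled_from(["b0", "b1", "b2"])))
_predicates = st.sampled_from([iri("http://p/1"), iri("http://p/2"),
                               RDF_TYPE])

_graphs = st.lists(st.builds(Triple, _subjects, _predicates, _terms),
                   max_size=25).map(Graph)


@given(g=_graphs)
def test_ntriples_round_trip_random_graphs(g):
    """parse(serialize(G)) returns the same triple multiset (and hence is
    isomorphic) for arbitrary graphs with blanks, datatypes, tags and
    duplicate triples."""
    back = parse_ntriples(serialize_ntriples(g))
    assert back == g
    assert isomorphic(back, g)


def test_isomorphic_accepts_blank_relabeling_and_rejects_mismatch():
    g1 = Graph([Triple(iri("http://s"), OWL_SAMEAS, blank("alpha")),
                Triple(blank("alpha"), RDF_TYPE, FOAF_PERSON)])
    g2 = Graph([Triple(iri("http://s"), OWL_SAMEAS, blank("beta")),
                Triple(blank("beta"), RDF_TYPE, FOAF_PERSON)])
    g3 = Graph([Triple(iri("http://s"), OWL_SAMEAS, blank("beta")),
                Triple(blank("gamma"), RDF_TYPE, FOAF_PERSON)])
    assert isomorphic(g1, g2)
    assert not isomorphic(g1, g3)
    assert not isomorphic(g1, Graph(list(g1)[:1]))
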