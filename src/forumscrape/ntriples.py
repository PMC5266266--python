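"""Minimal RDF model: terms, triples, a triple *multiset* graph, N-Triples I/O.

The graph deliberately keeps duplicate triples and blank-node labels exactly
as produced, so that serialization is deterministic (one line per triple, in
insertion order) and reruns yield bit-identical files.  Isomorphism up to
blank-node relabeling is provided for comparing graphs.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Term:
    """An RDF term: IRI, blank node, or literal.

    ``datatype`` and ``language`` are mutually exclusive and only meaningful
    for literals; ``datatype`` holds a full IRI, ``language`` a BCP-47 tag.
    """

    kind: str  # "iri" | "blank" | "literal"
    value: str
    datatype: str | None = None
    language: str | None = None

    def __post_init__(self):
        if self.datatype is not None and self.language is not None:
            raise ValueError("datatype and language are mutually exclusive")
        if self.kind != "literal" and (self.datatype or self.language):
            raise ValueError(f"{self.kind} term cannot carry datatype/language")


def iri(value: str) -> Term:
    return Term("iri", value)


def blank(label: str) -> Term:
    return Term("blank", label)


def literal(value: str, datatype: str | None = None,
            language: str | None = None) -> Term:
    return Term("literal", value, datatype=datatype, language=language)


@dataclass(frozen=True)
class Triple:
    subject: Term
    predicate: Term
    object: Term


class Graph:
    """A multiset of triples with an optional prefix → IRI table."""

    def __init__(self, triples: Iterable[Triple] = (),
                 namespace_map: dict[str, str] | None = None):
        self.triples: list[Triple] = list(triples)
        self.namespace_map = dict(namespace_map or {})

    def add(self, t: Triple) -> None:
        self.triples.append(t)

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples)

    def counter(self) -> Counter:
        return Counter(self.triples)

    def __eq__(self, other) -> bool:
        """Multiset equality of triples (order-insensitive, label-exact)."""
        if not isinstance(other, Graph):
            return NotImplemented
        return self.counter() == other.counter()

    def __hash__(self):  # pragma: no cover - graphs are mutable
        raise TypeError("Graph is unhashable")

    def subjects(self, predicate: Term | None = None,
                 object: Term | None = None) -> list[Term]:
        return [t.subject for t in self.triples
                if (predicate is None or t.predicate == predicate)
                and (object is None or t.object == object)]

    def objects(self, subject: Term | None = None,
                predicate: Term | None = None) -> list[Term]:
        return [t.object for t in self.triples
                if (subject is None or t.subject == subject)
                and (predicate is None or t.predicate == predicate)]

    def serialize(self) -> str:
        return serialize_ntriples(self)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.serialize())


# --- serialization ----------------------------------------------------------

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}

#: Characters str.splitlines treats as line breaks, beyond \n and \r.
_LINE_SEPARATORS = "\x0b\x0c\x1c\x1d\x1e\x85\u2028\u2029"


def _escape_literal(value: str) -> str:
    out = []
    for c in value:
        if c in _ESCAPES:
            out.append(_ESCAPES[c])
        elif ord(c) < 0x20 or c in _LINE_SEPARATORS:
            out.append(f"\\u{ord(c):04X}")
        else:
            out.append(c)
    return "".join(out)


_UNESCAPES = {"\\": "\\", '"': '"', "n": "\n", "r": "\r", "t": "\t"}


def _unescape_literal(value: str) -> str:
    out, i = [], 0
    while i < len(value):
        c = value[i]
        if c == "\\" and i + 1 < len(value):
            nxt = value[i + 1]
            if nxt in _UNESCAPES:
                out.append(_UNESCAPES[nxt])
                i += 2
                continue
            if nxt in "uU":
                width = 4 if nxt == "u" else 8
                out.append(chr(int(value[i + 2:i + 2 + width], 16)))
                i += 2 + width
                continue
        out.append(c)
        i += 1
    return "".join(out)


def _term_nt(term: Term) -> str:
    if term.kind == "iri":
        return f"<{term.value}>"
    if term.kind == "blank":
        return f"_:{term.value}"
    lit = f'"{_escape_literal(term.value)}"'
    if term.language:
        return f"{lit}@{term.language}"
    if term.datatype:
        return f"{lit}^^<{term.datatype}>"
    return lit


def serialize_ntriples(g: Graph) -> str:
    """One line per triple, each terminated by `` .`` — line count equals
    triple count."""
    return "".join(
        f"{_term_nt(t.subject)} {_term_nt(t.predicate)} {_term_nt(t.object)} .\n"
        for t in g.triples)


# --- parsing ----------------------------------------------------------------

class NTriplesParseError(ValueError):
    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


_TERM_RE = re.compile(
    r"""\s*(?:
        <(?P<iri>[^>]*)>
      | _:(?P<blank>[^\s]+)
      | "(?P<lit>(?:[^"\\]|\\.)*)"
        (?:@(?P<lang>[A-Za-z][A-Za-z0-9-]*)|\^\^<(?P<dt>[^>]*)>)?
    )""", re.VERBOSE)


def _parse_term(line: str, pos: int, lineno: int) -> tuple[Term, int]:
    m = _TERM_RE.match(line, pos)
    if not m:
        raise NTriplesParseError(f"malformed term at column {pos}", lineno)
    if m.group("iri") is not None:
        return iri(m.group("iri")), m.end()
    if m.group("blank") is not None:
        return blank(m.group("blank")), m.end()
    return literal(_unescape_literal(m.group("lit")),
                   datatype=m.group("dt"), language=m.group("lang")), m.end()


def parse_ntriples(text: str,
                   namespace_map: dict[str, str] | None = None) -> Graph:
    """Parse an N-Triples document.  Malformed lines raise
    :class:`NTriplesParseError` carrying the 1-based line number."""
    g = Graph(namespace_map=namespace_map)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        s, pos = _parse_term(line, 0, lineno)
        p, pos = _parse_term(line, pos, lineno)
        o, pos = _parse_term(line, pos, lineno)
        if s.kind == "literal":
            raise NTriplesParseError("literal subject", lineno)
        if p.kind != "iri":
            raise NTriplesParseError("predicate must be an IRI", lineno)
        rest = line[pos:].strip()
        if rest != ".":
            raise NTriplesParseError(f"expected terminating '.', got {rest!r}",
                                     lineno)
        g.add(Triple(s, p, o))
    return g


# --- isomorphism up to blank relabeling -------------------------------------

def _blank_labels(g: Graph) -> list[str]:
    seen: dict[str, None] = {}
    for t in g:
        for term in (t.subject, t.object):
            if term.kind == "blank":
                seen.setdefault(term.value, None)
    return list(seen)


def _signature(g: Graph, colors: dict[str, int]) -> dict[str, tuple]:
    sig: dict[str, list] = {label: [] for label in colors}

    def key(term: Term) -> tuple:
        if term.kind == "blank":
            return ("b", colors[term.value])
        return (term.kind, term.value, term.datatype, term.language)

    for t in g:
        if t.subject.kind == "blank":
            sig[t.subject.value].append(("s", key(t.predicate), key(t.object)))
        if t.object.kind == "blank":
            sig[t.object.value].append(("o", key(t.predicate), key(t.subject)))
    return {label: tuple(sorted(rows)) for label, rows in sig.items()}


def _relabel(g: Graph, mapping: dict[str, str]) -> Counter:
    def sub(term: Term) -> Term:
        if term.kind == "blank":
            return blank(mapping[term.value])
        return term

    return Counter(Triple(sub(t.subject), t.predicate, sub(t.object)) for t in g)


def isomorphic(g1: Graph, g2: Graph) -> bool:
    """True when the graphs hold the same triple multiset up to a bijective
    relabeling of blank nodes."""
    if g1.counter() == g2.counter():
        return True
    b1, b2 = _blank_labels(g1), _blank_labels(g2)
    if len(b1) != len(b2) or len(g1) != len(g2):
        return False
    colors1 = {b: 0 for b in b1}
    colors2 = {b: 0 for b in b2}
    for _ in range(max(3, len(b1))):
        sig1, sig2 = _signature(g1, colors1), _signature(g2, colors2)
        palette = {s: i for i, s in enumerate(sorted(set(sig1.values())
                                                     | set(sig2.values())))}
        colors1 = {b: palette[sig1[b]] for b in b1}
        colors2 = {b: palette[sig2[b]] for b in b2}
    groups1: dict[int, list[str]] = {}
    groups2: dict[int, list[str]] = {}
    for b, c in colors1.items():
        groups1.setdefault(c, []).append(b)
    for b, c in colors2.items():
        groups2.setdefault(c, []).append(b)
    if sorted(groups1) != sorted(groups2):
        return False
    if any(len(groups1[c]) != len(groups2[c]) for c in groups1):
        return False
    # Brute-force the (usually singleton) color classes.
    classes = sorted(groups1)
    candidates = [list(itertools.permutations(groups2[c])) for c in classes]
    base = g1.counter()
    for combo in itertools.product(*candidates):
        mapping: dict[str, str] = {}
        for c, perm in zip(classes, combo):
            mapping.update(dict(zip(groups1[c], perm)))
        inverse = {v: k for k, v in mapping.items()}
        if _relabel(g2, inverse) == base:
            return True
    return False
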