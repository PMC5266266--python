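"""Per-site scrape configuration: the INI-like dialect and its data model.

A configuration file drives everything the scraper does on one website: which
XPath leads to a thread or post identifier, which page element is the
"next page" link, and which further page fragments become RDF properties.
Property lines follow the pattern::

    RDF_Predicate_name = 'XPath_address'::annotation

where the annotation is optional and is either ``id`` (marks the identifier
XPath), a datatype CURIE such as ``xsd:integer`` / ``rdf:HTML``, or a
2-3 letter language tag such as ``fr``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from datetime import time as dtime

logger = logging.getLogger(__name__)

#: Characters accepted as value delimiters.  Published configuration examples
#: freely mix typographic and ASCII quotes; all four are treated alike.
QUOTE_CHARS = "'\"‘’"

#: Prefixes whose annotation tokens denote a literal datatype.
DATATYPE_PREFIXES = ("xsd", "rdf")

#: Predicates whose extracted cell is an author reference, not a plain literal.
CREATOR_PREDICATES = ("dc:creator", "sioc:creator")

DEFAULT_NAMESPACES = {
    "sioc": "http://rdfs.org/sioc/ns#",
    "dc": "http://purl.org/dc/elements/1.1/",
    "foaf": "http://xmlns.com/foaf/0.1/",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "nie": "http://www.semanticdesktop.org/ontologies/2007/01/19/nie#",
}

DEFAULT_INVALID_AUTHORS = ("Unknown", "Deleted profile")

#: Polite-crawling defaults: floor between sequential requests, and the
#: extended floor applied inside the configured busy window.
DEFAULT_MIN_DELAY_S = 0.330
DEFAULT_BUSY_DELAY_S = 2.0
DEFAULT_BUSY_WINDOW = (dtime(8, 0), dtime(18, 0))


class DialectError(ValueError):
    """A property line does not match the accepted pattern."""

    def __init__(self, message: str, line: str):
        super().__init__(f"{message}: {line!r}")
        self.line = line


class ValidationError(ValueError):
    """A parsed configuration misses mandatory elements."""

    def __init__(self, missing: list[str]):
        super().__init__("missing mandatory configuration element(s): "
                         + ", ".join(missing))
        self.missing = list(missing)


@dataclass(frozen=True)
class Annotation:
    """Optional trailing ``::token`` of a property line.

    kind is one of ``none`` / ``identifier`` / ``datatype`` / ``language``;
    ``value`` carries the datatype CURIE or the language tag.
    """

    kind: str = "none"
    value: str | None = None

    def token(self) -> str | None:
        if self.kind == "none":
            return None
        if self.kind == "identifier":
            return "id"
        return self.value


NO_ANNOTATION = Annotation()


@dataclass(frozen=True)
class PropertySpec:
    """One ``predicate = 'xpath'::annotation`` mapping."""

    predicate: str
    xpath: str
    annotation: Annotation = NO_ANNOTATION

    @property
    def is_creator(self) -> bool:
        return self.predicate in CREATOR_PREDICATES

    @property
    def datatype(self) -> str | None:
        return self.annotation.value if self.annotation.kind == "datatype" else None

    @property
    def language(self) -> str | None:
        return self.annotation.value if self.annotation.kind == "language" else None


@dataclass(frozen=True)
class SectionSpec:
    """One crawl level (thread listing or post listing)."""

    id_spec: PropertySpec
    next_page_xpath: str
    properties: tuple[PropertySpec, ...] = ()


@dataclass(frozen=True)
class ScrapeConfig:
    proxy: str = ""
    date_format: str = ""
    forums_input_list: str = ""
    log_file: str = ""
    rdf_file: str = ""
    threads: SectionSpec | None = None
    messages: SectionSpec | None = None
    invalid_author_strings: tuple[str, ...] = DEFAULT_INVALID_AUTHORS
    busy_window: tuple[dtime, dtime] | None = DEFAULT_BUSY_WINDOW
    min_delay_s: float = DEFAULT_MIN_DELAY_S
    busy_delay_s: float = DEFAULT_BUSY_DELAY_S
    namespace_map: tuple[tuple[str, str], ...] = tuple(DEFAULT_NAMESPACES.items())

    @property
    def namespaces(self) -> dict[str, str]:
        return dict(self.namespace_map)

    def expand_curie(self, curie: str) -> str:
        prefix, local = curie.split(":", 1)
        ns = self.namespaces.get(prefix)
        if ns is None:
            raise ValidationError([f"namespace prefix {prefix!r}"])
        return ns + local


def _normalize_curie(token: str) -> str:
    """Collapse whitespace inside a CURIE-ish token (``sioc: Thread``)."""
    return re.sub(r"\s+", "", token)


def _resolve_annotation(token: str, line: str) -> Annotation:
    token = _normalize_curie(token)
    if not token:
        raise DialectError("empty annotation after '::'", line)
    if token == "id":
        return Annotation("identifier")
    if ":" in token:
        prefix = token.split(":", 1)[0]
        if prefix in DATATYPE_PREFIXES:
            return Annotation("datatype", token)
        raise DialectError(f"unresolvable annotation token {token!r}", line)
    if re.fullmatch(r"[a-z]{2,3}", token):
        return Annotation("language", token)
    raise DialectError(f"unresolvable annotation token {token!r}", line)


def _unquote(raw: str, line: str) -> str:
    """Return the text between the first and last quote character of *raw*.

    Inner quotes are preserved verbatim — XPath predicates routinely nest
    string literals inside the quoted value and the dialect defines no
    escape syntax.
    """
    positions = [i for i, c in enumerate(raw) if c in QUOTE_CHARS]
    if len(positions) < 2:
        raise DialectError("value is not quoted", line)
    return raw[positions[0] + 1:positions[-1]]


def parse_property_line(line: str) -> PropertySpec:
    """Parse one ``predicate = 'xpath'::annotation`` line.

    The XPath value is delimited by the first quote after ``=`` and the last
    quote before the annotation separator (or end of line); quotes inside the
    value survive untouched.  Whitespace around ``=`` and ``::`` and inside
    CURIE tokens is tolerated.
    """
    if "=" not in line:
        raise DialectError("missing '=' separator", line)
    key, _, rhs = line.partition("=")
    predicate = _normalize_curie(key.strip())
    if not predicate:
        raise DialectError("empty predicate name", line)
    rhs = rhs.strip()

    positions = [i for i, c in enumerate(rhs) if c in QUOTE_CHARS]
    if len(positions) < 2:
        raise DialectError("XPath value is not quoted", line)
    last_quote = positions[-1]
    tail = rhs[last_quote + 1:].strip()
    annotation = NO_ANNOTATION
    if tail:
        if not tail.startswith("::"):
            raise DialectError(f"unexpected trailing text {tail!r}", line)
        annotation = _resolve_annotation(tail[2:], line)
    xpath = rhs[positions[0] + 1:last_quote]
    if not xpath.strip():
        raise DialectError("empty XPath", line)
    return PropertySpec(predicate=predicate, xpath=xpath, annotation=annotation)


# --- whole-file parsing -----------------------------------------------------

_SECTION_RE = re.compile(r"^\[(?P<name>[^\]]+)\]\s*$")

KNOWN_SECTIONS = ("Files_Info", "Threads_Info", "Messages_Info", "Namespaces")

_FILE_KEYS = {
    "forumsInputList": "forums_input_list",
    "logFileName": "log_file",
    "rdfFileName": "rdf_file",
}


def _parse_time(text: str) -> dtime:
    h, m = text.strip().split(":")
    return dtime(int(h), int(m))


def _parse_busy_window(value: str) -> tuple[dtime, dtime] | None:
    value = value.strip()
    if not value:
        return None
    start, _, end = value.partition("-")
    return (_parse_time(start), _parse_time(end))


def _section_from_lines(name: str, lines: list[str],
                        id_key: str) -> tuple[PropertySpec | None, str | None,
                                              list[PropertySpec]]:
    id_spec: PropertySpec | None = None
    next_page: str | None = None
    props: list[PropertySpec] = []
    seen: set[str] = set()
    for line in lines:
        spec = parse_property_line(line)
        if spec.predicate == id_key:
            id_spec = replace(spec, annotation=Annotation("identifier"))
        elif spec.predicate == "nextPage":
            next_page = spec.xpath
        else:
            if spec.predicate in seen:
                raise DialectError(
                    f"duplicate predicate {spec.predicate!r} in [{name}]", line)
            seen.add(spec.predicate)
            props.append(spec)
    return id_spec, next_page, props


def parse_config(text: str) -> ScrapeConfig:
    """Parse a full configuration document into a :class:`ScrapeConfig`.

    Raises :class:`ValidationError` listing *all* missing mandatory elements
    (``sioc:Thread``, ``sioc:Post`` and the two ``nextPage`` entries) rather
    than stopping at the first.
    """
    top: dict[str, str] = {}
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith(";"):
            continue
        m = _SECTION_RE.match(line)
        if m:
            name = m.group("name").strip()
            if name not in KNOWN_SECTIONS:
                logger.warning("ignoring unknown configuration section [%s]", name)
                current = []  # throwaway
                continue
            current = sections.setdefault(name, [])
            continue
        if current is None:
            key, _, value = line.partition("=")
            top[key.strip()] = _unquote(value, line) if any(
                c in QUOTE_CHARS for c in value) else value.strip()
        else:
            current.append(line)

    namespaces = dict(DEFAULT_NAMESPACES)
    for line in sections.get("Namespaces", []):
        key, _, value = line.partition("=")
        namespaces[_normalize_curie(key.strip())] = _unquote(value, line)

    files: dict[str, str] = {}
    for line in sections.get("Files_Info", []):
        key, _, value = line.partition("=")
        attr = _FILE_KEYS.get(key.strip())
        if attr is None:
            logger.warning("ignoring unknown Files_Info key %r", key.strip())
            continue
        files[attr] = _unquote(value, line)

    missing: list[str] = []
    threads = messages = None

    if "Threads_Info" not in sections:
        missing += ["[Threads_Info]", "sioc:Thread", "nextPage (threads)"]
    else:
        id_spec, next_page, props = _section_from_lines(
            "Threads_Info", sections["Threads_Info"], "sioc:Thread")
        if id_spec is None:
            missing.append("sioc:Thread")
        if next_page is None:
            missing.append("nextPage (threads)")
        if id_spec and next_page:
            threads = SectionSpec(id_spec, next_page, tuple(props))

    if "Messages_Info" not in sections:
        missing += ["[Messages_Info]", "sioc:Post", "nextPage (messages)"]
    else:
        id_spec, next_page, props = _section_from_lines(
            "Messages_Info", sections["Messages_Info"], "sioc:Post")
        if id_spec is None:
            missing.append("sioc:Post")
        if next_page is None:
            missing.append("nextPage (messages)")
        if id_spec and next_page:
            messages = SectionSpec(id_spec, next_page, tuple(props))

    if missing:
        raise ValidationError(missing)

    invalid = top.get("invalidAuthors")
    invalid_strings = (tuple(s.strip() for s in invalid.split(",") if s.strip())
                       if invalid is not None else DEFAULT_INVALID_AUTHORS)

    busy_window = (DEFAULT_BUSY_WINDOW if "busyWindow" not in top
                   else _parse_busy_window(top["busyWindow"]))

    min_delay = float(top.get("minDelaySeconds", DEFAULT_MIN_DELAY_S))
    busy_delay = float(top.get("busyDelaySeconds", DEFAULT_BUSY_DELAY_S))
    if min_delay < 0:
        raise ValidationError(["minDelaySeconds must be >= 0"])
    if busy_delay < min_delay:
        raise ValidationError(["busyDelaySeconds must be >= minDelaySeconds"])

    cfg = ScrapeConfig(
        proxy=top.get("proxy", ""),
        date_format=top.get("dateFormat", ""),
        threads=threads,
        messages=messages,
        invalid_author_strings=invalid_strings,
        busy_window=busy_window,
        min_delay_s=min_delay,
        busy_delay_s=busy_delay,
        namespace_map=tuple(namespaces.items()),
        **files,
    )
    _check_prefixes(cfg)
    return cfg


def _check_prefixes(cfg: ScrapeConfig) -> None:
    """Every prefix used by a predicate or datatype must be declared."""
    missing = []
    for section in (cfg.threads, cfg.messages):
        for spec in (section.id_spec, *section.properties):
            for curie in filter(None, (spec.predicate, spec.datatype)):
                if ":" in curie:
                    prefix = curie.split(":", 1)[0]
                    if prefix not in cfg.namespaces:
                        missing.append(f"namespace prefix {prefix!r}")
    if missing:
        raise ValidationError(sorted(set(missing)))


# --- serialization (round-trip support) -------------------------------------

def _property_line(spec: PropertySpec) -> str:
    token = spec.annotation.token()
    suffix = f"::{token}" if token else ""
    return f"{spec.predicate} = '{spec.xpath}'{suffix}"


def serialize_config(cfg: ScrapeConfig) -> str:
    """Render a :class:`ScrapeConfig` back to configuration-file text such
    that ``parse_config(serialize_config(cfg)) == cfg``."""
    out = [
        f"proxy = '{cfg.proxy}'",
        f"dateFormat = '{cfg.date_format}'",
        f"minDelaySeconds = '{cfg.min_delay_s}'",
        f"busyDelaySeconds = '{cfg.busy_delay_s}'",
        "busyWindow = '{}'".format(
            "" if cfg.busy_window is None else
            "{:%H:%M}-{:%H:%M}".format(*cfg.busy_window)),
        "invalidAuthors = '{}'".format(", ".join(cfg.invalid_author_strings)),
        "",
        "[Files_Info]",
        f"forumsInputList = '{cfg.forums_input_list}'",
        f"logFileName = '{cfg.log_file}'",
        f"rdfFileName = '{cfg.rdf_file}'",
        "",
        "[Namespaces]",
    ]
    out += [f"{p} = '{iri}'" for p, iri in cfg.namespace_map]
    for name, section, id_key in (("Threads_Info", cfg.threads, "sioc:Thread"),
                                  ("Messages_Info", cfg.messages, "sioc:Post")):
        out += ["", f"[{name}]"]
        out.append(f"{id_key} = '{section.id_spec.xpath}'::id")
        out += [_property_line(p) for p in section.properties]
        out.append(f"nextPage = '{section.next_page_xpath}'")
    return "\n".join(out) + "\n"


def read_forum_list(text: str) -> list[str]:
    """Parse the forum-list input file: one absolute URL per line, ``#``
    comments and blank lines allowed."""
    urls = []
    for raw in text.splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            urls.append(line)
    return urls
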