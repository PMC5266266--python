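"""Page-level extraction: DOM building, XPath evaluation, record alignment,
date normalization and next-page resolution.

A board or thread page is parsed tolerantly (malformed HTML never aborts a
crawl).  The section's identifier XPath determines how many entities the page
holds; every other property XPath must yield exactly that many nodes, which
are then aligned index-to-index.  A property whose node list has a different
length is dropped for that page with a warning — identifiers stay
authoritative and the crawl continues.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from urllib.parse import urljoin

from lxml import etree, html as lxml_html

from .config import PropertySpec, SectionSpec

logger = logging.getLogger(__name__)

RDF_HTML_DATATYPE = "rdf:HTML"


@dataclass(frozen=True)
class AuthorCell:
    """Raw creator cell of a record: visible text plus the first anchor href
    (already resolved to an absolute URL), if any."""

    text: str
    href: str | None = None


@dataclass(frozen=True)
class EntityRecord:
    """One extracted thread or post.

    ``values`` is aligned with the section's property list; properties dropped
    on a page are simply absent.  ``container_id`` is the forum URL for a
    thread record and the thread URL for a post record.
    """

    entity_kind: str  # "thread" | "post"
    id_url: str
    container_id: str
    values: tuple[tuple[PropertySpec, str], ...] = ()
    author_cell: AuthorCell | None = None


class DomPage:
    """A fetched page parsed into an XPath-queryable DOM tree."""

    def __init__(self, url: str, body: str):
        self.url = url
        if not body or not body.strip():
            body = "<html></html>"
        self.tree = lxml_html.fromstring(body)

    def xpath(self, expression: str) -> list:
        return self.tree.xpath(expression)


def normalize_ws(text: str) -> str:
    """Collapse internal whitespace runs and strip the ends."""
    return re.sub(r"\s+", " ", text).strip()


def _node_text(node) -> str:
    if isinstance(node, str):
        return normalize_ws(str(node))
    return normalize_ws(node.text_content())


def _inner_markup(node) -> str:
    """The node's inner HTML, serialized verbatim (used for ``rdf:HTML``)."""
    if isinstance(node, str):
        return str(node)
    parts = [node.text or ""]
    for child in node:
        parts.append(etree.tostring(child, encoding="unicode"))
    return "".join(parts)


def _identifier_value(node, page_url: str) -> str:
    """Identifier resolution: attribute value if the XPath targeted an
    attribute, else the element's href if present, else its text."""
    if isinstance(node, str):
        value = str(node).strip()
    else:
        value = node.get("href") or _node_text(node)
    return urljoin(page_url, value)


def _first_anchor_href(node, page_url: str) -> str | None:
    if isinstance(node, str):
        return None
    if node.tag == "a" and node.get("href"):
        return urljoin(page_url, node.get("href"))
    anchors = node.xpath(".//a[@href]")
    if anchors:
        return urljoin(page_url, anchors[0].get("href"))
    return None


def extract_records(page: DomPage, section: SectionSpec, container_id: str,
                    entity_kind: str = "post") -> list[EntityRecord]:
    """Evaluate a section's XPaths against one page and align the node lists
    into :class:`EntityRecord` values.

    Zero identifier matches legitimately yield an empty list (an empty
    forum page).  Interleaved markup that matches no configured XPath — ads,
    navigation chrome — contributes nothing.
    """
    id_nodes = page.xpath(section.id_spec.xpath)
    n = len(id_nodes)
    if n == 0:
        return []
    ids = [_identifier_value(node, page.url) for node in id_nodes]

    columns: list[tuple[PropertySpec, list]] = []
    for spec in section.properties:
        nodes = page.xpath(spec.xpath)
        if len(nodes) != n:
            logger.warning(
                "property %s on %s matched %d nodes for %d identifiers; "
                "dropped for this page", spec.predicate, page.url,
                len(nodes), n)
            continue
        columns.append((spec, nodes))

    records = []
    for i, id_url in enumerate(ids):
        values = []
        author_cell = None
        for spec, nodes in columns:
            node = nodes[i]
            if spec.datatype == RDF_HTML_DATATYPE:
                value = _inner_markup(node)
            else:
                value = _node_text(node)
            values.append((spec, value))
            if spec.is_creator:
                author_cell = AuthorCell(text=_node_text(node),
                                         href=_first_anchor_href(node, page.url))
        records.append(EntityRecord(entity_kind=entity_kind, id_url=id_url,
                                    container_id=container_id,
                                    values=tuple(values),
                                    author_cell=author_cell))
    return records


def next_page_url(page: DomPage, next_xpath: str) -> str | None:
    """First match of the next-page XPath resolved against the page URL;
    ``None`` when nothing matches (last page of the container)."""
    matches = page.xpath(next_xpath)
    if not matches:
        return None
    node = matches[0]
    if isinstance(node, str):
        target = str(node).strip()
    else:
        target = node.get("href") or _node_text(node)
    if not target:
        return None
    return urljoin(page.url, target)


# --- date normalization -----------------------------------------------------

_DATE_TOKENS = {
    "d": r"\d{1,2}",
    "m": r"\d{1,2}",
    "Y": r"\d{4}",
    "H": r"\d{2}",
    "i": r"\d{2}",
    "s": r"\d{2}",
}


@dataclass
class DatePattern:
    """Compiled site-specific date pattern.

    Tokens ``d m Y H i s`` capture day, month, 4-digit year, hour, minute,
    second; ``*`` lazily skips any character run; ``?`` marks the preceding
    token or literal optional; a literal space matches any (possibly empty)
    whitespace run.  An empty pattern matches nothing, so raw values pass
    through untouched.
    """

    pattern: str
    _regex: re.Pattern | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.pattern:
            return
        fragments: list[str] = []
        seen: set[str] = set()
        for ch in self.pattern:
            if ch == "?":
                if fragments and not fragments[-1].endswith("?"):
                    last = fragments.pop()
                    if not (last.startswith("(") and last.endswith(")")):
                        last = f"(?:{last})"
                    fragments.append(last + "?")
                continue
            if ch == "*":
                fragments.append(".*?")
            elif ch in _DATE_TOKENS and ch not in seen:
                seen.add(ch)
                fragments.append(f"(?P<{ch}>{_DATE_TOKENS[ch]})")
            elif ch == " ":
                fragments.append(r"\s*")
            else:
                fragments.append(re.escape(ch))
        self._regex = re.compile("".join(fragments))

    def match(self, raw: str) -> datetime | None:
        """Return the captured timestamp, or ``None`` on no match, missing
        date parts, or an invalid calendar date."""
        if self._regex is None:
            return None
        m = self._regex.fullmatch(raw.strip())
        if not m:
            return None
        parts = m.groupdict()
        if any(parts.get(k) is None for k in ("d", "m", "Y")):
            return None
        try:
            return datetime(
                int(parts["Y"]), int(parts["m"]), int(parts["d"]),
                int(parts.get("H") or 0), int(parts.get("i") or 0),
                int(parts.get("s") or 0))
        except ValueError:
            return None


def normalize_date(raw: str, pattern: DatePattern | str) -> str:
    """Standardize *raw* to ``YYYY-MM-DDTHH:MM:SS`` when the pattern fully
    captures it; otherwise return *raw* unchanged (the caller emits the value
    untyped in that case)."""
    if isinstance(pattern, str):
        pattern = DatePattern(pattern)
    dt = pattern.match(raw)
    if dt is None:
        return raw
    return dt.strftime("%Y-%m-%dT%H:%M:%S")
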