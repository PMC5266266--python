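"""Deterministic synthetic forum sites with known ground truth.

The generator builds a small French-flavored forum site — boards holding
paginated thread lists, threads holding paginated post lists, "Réponses"/
"Affichages" count columns, ``>`` next-page anchors — entirely offline.
Ground truth (records and the expected pre-anonymization graph) is
constructed *first* and the HTML is rendered from it, so extraction results
can be compared for exact equality.  Author cells realize all three
classes: profile links (known), bare nicknames (unknown) and site-wide
marker strings (invalid).  Optional ad blocks share no attributes with the
configured XPaths, and a ``shared_thread`` flag lists one thread under two
boards with the same URL.
"""

from __future__ import annotations

import math
import random
import threading
import time as _time
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Callable

from .config import ScrapeConfig, parse_config
from .extract import AuthorCell, EntityRecord
from .fetch import FetchError, strip_fragment
from .ntriples import Graph
from .semantics import build_graph

DEFAULT_INVALID_MARKERS = ("Unknown", "Deleted profile")

_DRUGS = ("Doliprane", "Levothyrox", "Ibuprofene", "Tramadol", "Amoxicilline",
          "Paroxetine", "Metformine", "Crestor")
_SYMPTOMS = ("des vertiges", "une eruption cutanee", "des nausees",
             "une fatigue intense", "des maux de tete", "des palpitations")
_PHRASES = ("Depuis que je prends", "Mon medecin m'a prescrit",
            "J'ai arrete", "Je prends depuis deux mois")


@dataclass(frozen=True)
class FixtureParams:
    seed: int = 42
    n_forums: int = 2
    threads_per_forum: int = 3
    posts_per_thread: int = 4
    threads_per_page: int = 2
    posts_per_page: int = 2
    n_known: int = 3
    n_unknown: int = 2
    n_invalid: int = 1
    noise: float = 0.3
    shared_thread: bool = False
    base_url: str = "http://forum.example"
    invalid_markers: tuple[str, ...] = DEFAULT_INVALID_MARKERS

    def __post_init__(self):
        if min(self.n_forums, self.threads_per_forum, self.posts_per_thread,
               self.n_known, self.n_unknown, self.n_invalid) < 0:
            raise ValueError("counts must be >= 0")
        if min(self.threads_per_page, self.posts_per_page) < 1:
            raise ValueError("pagination sizes must be >= 1")


@dataclass
class SiteFixture:
    params: FixtureParams
    pages: dict[str, str]
    config_text: str
    config: ScrapeConfig
    forum_list: list[str]
    truth_threads: list[EntityRecord]
    truth_posts: list[EntityRecord]
    truth_graph: Graph
    site_id: str

    @property
    def truth_records(self) -> list[EntityRecord]:
        return [*self.truth_threads, *self.truth_posts]


@dataclass(frozen=True)
class _Author:
    classification: str  # "known" | "unknown" | "invalid"
    nickname: str
    profile_href: str | None = None  # root-relative, as rendered in HTML

    def cell_html(self) -> str:
        if self.classification == "known":
            return f'<a href="{self.profile_href}">{self.nickname}</a>'
        return self.nickname


_CONFIG_TEMPLATE = """\
proxy = ''
dateFormat = '* d-m-Y * H:i:s'
invalidAuthors = '{invalid}'

[Files_Info]
forumsInputList = 'forums.txt'
logFileName = 'visited.log'
rdfFileName = 'site.n3'

[Threads_Info]
sioc:Thread = '//td[@class = 'threadCase1']/a[1]/@href'::id
dc:creator = '//td[@class = 'threadCase2']'
dc:title = '//td[@class = 'threadCase1']/a[1]'
sioc:num_replies = '//td[@class = 'threadCase3']'::xsd:integer
sioc:num_views = '//td[@class = 'threadCase4']'::xsd:integer
nextPage = '//div[@class = 'paging']/a[@class = 'next']'

[Messages_Info]
sioc:Post = '//td[@class = 'messCase1']/div[1]/a[1]/@href'::id
dc:creator = '//td[@class = 'messCase1']/div[2]'
dc:date = '//td[@class = 'messCase2']/div[1]'::xsd:dateTime
sioc:content = '//td[@class = 'messCase2']/div[2]'::fr
nie:htmlContent = '//td[@class = 'messCase2']/div[2]'::rdf:HTML
nextPage = '//div[@class = 'paging']/a[@class = 'next']'
"""


def _nickname(rng: random.Random, taken: set[str]) -> str:
    consonants, vowels = "bcdfglmnprstv", "aeiou"
    while True:
        nick = "".join(rng.choice(consonants) + rng.choice(vowels)
                       for _ in range(3)) + str(rng.randint(10, 99))
        if nick not in taken:
            taken.add(nick)
            return nick


def _author_pool(params: FixtureParams, rng: random.Random) -> list[_Author]:
    taken: set[str] = set()
    pool: list[_Author] = []
    for _ in range(params.n_known):
        nick = _nickname(rng, taken)
        pool.append(_Author("known", nick, f"/profil/{nick}"))
    for _ in range(params.n_unknown):
        pool.append(_Author("unknown", _nickname(rng, taken)))
    for i in range(params.n_invalid):
        marker = params.invalid_markers[i % len(params.invalid_markers)]
        pool.append(_Author("invalid", marker))
    rng.shuffle(pool)
    return pool


def _content(rng: random.Random) -> tuple[str, str]:
    """(plain text, inner HTML) for one post body."""
    drug = rng.choice(_DRUGS)
    phrase, symptom = rng.choice(_PHRASES), rng.choice(_SYMPTOMS)
    if rng.random() < 0.5:
        html = f"{phrase} <b>{drug}</b> et j'ai {symptom}."
    else:
        html = f"{phrase} {drug} et j'ai {symptom}."
    text = html.replace("<b>", "").replace("</b>", "")
    return text, html


def _paginate(items: list, per_page: int) -> list[list]:
    n_pages = max(1, math.ceil(len(items) / per_page))
    return [items[i * per_page:(i + 1) * per_page] for i in range(n_pages)]


def _ad_block(rng: random.Random) -> str:
    return ('<div class="ad"><p>Publicite - <a href="http://ads.invalid/c%d">'
            'cliquez ici</a></p></div>' % rng.randint(100, 999))


def generate_site(params: FixtureParams) -> SiteFixture:
    """Build a complete synthetic site: pages, matching configuration,
    board list, ground-truth records and the expected graph.  Byte-identical
    for a given parameter set."""
    rng = random.Random(params.seed)
    base = params.base_url.rstrip("/")
    config_text = _CONFIG_TEMPLATE.format(
        invalid=", ".join(params.invalid_markers))
    cfg = parse_config(config_text)
    pool = _author_pool(params, rng)

    def author_at(i: int) -> _Author:
        return pool[i % len(pool)] if pool else _Author("invalid", "Unknown")

    # --- ground truth ------------------------------------------------------
    forums = [f"{base}/forum{f}" for f in range(1, params.n_forums + 1)]
    clock = datetime(2016, 3, 5, 9, 14, 0)
    author_counter = 0

    @dataclass
    class _Thread:
        url: str
        href: str
        title: str
        author: _Author
        replies: str
        views: str
        posts: list

    threads_by_forum: dict[str, list[_Thread]] = {}
    all_threads: list[_Thread] = []
    for f, forum_url in enumerate(forums, start=1):
        rows: list[_Thread] = []
        for t in range(1, params.threads_per_forum + 1):
            author = author_at(author_counter)
            author_counter += 1
            drug = rng.choice(_DRUGS)
            thread = _Thread(
                url=f"{base}/thread{f}_{t}", href=f"/thread{f}_{t}",
                title=f"Effets secondaires du {drug} ({f}-{t})",
                author=author,
                replies=str(rng.randint(0, 40)), views=str(rng.randint(5, 900)),
                posts=[])
            rows.append(thread)
            all_threads.append(thread)
        threads_by_forum[forum_url] = rows
    if params.shared_thread and params.n_forums >= 2:
        threads_by_forum[forums[1]].append(threads_by_forum[forums[0]][0])

    for thread in all_threads:
        f, t = thread.url.rsplit("thread", 1)[1].split("_")
        for p in range(1, params.posts_per_thread + 1):
            author = author_at(author_counter)
            author_counter += 1
            clock += timedelta(minutes=17)
            date_str = (f"le {clock.day:02d}-{clock.month:02d}-{clock.year} "
                        f"a {clock.hour:02d}:{clock.minute:02d}:"
                        f"{clock.second:02d}")
            text, html = _content(rng)
            thread.posts.append({
                "href": f"/post{f}_{t}_{p}", "url": f"{base}/post{f}_{t}_{p}",
                "author": author, "date": date_str,
                "text": text, "html": html, "label": f"#{p}",
            })

    # Records, in the order the crawler meets them: per forum, the listing
    # pages in order; then each thread's post pages.  A shared thread yields
    # a second thread record (under its second forum) but its posts only once.
    def author_cell(author: _Author) -> AuthorCell:
        href = (f"{base}{author.profile_href}"
                if author.profile_href else None)
        return AuthorCell(text=author.nickname, href=href)

    tprops = {p.predicate: p for p in cfg.threads.properties}
    pprops = {p.predicate: p for p in cfg.messages.properties}

    truth_threads: list[EntityRecord] = []
    seen_thread_urls: set[str] = set()
    posts_order: list[_Thread] = []
    for forum_url in forums:
        for thread in threads_by_forum[forum_url]:
            truth_threads.append(EntityRecord(
                entity_kind="thread", id_url=thread.url,
                container_id=forum_url,
                values=(
                    (tprops["dc:creator"], thread.author.nickname),
                    (tprops["dc:title"], thread.title),
                    (tprops["sioc:num_replies"], thread.replies),
                    (tprops["sioc:num_views"], thread.views),
                ),
                author_cell=author_cell(thread.author)))
            if thread.url not in seen_thread_urls:
                seen_thread_urls.add(thread.url)
                posts_order.append(thread)

    truth_posts: list[EntityRecord] = []
    for thread in posts_order:
        for post in thread.posts:
            truth_posts.append(EntityRecord(
                entity_kind="post", id_url=post["url"],
                container_id=thread.url,
                values=(
                    (pprops["dc:creator"], post["author"].nickname),
                    (pprops["dc:date"], post["date"]),
                    (pprops["sioc:content"], post["text"]),
                    (pprops["nie:htmlContent"], post["html"]),
                ),
                author_cell=author_cell(post["author"])))

    # --- HTML rendering -----------------------------------------------------
    pages: dict[str, str] = {}

    def render(title: str, body_rows: str, next_href: str | None) -> str:
        ad_top = _ad_block(rng) if rng.random() < params.noise else ""
        ad_bottom = _ad_block(rng) if rng.random() < params.noise else ""
        paging = (f'<div class="paging"><a class="next" href="{next_href}">'
                  '&gt;</a></div>' if next_href else '<div class="paging">'
                  '</div>')
        return (f"<html><head><title>{title}</title></head><body>"
                f"{ad_top}{body_rows}{paging}{ad_bottom}</body></html>")

    for f, forum_url in enumerate(forums, start=1):
        chunks = _paginate(threads_by_forum[forum_url],
                           params.threads_per_page)
        for k, chunk in enumerate(chunks, start=1):
            url = forum_url if k == 1 else f"{forum_url}?page={k}"
            rows = ["<table class=\"threadlist\">",
                    "<tr><th>Sujet</th><th>Auteur</th><th>Reponses</th>"
                    "<th>Affichages</th></tr>"]
            for thread in chunk:
                rows.append(
                    '<tr class="threadrow">'
                    f'<td class="threadCase1"><a href="{thread.href}">'
                    f'{thread.title}</a></td>'
                    f'<td class="threadCase2">{thread.author.cell_html()}</td>'
                    f'<td class="threadCase3">{thread.replies}</td>'
                    f'<td class="threadCase4">{thread.views}</td></tr>')
            rows.append("</table>")
            next_href = (f"/forum{f}?page={k + 1}" if k < len(chunks)
                         else None)
            pages[url] = render(f"Forum {f}", "".join(rows), next_href)

    for thread in posts_order:
        chunks = _paginate(thread.posts, params.posts_per_page)
        path = thread.href
        for k, chunk in enumerate(chunks, start=1):
            url = thread.url if k == 1 else f"{thread.url}?page={k}"
            rows = ['<table class="posts">']
            for post in chunk:
                rows.append(
                    '<tr class="postrow">'
                    '<td class="messCase1">'
                    f'<div class="permalink"><a href="{post["href"]}">'
                    f'{post["label"]}</a></div>'
                    f'<div class="author">{post["author"].cell_html()}</div>'
                    '</td>'
                    '<td class="messCase2">'
                    f'<div class="date">{post["date"]}</div>'
                    f'<div class="content">{post["html"]}</div>'
                    '</td></tr>')
            rows.append("</table>")
            next_href = f"{path}?page={k + 1}" if k < len(chunks) else None
            pages[url] = render(thread.title, "".join(rows), next_href)

    site_id = base
    truth_graph = build_graph(truth_threads, truth_posts, site_id, cfg)
    return SiteFixture(params=params, pages=pages, config_text=config_text,
                       config=cfg, forum_list=forums,
                       truth_threads=truth_threads, truth_posts=truth_posts,
                       truth_graph=truth_graph, site_id=site_id)


class FixtureBackend:
    """Fetch backend resolving URLs from a :class:`SiteFixture`.

    Counts requests per URL and records monotonic request timestamps, which
    feed the dedup and throttle assertions.  Unknown URLs raise a simulated
    404 :class:`FetchError`.
    """

    def __init__(self, fixture: SiteFixture,
                 clock: Callable[[], float] = _time.monotonic):
        self.pages = fixture.pages
        self.request_counts: dict[str, int] = {}
        self.timestamps: list[float] = []
        self._clock = clock

    def __call__(self, url: str) -> str:
        url = strip_fragment(url)
        self.request_counts[url] = self.request_counts.get(url, 0) + 1
        self.timestamps.append(self._clock())
        body = self.pages.get(url)
        if body is None:
            raise FetchError(url, "HTTP status 404")
        return body


def fixture_backend(fixture: SiteFixture, **kwargs) -> FixtureBackend:
    return FixtureBackend(fixture, **kwargs)


class _FixtureHandler(BaseHTTPRequestHandler):
    fixture: SiteFixture = None  # set on the subclass

    def do_GET(self):  # noqa: N802 - http.server API
        url = f"{self.fixture.site_id}{self.path}"
        body = self.fixture.pages.get(strip_fragment(url))
        if body is None:
            self.send_error(404)
            return
        payload = body.encode("utf-8")
        self.send_response(200)
        self.send_header("Content-Type", "text/html; charset=utf-8")
        self.send_header("Content-Length", str(len(payload)))
        self.end_headers()
        self.wfile.write(payload)

    def log_message(self, *args):  # silence request logging
        pass


def serve_site(params: FixtureParams,
               host: str = "127.0.0.1") -> tuple[ThreadingHTTPServer,
                                                 SiteFixture]:
    """Regenerate the fixture under a live local-HTTP base URL and serve it.

    Returns the running server (call ``shutdown()`` when done) and the
    fixture whose page URLs point at it.
    """
    server = ThreadingHTTPServer((host, 0), _FixtureHandler)
    base_url = f"http://{host}:{server.server_port}"
    fixture = generate_site(replace(params, base_url=base_url))

    class Handler(_FixtureHandler):
        pass

    Handler.fixture = fixture
    server.RequestHandlerClass = Handler
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return server, fixture
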