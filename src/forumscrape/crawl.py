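"""Crawl orchestration: boards → thread URLs → posts, with page-flipping,
per-run deduplication and a persistent completed-URL log.

The crawl mimics a reader's navigation: for each configured board, walk its
thread-list pages following the "next page" link, collect the thread
identifier URLs, then scrape every post page of each thread before moving to
the next board.  A thread listed under several boards is crawled once per
run.  Every page whose records were extracted is appended to the completed
log; together with the page cache this guarantees that a crawl interrupted
and restarted re-reads completed pages from the cache with zero further
network requests and converges on the same record multiset.
"""

from __future__ import annotations

import logging
from pathlib import Path
from urllib.parse import urlsplit

from .config import ScrapeConfig, SectionSpec, read_forum_list
from .extract import DomPage, EntityRecord, extract_records, next_page_url
from .fetch import FetchError, Fetcher

logger = logging.getLogger(__name__)


class CrawlState:
    """Per-run visited set plus the persistent completed-URL log.

    The in-run set stops duplicate scraping (shared threads, next-page
    cycles).  The log file — one URL per line, append-only — records pages
    whose extraction finished; it survives restarts, marking which URLs are
    safely resolvable from the cache.  A page interrupted mid-extraction is
    absent from the log and therefore retried.
    """

    def __init__(self, log_path: str | Path | None = None):
        self.log_path = Path(log_path) if log_path is not None else None
        self.completed: set[str] = set()
        self.visited_this_run: set[str] = set()
        if self.log_path is not None and self.log_path.exists():
            with open(self.log_path, encoding="utf-8") as fh:
                self.completed.update(line.strip() for line in fh
                                      if line.strip())

    def is_visited(self, url: str) -> bool:
        return url in self.visited_this_run

    def mark_visited(self, url: str) -> None:
        self.visited_this_run.add(url)
        if url not in self.completed:
            self.completed.add(url)
            if self.log_path is not None:
                with open(self.log_path, "a", encoding="utf-8") as fh:
                    fh.write(url + "\n")
                    fh.flush()


def crawl_container(start_url: str, section: SectionSpec, container_id: str,
                    fetcher: Fetcher, state: CrawlState,
                    entity_kind: str = "post") -> list[EntityRecord]:
    """Walk one container (a board's thread list or a thread's post list)
    across all its pages.

    Stops when the next-page XPath yields no match or points at a page
    already visited this run (loop guard).  A page that fails to fetch is
    logged and ends the walk for this container — without its body the next
    link is unknowable — but the crawl as a whole continues.
    """
    records: list[EntityRecord] = []
    url: str | None = start_url
    while url is not None:
        if state.is_visited(url):
            break
        try:
            page_fetch = fetcher.fetch(url)
        except FetchError as exc:
            logger.warning("skipping failed page: %s", exc)
            break
        page = DomPage(url, page_fetch.body)
        records.extend(extract_records(page, section, container_id,
                                       entity_kind=entity_kind))
        state.mark_visited(url)
        url = next_page_url(page, section.next_page_xpath)
    return records


def site_id_of(url: str) -> str:
    parts = urlsplit(url)
    return f"{parts.scheme}://{parts.netloc}"


def run_scrape(cfg: ScrapeConfig, fetcher: Fetcher, state: CrawlState,
               forum_urls: list[str] | None = None,
               ) -> tuple[list[EntityRecord], list[EntityRecord], str]:
    """Scrape every configured board and its threads.

    Returns ``(thread_records, post_records, site_id)`` where *site_id* is
    the scheme+host of the first board URL.  With ``forum_urls=None`` the
    board list is read from ``cfg.forums_input_list``.
    """
    if forum_urls is None:
        with open(cfg.forums_input_list, encoding="utf-8") as fh:
            forum_urls = read_forum_list(fh.read())
    if not forum_urls:
        logger.warning("empty forum list; nothing to scrape")
        return [], [], ""

    site_id = site_id_of(forum_urls[0])
    thread_records: list[EntityRecord] = []
    post_records: list[EntityRecord] = []

    for forum_url in forum_urls:
        if state.is_visited(forum_url):
            continue
        threads = crawl_container(forum_url, cfg.threads, forum_url,
                                  fetcher, state, entity_kind="thread")
        thread_records.extend(threads)
        pending: list[str] = []
        for record in threads:
            if record.id_url not in pending:
                pending.append(record.id_url)
        for thread_url in pending:
            if state.is_visited(thread_url):
                continue  # shared thread already scraped this run
            post_records.extend(
                crawl_container(thread_url, cfg.messages, thread_url,
                                fetcher, state, entity_kind="post"))

    return thread_records, post_records, site_id
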