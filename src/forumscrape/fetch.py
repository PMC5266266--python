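"""Polite page retrieval: cache-first fetching with a minimum inter-request
delay.

The original deployment ran a separate caching proxy process; here the same
contract lives in-process.  A cache hit is returned immediately with no
network activity and no delay; a miss waits out the remainder of the active
delay floor (0.330 s by default, 2 s inside the configured busy window),
performs exactly one request through a pluggable backend, and stores the body.
The cache is an append-only JSON-lines file keyed on the exact URL (fragment
stripped), so a restarted process resolves every previously fetched page
without touching the network.
"""

from __future__ import annotations

import json
import logging
import time as _time
import urllib.error
import urllib.request
from dataclasses import dataclass
from datetime import datetime, time as dtime
from pathlib import Path
from typing import Callable

from .config import ScrapeConfig

logger = logging.getLogger(__name__)

DEFAULT_USER_AGENT = "forumscrape/0.1 (polite research crawler)"
DEFAULT_TIMEOUT_S = 30.0


class FetchError(RuntimeError):
    """A page could not be retrieved; carries the URL and the cause."""

    def __init__(self, url: str, cause: str):
        super().__init__(f"fetch failed for {url}: {cause}")
        self.url = url
        self.cause = cause


@dataclass(frozen=True)
class PageFetch:
    url: str
    body: str
    origin: str  # "network" | "cache"
    fetched_at: float


def strip_fragment(url: str) -> str:
    return url.split("#", 1)[0]


class CacheStore:
    """Persistent URL → body map backed by an append-only JSONL file.

    ``path=None`` gives a purely in-memory store with the same interface.
    Insertion-only during a run; a later ``put`` for an existing URL is
    ignored (the first retrieved copy wins).
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._index: dict[str, str] = {}
        if self.path is not None and self.path.exists():
            with open(self.path, encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        rec = json.loads(line)
                        self._index.setdefault(rec["url"], rec["body"])

    def __contains__(self, url: str) -> bool:
        return strip_fragment(url) in self._index

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, url: str) -> str | None:
        return self._index.get(strip_fragment(url))

    def put(self, url: str, body: str) -> None:
        url = strip_fragment(url)
        if url in self._index:
            return
        self._index[url] = body
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps({"url": url, "body": body},
                                    ensure_ascii=False) + "\n")
                fh.flush()


def in_busy_window(now: dtime, window: tuple[dtime, dtime] | None) -> bool:
    if window is None:
        return False
    start, end = window
    if start <= end:
        return start <= now < end
    return now >= start or now < end  # window wrapping midnight


def required_delay(now: datetime, last_network_request: datetime | None,
                   cfg: ScrapeConfig) -> float:
    """Seconds to wait before the next network request may start.

    The active floor is ``busy_delay_s`` when *now* falls inside the busy
    window, else ``min_delay_s``; the elapsed gap since the last network
    request is credited.  No previous request means no wait.
    """
    if last_network_request is None:
        return 0.0
    floor = (cfg.busy_delay_s if in_busy_window(now.time(), cfg.busy_window)
             else cfg.min_delay_s)
    gap = (now - last_network_request).total_seconds()
    return max(0.0, floor - gap)


Backend = Callable[[str], str]


class Fetcher:
    """Cache-first page retriever enforcing the inter-request delay.

    ``backend`` maps a URL to an HTML body (raising :class:`FetchError` on
    failure); tests inject fixture resolvers, live crawls use
    :func:`http_backend`.  ``clock``/``sleep``/``local_now`` are injectable
    for deterministic throttle tests.
    """

    def __init__(self, cache: CacheStore, cfg: ScrapeConfig, backend: Backend,
                 *, clock: Callable[[], float] = _time.monotonic,
                 sleep: Callable[[float], None] = _time.sleep,
                 local_now: Callable[[], datetime] = datetime.now):
        self.cache = cache
        self.cfg = cfg
        self.backend = backend
        self._clock = clock
        self._sleep = sleep
        self._local_now = local_now
        self._last_request_mono: float | None = None
        #: Monotonic start times of every network request this session.
        self.network_times: list[float] = []

    def _wait(self) -> None:
        if self._last_request_mono is None:
            return
        now = self._local_now()
        floor = (self.cfg.busy_delay_s
                 if in_busy_window(now.time(), self.cfg.busy_window)
                 else self.cfg.min_delay_s)
        gap = self._clock() - self._last_request_mono
        wait = max(0.0, floor - gap)
        if wait > 0:
            self._sleep(wait)

    def fetch(self, url: str) -> PageFetch:
        """Return the page at *url*, from cache when possible."""
        cached = self.cache.lookup(url)
        if cached is not None:
            return PageFetch(url=url, body=cached, origin="cache",
                             fetched_at=self._clock())
        self._wait()
        start = self._clock()
        self._last_request_mono = start
        self.network_times.append(start)
        body = self.backend(url)
        self.cache.put(url, body)
        return PageFetch(url=url, body=body, origin="network",
                         fetched_at=start)


def http_backend(proxy: str = "", user_agent: str = DEFAULT_USER_AGENT,
                 timeout: float = DEFAULT_TIMEOUT_S) -> Backend:
    """Live HTTP backend over :mod:`urllib`; one request per call, no
    automatic retries (a failed URL is the caller's to skip and log)."""
    handlers = []
    if proxy:
        handlers.append(urllib.request.ProxyHandler({"http": proxy,
                                                     "https": proxy}))
    opener = urllib.request.build_opener(*handlers)

    def backend(url: str) -> str:
        request = urllib.request.Request(url,
                                         headers={"User-Agent": user_agent})
        try:
            with opener.open(request, timeout=timeout) as response:
                status = getattr(response, "status", 200)
                if not 200 <= status < 300:
                    raise FetchError(url, f"HTTP status {status}")
                charset = response.headers.get_content_charset() or "utf-8"
                return response.read().decode(charset, errors="replace")
        except urllib.error.URLError as exc:
            raise FetchError(url, str(exc)) from exc

    return backend
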