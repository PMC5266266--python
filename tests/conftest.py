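import dataclasses

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")

from forumscrape import CacheStore, CrawlState, Fetcher, run_scrape
from forumscrape.fixture import FixtureParams, fixture_backend, generate_site

LISTING_STYLE_CONFIG = """\
proxy = ''
dateFormat = '* * d-m-Y*?? H: i: s??'
[Files_Info]
forumsInputList = 'configFiles/ForumsLists/Doctissimo_Forums.txt'
logFileName = '../logs/Doctissimo_'
rdfFileName = '../download/Doctissimo/Doctissimo_Graph. n3'
[Threads_Info]
sioc: Thread = '//*[starts-with(@id, 'url_topic_')]':: id
dc: creator = '//*[@id = 'block_topics_list']/ tr/ td [6]'
dc: title = '//*[starts-with(@id, 'url_topic_')]'
sioc: num_replies = '//*[@id = 'block_topics_list']/ tr/ td [7]':: xsd: integer
sioc: num_views = '//*[@id = 'block_topics_list']/ tr/ td [8]':: xsd: integer
nextPage = '//*[@id = 'block_topics_list']/ tr [2]/ td / div [1]/ div [1]/ a'
[Messages_Info]
sioc: Post = '//td[@class = 'messCase1']/ div [1]/ a[1]/@href':: id
dc: creator = '//td[@class = 'messCase1']/ div [2]'
dc: date = '//td[@class = 'messCase2']/ div [1]/ div [1]':: xsd: dateTime
sioc: content = '//*[starts-with(@id, 'para')]':: fr
nie: htmlContent = '//*[starts-with(@id, 'para')]':: rdf: HTML
nextPage = '//*[@id = 'topic']/ table [1]/ tr [2]/ td/ div [1]/ div [1]/ a [1]'
"""


def zero_delay(cfg):
    """Throttle-free copy of a config, for crawl logic tests."""
    return dataclasses.replace(cfg, min_delay_s=0.0, busy_delay_s=0.0)


def scrape_fixture(fixture, *, cache=None, state=None, backend=None):
    """Run a full throttle-free scrape over an in-memory fixture."""
    cfg = zero_delay(fixture.config)
    backend = backend or fixture_backend(fixture)
    fetcher = Fetcher(cache or CacheStore(), cfg, backend)
    threads, posts, site_id = run_scrape(cfg, fetcher, state or CrawlState(),
                                         forum_urls=fixture.forum_list)
    return threads, posts, site_id, backend


@pytest.fixture(scope="session")
def site():
    """Default synthetic site: 2 forums x 3 threads x 4 posts, no noise."""
    return generate_site(FixtureParams(seed=42, noise=0.0))


@pytest.fixture(scope="session")
def noisy_shared_site():
    """Site with ad noise and one thread listed under both forums."""
    return generate_site(FixtureParams(seed=7, shared_thread=True, noise=0.4))
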