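import datetime

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from hospmine.corpus import Message, Thread
from hospmine.lexicons import (
    FactorKeywordEntry,
    FactorLexicon,
    HospitalEntry,
    HospitalLexicon,
    SentimentLexicon,
)
from hospmine.synthetic import default_lexicons


@pytest.fixture(scope="session")
def bundled_lexicons():
    """The shipped stand-in lexicons (hospitals, factors, sentiment)."""
    return default_lexicons()


@pytest.fixture()
def tiny_hospitals() -> HospitalLexicon:
    return HospitalLexicon(
        [
            HospitalEntry("H1", "Alpha Clinic", "Seoul", frozenset({"Alpha Clinic", "alfa"})),
            HospitalEntry("H2", "Beta Care Center", "Busan", frozenset({"Beta Care Center", "beta care"})),
            HospitalEntry("H3", "Gamma Hospital", "Seoul", frozenset({"Gamma Hospital"})),
        ]
    )


@pytest.fixture()
def tiny_factors() -> FactorLexicon:
    return FactorLexicon(
        [
            FactorKeywordEntry("waiting time", "process", "f15", frozenset({"long wait"})),
            FactorKeywordEntry("waiting", "process", "f15"),
            FactorKeywordEntry("kind nurse", "service", "f1"),
            FactorKeywordEntry("famous tradition", "popularity", "e6"),
        ]
    )


@pytest.fixture()
def tiny_sentiment() -> SentimentLexicon:
    return SentimentLexicon(
        positive_cues=frozenset({"recommend", "satisfied"}),
        negative_cues=frozenset({"disappointed", "never again"}),
    )


def make_message(
    text: str,
    message_id: str = "m1",
    thread_id: str = "t1",
    region: str = "Seoul",
    posted: str = "2009-06-01",
) -> Message:
    return Message(
        message_id=message_id,
        thread_id=thread_id,
        region=region,
        posted_at=datetime.date.fromisoformat(posted),
        raw_text=text,
    )


def make_thread(thread_id: str, message_ids, region: str = "Seoul", title: str = "") -> Thread:
    return Thread(thread_id=thread_id, title=title, region=region, message_ids=list(message_ids))
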