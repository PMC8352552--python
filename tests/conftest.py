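import datetime
import json
import logging

import pytest

from semshift.corpus import Document, assign_windows

# the preset-mismatch warning is intentional; keep test output readable
logging.getLogger("semshift.novelty").setLevel(logging.ERROR)


def make_doc(doc_id, title, year, month=6, day=15, abstract=None):
    return Document(doc_id=doc_id, title=title, abstract=abstract,
                    date=datetime.date(year, month, day))


@pytest.fixture
def toy_corpus():
    """Four yearly windows of hand-countable titles (leprosy theme)."""
    docs = [
        make_doc("a1", "leprosy therapy", 1980),
        make_doc("a2", "leprosy relapse", 1980),
        make_doc("b1", "leprosy nerve damage", 1981),
        make_doc("b2", "nerve biopsy study", 1981),
        make_doc("c1", "multidrug therapy trial", 1982),
        make_doc("c2", "leprosy multidrug therapy", 1982),
        make_doc("d1", "multidrug therapy outcome", 1983),
        make_doc("d2", "therapy outcome survey", 1983),
    ]
    return assign_windows(docs, granularity="year")


@pytest.fixture
def jsonl_writer(tmp_path):
    def write(records, name="docs.jsonl"):
        p = tmp_path / name
        with open(p, "w") as fh:
            for r in records:
                fh.write(json.dumps(r) + "\n")
        return p

    return write
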