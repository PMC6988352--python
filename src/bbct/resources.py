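"""Access to the packaged word lists, lexicons, and worked-example documents."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path


def data_path(*parts: str) -> Path:
    return Path(resources.files("bbct").joinpath("data", *parts))  # type: ignore[arg-type]


def read_data_text(*parts: str) -> str:
    return data_path(*parts).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def wordlist(name: str) -> frozenset[str]:
    """A packaged one-word-per-line list, lower-cased, comments/# blanks dropped."""
    words = set()
    for line in read_data_text(name).splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


@lru_cache(maxsize=None)
def nominalization_table() -> dict[str, str]:
    """Derivationally related noun for verb/adjective lemmas (lemma -> noun)."""
    table = {}
    for line in read_data_text("nominalizations.tsv").splitlines():
        line = line.strip()
        if not line:
            continue
        lemma, noun = line.split("\t")
        table[lemma.lower()] = noun.lower()
    return table
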