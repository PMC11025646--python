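"""Corpus characterization and benchmark-contamination checks.

Tokenization follows Penn-Treebank-style conventions as applied here:
contractions are split at the apostrophe with the apostrophe discarded
("they're" -> they + re), punctuation marks are emitted as separate tokens,
and case is preserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["CorpusStats", "ptb_tokenize", "ngram_stats", "contamination_check"]

# word characters (underscore included by \w) or single non-space,
# non-word, non-apostrophe marks; apostrophes act as discarded separators
_TOKEN_RE = re.compile(r"\w+|[^\w\s'’]", re.UNICODE)


def ptb_tokenize(text: str) -> list[str]:
    """Split text into word and punctuation tokens; contractions split at the
    (discarded) apostrophe. No lowercasing."""
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class CorpusStats:
    total_tokens: int
    unique_ngrams: dict  # n -> count of distinct n-grams

    @property
    def unique_token_fraction(self) -> float:
        """Percentage of distinct tokens relative to total tokens."""
        if self.total_tokens == 0:
            return 0.0
        return 100.0 * self.unique_ngrams[1] / self.total_tokens


def ngram_stats(tokens: list, max_n: int = 4) -> CorpusStats:
    """Exact distinct n-gram counts for n = 1..max_n by window enumeration."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    tokens = list(tokens)
    counts = {}
    for n in range(1, max_n + 1):
        counts[n] = len({tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)})
    return CorpusStats(total_tokens=len(tokens), unique_ngrams=counts)


def _contains_subsequence(haystack: list, needle: list) -> bool:
    if not needle or len(needle) > len(haystack):
        return False
    first = needle[0]
    n = len(needle)
    for i in range(len(haystack) - n + 1):
        if haystack[i] == first and haystack[i : i + n] == needle:
            return True
    return False


def contamination_check(benchmark_sentences: list[str], corpus_tokens: list) -> list[str]:
    """Sentences whose tokenized form occurs verbatim as a contiguous token
    subsequence of the corpus (exact, case-sensitive matching)."""
    corpus_tokens = list(corpus_tokens)
    matched = []
    for sentence in benchmark_sentences:
        needle = ptb_tokenize(sentence)
        if needle and _contains_subsequence(corpus_tokens, needle):
            matched.append(sentence)
    return matched


class Vocabulary:
    """Token-string <-> integer-id mapping for plain-text corpora.

    Built in order of first appearance; unknown tokens at encode time raise
    unless an ``<unk>`` token was reserved.
    """

    def __init__(self, tokens=None, add_unk: bool = True):
        self.id_of: dict = {}
        self.token_of: list = []
        if add_unk:
            self._add("<unk>")
        for t in tokens or []:
            if t not in self.id_of:
                self._add(t)

    def _add(self, token) -> int:
        self.id_of[token] = len(self.token_of)
        self.token_of.append(token)
        return self.id_of[token]

    def __len__(self) -> int:
        return len(self.token_of)

    def encode(self, tokens) -> "list[int]":
        unk = self.id_of.get("<unk>")
        out = []
        for t in tokens:
            i = self.id_of.get(t, unk)
            if i is None:
                raise KeyError(f"token {t!r} not in vocabulary")
            out.append(i)
        return out
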