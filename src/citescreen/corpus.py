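"""Citation corpora: parsing, tokenisation, vocabulary and TF-IDF weighting.

A corpus is an ordered collection of citations (id, title, abstract,
optional binary eligibility label).  Text from title and abstract is pooled
into a single bag of words per citation; the TF-IDF matrix weights the term
count of word ``w`` in citation ``d`` by ``log(1/f_w)`` where ``f_w`` is the
fraction of citations containing ``w``.  Document frequencies are computed
over the full pool (labelled and unlabelled citations alike), matching the
pool-based screening setting where the complete citation list is available
up front.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Citation",
    "Corpus",
    "Vocabulary",
    "CorpusFormatError",
    "CorpusValidationError",
    "tokenize",
    "read_corpus",
    "write_corpus",
    "build_vocabulary",
    "tfidf_matrix",
    "export_term_matrix",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")

# Strings treated as "no label" in the label column.
_NA_STRINGS = {"", "na", "nan", "none", "null"}


class CorpusFormatError(ValueError):
    """The input file does not have the expected columns or dialect."""


class CorpusValidationError(ValueError):
    """The file parsed but violates a corpus invariant (e.g. duplicate id)."""


@dataclass(frozen=True)
class Citation:
    """One bibliographic record to be screened.

    ``gold_label`` is 1 for eligible (include), 0 for ineligible (exclude)
    and ``None`` when the record is unlabelled.
    """

    id: str
    title: str
    abstract: str = ""
    gold_label: int | None = None

    def __post_init__(self) -> None:
        if self.gold_label is not None and self.gold_label not in (0, 1):
            raise CorpusValidationError(
                f"citation {self.id!r}: label must be 0 or 1, got {self.gold_label!r}"
            )

    @property
    def text(self) -> str:
        """Title and abstract pooled into one string."""
        return f"{self.title} {self.abstract}" if self.abstract else self.title


class Corpus:
    """Ordered, id-unique collection of citations."""

    def __init__(self, citations: Iterable[Citation]):
        self._citations: list[Citation] = list(citations)
        seen: dict[str, int] = {}
        for i, c in enumerate(self._citations):
            if c.id in seen:
                raise CorpusValidationError(f"duplicate citation id {c.id!r}")
            seen[c.id] = i
        self._index = seen

    def __len__(self) -> int:
        return len(self._citations)

    def __iter__(self) -> Iterator[Citation]:
        return iter(self._citations)

    def __getitem__(self, i: int) -> Citation:
        return self._citations[i]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self._citations]

    def index_of(self, citation_id: str) -> int:
        return self._index[citation_id]

    def labels(self) -> np.ndarray:
        """Gold labels as an int array, -1 where unlabelled."""
        return np.array(
            [-1 if c.gold_label is None else c.gold_label for c in self._citations],
            dtype=np.int64,
        )

    def labelled_indices(self) -> dict[int, int]:
        """Map corpus index -> gold label, restricted to labelled citations."""
        return {
            i: c.gold_label
            for i, c in enumerate(self._citations)
            if c.gold_label is not None
        }


def tokenize(text: str) -> list[str]:
    """Lowercase, split on any non-alphanumeric run, keep tokens of length >= 1."""
    return _TOKEN_RE.findall(text.lower())


def _parse_label(raw: str, citation_id: str) -> int | None:
    if raw.strip().lower() in _NA_STRINGS:
        return None
    try:
        value = float(raw)
    except ValueError:
        raise CorpusValidationError(
            f"citation {citation_id!r}: unparseable label {raw!r}"
        ) from None
    if value not in (0.0, 1.0):
        raise CorpusValidationError(
            f"citation {citation_id!r}: label must be 0, 1 or NA, got {raw!r}"
        )
    return int(value)


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if dialect not in ("csv", "tsv"):
        raise CorpusFormatError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_corpus(path: str | Path, dialect: str | None = None) -> Corpus:
    """Read a citation corpus from a delimited text file.

    The file must be UTF-8 with a header naming at least ``id``, ``title``
    and ``abstract``; an optional ``label`` column holds 0/1/NA.  Rows are
    kept in file order.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"id", "title", "abstract"} - set(frame.columns)
    if missing:
        raise CorpusFormatError(
            f"{path.name}: missing mandatory column(s) {sorted(missing)}"
        )
    has_label = "label" in frame.columns
    citations = []
    for row in frame.itertuples(index=False):
        cid = str(getattr(row, "id"))
        label = _parse_label(str(getattr(row, "label")), cid) if has_label else None
        citations.append(
            Citation(
                id=cid,
                title=str(getattr(row, "title")),
                abstract=str(getattr(row, "abstract")),
                gold_label=label,
            )
        )
    return Corpus(citations)


def write_corpus(corpus: Corpus, path: str | Path, dialect: str | None = None) -> None:
    """Write a corpus back to CSV/TSV; unlabelled citations get an empty label."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    frame = pd.DataFrame(
        {
            "id": [c.id for c in corpus],
            "title": [c.title for c in corpus],
            "abstract": [c.abstract for c in corpus],
            "label": ["" if c.gold_label is None else str(c.gold_label) for c in corpus],
        }
    )
    frame.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token list with 0-based contiguous indices and document frequencies.

    ``doc_freq[j]`` is the fraction of citations containing token ``j``
    (0 < f_w <= 1 for every retained token).
    """

    tokens: tuple[str, ...]
    doc_freq: np.ndarray

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.doc_freq):
            raise ValueError("tokens and doc_freq length mismatch")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.tokens)}


def build_vocabulary(
    corpus: Corpus,
    *,
    stop_words: Sequence[str] | None = None,
) -> Vocabulary:
    """Collect every token appearing in at least one citation.

    Tokens are ordered lexicographically for determinism.  ``stop_words``
    (off by default) removes the given tokens before counting.
    """
    if len(corpus) == 0:
        raise CorpusValidationError("cannot build a vocabulary from an empty corpus")
    stop = set(stop_words) if stop_words else set()
    doc_counts: dict[str, int] = {}
    total_tokens = 0
    for citation in corpus:
        toks = [t for t in tokenize(citation.text) if t not in stop]
        total_tokens += len(toks)
        for t in set(toks):
            doc_counts[t] = doc_counts.get(t, 0) + 1
    if total_tokens == 0:
        raise CorpusValidationError("corpus contains no tokens")
    tokens = tuple(sorted(doc_counts))
    freq = np.array([doc_counts[t] / len(corpus) for t in tokens], dtype=np.float64)
    return Vocabulary(tokens=tokens, doc_freq=freq)


def tfidf_matrix(corpus: Corpus, vocab: Vocabulary) -> sp.csr_matrix:
    """Sparse n x m TF-IDF matrix X with X[d, w] = c_{d,w} * ln(1 / f_w).

    Natural log; a token present in every citation has f_w = 1 and
    contributes a zero column.  Entries are never negative.
    """
    index = vocab.index
    idf = -np.log(vocab.doc_freq)  # ln(1/f_w)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for d, citation in enumerate(corpus):
        counts: dict[int, int] = {}
        for t in tokenize(citation.text):
            j = index.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            if idf[j] > 0.0:
                rows.append(d)
                cols.append(j)
                vals.append(c * idf[j])
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(corpus), len(vocab)), dtype=np.float64
    )
    X.sort_indices()
    return X


def export_term_matrix(
    X: sp.csr_matrix, vocab: Vocabulary, mtx_path: str | Path, vocab_path: str | Path
) -> None:
    """Write the term matrix as Matrix Market plus a (token, index, f_w) TSV."""
    from scipy.io import mmwrite

    mmwrite(str(mtx_path), X)
    frame = pd.DataFrame(
        {
            "token": vocab.tokens,
            "index": np.arange(len(vocab)),
            "doc_freq": vocab.doc_freq,
        }
    )
    frame.to_csv(vocab_path, sep="\t", index=False)
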