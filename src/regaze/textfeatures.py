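"""Surface psycholinguistic features for poem words.

Tokenizes verse text into word tokens with positional identity
(line number, word number within line) and scores each token on seven
surface features against a pluggable frequency lexicon:

- ``wl``       word length (letters only)
- ``logf``     log10 word frequency, add-one smoothed
- ``on``       orthographic neighborhood density (Coltheart's N)
- ``hfn``      number of higher-frequency orthographic neighbors
- ``odc``      orthographic dissimilarity: mean Levenshtein distance to
               every other lexicon type
- ``cvq``      consonant/vowel quotient
- ``sonscore`` sonority score: summed sonority ranks / sqrt(wl)
"""

from __future__ import annotations

import logging
import math
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Lexicon",
    "WordToken",
    "SonorityTable",
    "DEFAULT_SONORITY_TABLE",
    "tokenize_poem",
    "load_bundled_sonnets",
    "word_length",
    "log_frequency",
    "orthographic_neighbors",
    "higher_freq_neighbors",
    "orthographic_dissimilarity",
    "consonant_vowel_quotient",
    "sonority_score",
    "levenshtein",
    "build_feature_table",
]

VOWELS = frozenset("aeiou")

FEATURE_COLUMNS = ["wl", "logf", "on", "hfn", "odc", "cvq", "sonscore"]
PREDICTOR_COLUMNS = ["line_no", "word_no"] + FEATURE_COLUMNS


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------


class Lexicon:
    """A word-frequency list: lower-cased word types mapped to counts.

    Stands in for any reference corpus frequency list (e.g. a literary
    corpus unigram count table). Word types are case-folded; duplicate
    entries are merged by summing counts.
    """

    def __init__(self, entries: Mapping[str, int]):
        merged: dict[str, int] = {}
        for word, count in entries.items():
            w = _normalize_word(str(word))
            if not w:
                raise ValueError("empty word type in lexicon")
            c = int(count)
            if c < 0:
                raise ValueError(f"negative count for {w!r}")
            merged[w] = merged.get(w, 0) + c
        if not merged:
            raise ValueError("lexicon is empty")
        self._entries = merged
        self.total_tokens = sum(merged.values())
        # types bucketed by length: neighbor scans touch only same-length types
        self._by_length: dict[int, list[str]] = {}
        for w in merged:
            self._by_length.setdefault(len(w), []).append(w)

    @property
    def entries(self) -> Mapping[str, int]:
        return dict(self._entries)

    def count(self, word: str) -> int:
        return self._entries.get(_normalize_word(word), 0)

    def __contains__(self, word: str) -> bool:
        return _normalize_word(word) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def types(self) -> Iterable[str]:
        return self._entries.keys()

    def same_length_types(self, length: int) -> Sequence[str]:
        return self._by_length.get(length, ())

    @classmethod
    def from_tsv(cls, path) -> "Lexicon":
        """Load a two-column ``word<TAB>count`` file; header row optional."""
        entries: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{i + 1}: expected 2 tab-separated fields")
                word, count = parts
                try:
                    c = int(count)
                except ValueError:
                    if i == 0:  # tolerate a header row
                        continue
                    raise ValueError(f"{path}:{i + 1}: non-integer count {count!r}")
                w = _normalize_word(word)
                if w:
                    entries[w] = entries.get(w, 0) + c
        return cls(entries)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\tcount\n")
            for w in sorted(self._entries):
                fh.write(f"{w}\t{self._entries[w]}\n")


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WordToken:
    """One word occurrence in a poem, identified by its position."""

    surface: str
    norm: str
    sonnet_id: str
    line_no: int  # 1-based verse line
    word_no: int  # 1-based position within the line

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.sonnet_id, self.line_no, self.word_no)


def _normalize_word(word: str) -> str:
    """Case-fold and normalize apostrophe variants; keep ' and - internal."""
    w = unicodedata.normalize("NFC", word).replace("’", "'").replace("ʼ", "'")
    return w.lower()


_EDGE_STRIP = re.compile(r"^[^a-zA-Z]+|[^a-zA-Z]+$")


def _clean_chunk(chunk: str) -> str:
    """Strip edge punctuation, keeping internal apostrophes and hyphens."""
    return _EDGE_STRIP.sub("", chunk)


def tokenize_poem(
    text: str,
    sonnet_id: str,
    *,
    split_hyphens: bool = False,
    exclude: Iterable[tuple[int, int]] = (),
) -> list[WordToken]:
    """Tokenize verse text into :class:`WordToken` records.

    Each input line is one verse line. Edge punctuation is stripped;
    internal apostrophes are kept, so contractions ("body's", "trimm'd")
    are single tokens. Hyphenated compounds are one token by default;
    ``split_hyphens=True`` splits them into their parts (needed to match
    word counts in editions that treat compounds as two words).

    ``exclude`` removes specific (line_no, word_no) positions after
    numbering, for editions that omit words.
    """
    if not text or not text.strip():
        raise ValueError("empty poem text")
    exclude_set = set(exclude)
    tokens: list[WordToken] = []
    line_no = 0
    for raw_line in text.splitlines():
        if not raw_line.strip():
            continue
        line_no += 1
        chunks = []
        for chunk in raw_line.split():
            cleaned = _clean_chunk(chunk)
            if split_hyphens:
                parts = [p for p in re.split(r"[-—]", cleaned) if p]
            else:
                parts = [cleaned] if cleaned else []
            for part in parts:
                part = _clean_chunk(part)
                if any(ch.isalpha() for ch in part):
                    chunks.append(part)
        if not chunks:
            logger.warning(
                "%s line %d has no alphabetic content; skipped", sonnet_id, line_no
            )
            line_no -= 1
            continue
        for word_no, surface in enumerate(chunks, start=1):
            if (line_no, word_no) in exclude_set:
                continue
            tokens.append(
                WordToken(
                    surface=surface,
                    norm=_normalize_word(surface),
                    sonnet_id=str(sonnet_id),
                    line_no=line_no,
                    word_no=word_no,
                )
            )
    return tokens


def load_bundled_sonnets(*, split_hyphens: bool = False) -> list[WordToken]:
    """Tokenize the two bundled public-domain sonnets (ids '27' and '66')."""
    tokens: list[WordToken] = []
    for sid in ("27", "66"):
        text = (
            resources.files("regaze.data").joinpath(f"sonnet{sid}.txt").read_text("utf-8")
        )
        tokens.extend(tokenize_poem(text, sid, split_hyphens=split_hyphens))
    return tokens


# ---------------------------------------------------------------------------
# Per-word features
# ---------------------------------------------------------------------------


def _letters(norm: str) -> str:
    return "".join(ch for ch in norm if ch.isalpha())


def word_length(token: WordToken | str) -> int:
    """Number of letters (apostrophes/hyphens do not count)."""
    norm = token if isinstance(token, str) else token.norm
    n = len(_letters(norm))
    if n == 0:
        raise ValueError(f"token {norm!r} has no letters")
    return n


def log_frequency(token: WordToken | str, lexicon: Lexicon) -> float:
    """log10(count + 1); out-of-vocabulary words map to 0."""
    norm = token if isinstance(token, str) else token.norm
    return math.log10(lexicon.count(norm) + 1)


def _hamming_is_one(a: str, b: str) -> bool:
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def orthographic_neighbors(token: WordToken | str, lexicon: Lexicon) -> int:
    """Coltheart's N: same-length lexicon types differing by one letter."""
    norm = token if isinstance(token, str) else token.norm
    return sum(
        1
        for w in lexicon.same_length_types(len(norm))
        if w != norm and _hamming_is_one(norm, w)
    )


def higher_freq_neighbors(token: WordToken | str, lexicon: Lexicon) -> int:
    """Orthographic neighbors with strictly greater frequency than the word."""
    norm = token if isinstance(token, str) else token.norm
    own = lexicon.count(norm)
    return sum(
        1
        for w in lexicon.same_length_types(len(norm))
        if w != norm and _hamming_is_one(norm, w) and lexicon.count(w) > own
    )


def levenshtein(a: str, b: str) -> int:
    """Edit distance (insert/delete/substitute, unit costs), iterative DP."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def orthographic_dissimilarity(token: WordToken | str, lexicon: Lexicon) -> float:
    """Mean Levenshtein distance to every *other* lexicon type."""
    norm = token if isinstance(token, str) else token.norm
    total = 0
    n = 0
    for w in lexicon.types():
        if w == norm:
            continue
        total += levenshtein(norm, w)
        n += 1
    if n == 0:
        raise ValueError(f"lexicon contains no type other than {norm!r}")
    return total / n


def consonant_vowel_quotient(
    token: WordToken | str, vowels: frozenset[str] = VOWELS
) -> float:
    """Consonants divided by vowels, counting letters of the norm form.

    'y' counts as a vowel only when the word contains no other vowel
    (e.g. "rhythm"); otherwise it is a consonant. Words with no vowel
    even under that fallback get NaN with a warning.
    """
    norm = token if isinstance(token, str) else token.norm
    letters = _letters(norm)
    n_vowels = sum(1 for ch in letters if ch in vowels)
    effective_vowels = set(vowels)
    if n_vowels == 0 and "y" in letters:
        effective_vowels.add("y")
        n_vowels = sum(1 for ch in letters if ch in effective_vowels)
    if n_vowels == 0:
        logger.warning("no vowels in %r; cvq undefined", norm)
        return float("nan")
    n_consonants = len(letters) - n_vowels
    return n_consonants / n_vowels


# ---------------------------------------------------------------------------
# Sonority
# ---------------------------------------------------------------------------

# The 10-rank sonority hierarchy (most sonorous = 10):
#   [a] > [e o] > [i u j w] > [r] > [l] > [m n ng] > [z v] > [f th s] > [b d g] > [p t k]
# Letters without a rank in the phoneme hierarchy are mapped by their most
# common English realization: c,q,x like /k/; h like the voiceless
# fricatives; y like the glide /j/.
_DEFAULT_RANKS: dict[str, int] = {
    "a": 10,
    "e": 9, "o": 9,
    "i": 8, "u": 8, "j": 8, "w": 8, "y": 8,
    "r": 7,
    "l": 6,
    "m": 5, "n": 5,
    "z": 4, "v": 4,
    "f": 3, "s": 3, "h": 3,
    "b": 2, "d": 2, "g": 2,
    "p": 1, "t": 1, "k": 1, "c": 1, "q": 1, "x": 1,
}


@dataclass(frozen=True)
class SonorityTable:
    """Symbol-to-rank mapping on the 10-level sonority hierarchy.

    ``phonemic`` enables the single digraph rule implemented here:
    "ng" scores as one nasal segment (rank of 'n') instead of n + g.
    """

    ranks: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_RANKS))
    phonemic: bool = False

    def __post_init__(self):
        if not self.ranks:
            raise ValueError("empty sonority table")
        if any(v <= 0 for v in self.ranks.values()):
            raise ValueError("sonority ranks must be positive")

    def rank(self, symbol: str) -> int:
        try:
            return self.ranks[symbol]
        except KeyError:
            raise KeyError(f"no sonority rank for symbol {symbol!r}") from None


DEFAULT_SONORITY_TABLE = SonorityTable()


def sonority_score(
    token: WordToken | str, table: SonorityTable = DEFAULT_SONORITY_TABLE
) -> float:
    """Sum of per-letter sonority ranks divided by sqrt(word length).

    Example: "art" -> (10 + 7 + 1) / sqrt(3) = 10.39.
    """
    norm = token if isinstance(token, str) else token.norm
    letters = _letters(norm.lower())
    if not letters:
        raise ValueError(f"token {norm!r} has no letters")
    if table.phonemic:
        letters = letters.replace("ng", "n")
    total = sum(table.rank(ch) for ch in letters)
    return total / math.sqrt(word_length(norm))


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


def zscore(values: pd.Series | np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD)."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (v - v.mean()) / sd


def build_feature_table(
    poems: Mapping[str, str] | Sequence[WordToken],
    lexicon: Lexicon,
    table: SonorityTable = DEFAULT_SONORITY_TABLE,
    *,
    split_hyphens: bool = False,
    standardize: bool = False,
) -> pd.DataFrame:
    """Score every word token of one or more poems on all nine predictors.

    ``poems`` is either a mapping sonnet_id -> poem text, or an already
    tokenized sequence. One row per token — repeated words are NOT merged;
    positional columns (line_no, word_no) keep them distinct. With
    ``standardize=True``, z-scored ``_z`` columns are appended for the
    nine predictors.
    """
    if isinstance(poems, Mapping):
        tokens: list[WordToken] = []
        for sid, text in poems.items():
            tokens.extend(tokenize_poem(text, sid, split_hyphens=split_hyphens))
    else:
        tokens = list(poems)
    if not tokens:
        raise ValueError("no tokens to score")
    seen = set()
    for t in tokens:
        if t.key in seen:
            raise ValueError(f"duplicate token position {t.key}")
        seen.add(t.key)

    rows = []
    for t in tokens:
        rows.append(
            {
                "sonnet_id": t.sonnet_id,
                "line_no": t.line_no,
                "word_no": t.word_no,
                "surface": t.surface,
                "norm": t.norm,
                "wl": word_length(t),
                "logf": log_frequency(t, lexicon),
                "on": orthographic_neighbors(t, lexicon),
                "hfn": higher_freq_neighbors(t, lexicon),
                "odc": orthographic_dissimilarity(t, lexicon),
                "cvq": consonant_vowel_quotient(t),
                "sonscore": sonority_score(t, table),
            }
        )
    df = pd.DataFrame(rows)
    if standardize:
        for col in PREDICTOR_COLUMNS:
            df[f"{col}_z"] = zscore(df[col])
    return df
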