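"""miRNA seed words and their occurrences in a 3'UTR universe.

A miRNA recognises its targets chiefly through its 5' seed region
(nucleotides 1-8 of the mature sequence, canonically 2-7).  The DNA word in
an mRNA 3'UTR that base-pairs with a seed element is its *seed complementary
region* (SCR): the reverse complement of the seed sub-sequence, written in
DNA space (U -> T).  This module derives SCR words from mature miRNA
sequences, scans a universe of 3'UTRs for them, and reports gene-level
presence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "MiRNA",
    "SCRElement",
    "SCRElementSet",
    "UTRUniverse",
    "OccurrenceIndex",
    "DEFAULT_ELEMENT_SPANS",
    "CANONICAL_SEED_SPAN",
    "derive_scr_elements",
    "scan_occurrences",
    "background_presence_rate",
    "count_occurrences",
]

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

#: Contiguous sub-spans of the 1-8 seed region used by default to build the
#: element set: three 6-mers, two 7-mers and the full 8-mer.
DEFAULT_ELEMENT_SPANS: tuple[tuple[int, int], ...] = (
    (1, 6),
    (2, 7),
    (3, 8),
    (1, 7),
    (2, 8),
    (1, 8),
)

#: The canonical seed word positions used for gene-level target calls.
CANONICAL_SEED_SPAN: tuple[int, int] = (2, 7)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence with its seed-region convention.

    Parameters
    ----------
    name : str
        Label, e.g. ``"miR-100-5p"``.
    mature_seq : str
        Mature sequence 5'->3' in the RNA alphabet (A/C/G/U).
    seed_span : tuple of int
        1-based inclusive positions delimiting the seed region
        (default ``(1, 8)``).
    """

    name: str
    mature_seq: str
    seed_span: tuple[int, int] = (1, 8)

    def __post_init__(self) -> None:
        seq = self.mature_seq.upper().replace("T", "U")
        object.__setattr__(self, "mature_seq", seq)
        if len(seq) < 8:
            raise ValueError(f"{self.name}: mature sequence must be >= 8 nt")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: non-RNA characters {sorted(bad)}")
        lo, hi = self.seed_span
        if not (1 <= lo <= hi <= len(seq)):
            raise ValueError(f"{self.name}: seed span {self.seed_span} out of bounds")

    def seed_subsequence(self, span: tuple[int, int] | None = None) -> str:
        """Return the seed sub-sequence for a 1-based inclusive span."""
        lo, hi = span if span is not None else self.seed_span
        if not (1 <= lo <= hi <= len(self.mature_seq)):
            raise ValueError(f"span {(lo, hi)} outside {self.name} bounds")
        return self.mature_seq[lo - 1 : hi]


@dataclass(frozen=True)
class SCRElement:
    """One SCR word: the DNA reverse complement of a seed sub-span."""

    label: str
    word: str
    seed_positions: tuple[int, int]

    def __post_init__(self) -> None:
        if not 6 <= len(self.word) <= 8:
            raise ValueError(f"{self.label}: word length must be 6-8")
        bad = set(self.word) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.label}: non-DNA characters {sorted(bad)}")


@dataclass(frozen=True)
class SCRElementSet:
    """Ordered SCR elements for one miRNA."""

    mirna_name: str
    elements: tuple[SCRElement, ...]

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(e.word for e in self.elements)

    def word_for(self, span: tuple[int, int]) -> str:
        for e in self.elements:
            if e.seed_positions == tuple(span):
                return e.word
        raise KeyError(f"no element with seed positions {span}")

    @property
    def canonical_word(self) -> str:
        """The 2-7 seed word if present, else the first element's word."""
        try:
            return self.word_for(CANONICAL_SEED_SPAN)
        except KeyError:
            return self.elements[0].word


def rna_to_scr_word(seed_subseq: str) -> str:
    """DNA reverse complement of an RNA seed sub-sequence (U -> T first)."""
    dna = seed_subseq.upper().replace("U", "T")
    return str(Seq(dna).reverse_complement())


def derive_scr_elements(
    mirna: MiRNA,
    element_spec: Sequence[tuple[int, int]] | None = None,
) -> SCRElementSet:
    """Derive SCR words for a miRNA from seed sub-spans.

    Each sub-span (1-based inclusive, within the miRNA's ``seed_span``)
    yields one element whose word is the DNA reverse complement of that seed
    sub-sequence.  The default spec is the six contiguous sub-spans of the
    1-8 seed with lengths 6, 7 and 8.

    Examples
    --------
    >>> mir100 = MiRNA("miR-100-5p", "AACCCGUAGAUCCGAACUUGUG")
    >>> derive_scr_elements(mir100).word_for((2, 7))
    'ACGGGT'
    """
    spans = tuple(tuple(s) for s in (element_spec or DEFAULT_ELEMENT_SPANS))
    lo0, hi0 = mirna.seed_span
    elements = []
    for lo, hi in spans:
        if not (lo0 <= lo <= hi <= hi0):
            raise ValueError(
                f"{mirna.name}: element span {(lo, hi)} outside seed span {mirna.seed_span}"
            )
        word = rna_to_scr_word(mirna.seed_subsequence((lo, hi)))
        elements.append(SCRElement(label=f"m{lo}-{hi}", word=word, seed_positions=(lo, hi)))
    return SCRElementSet(mirna_name=mirna.name, elements=tuple(elements))


@dataclass
class UTRUniverse:
    """gene_id -> 3'UTR DNA sequence (uppercase A/C/G/T/N)."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for gene_id, seq in self.records.items():
            s = seq.upper().replace("U", "T")
            if not s:
                raise ValueError(f"{gene_id}: empty sequence")
            bad = set(s) - (DNA_ALPHABET | {"N"})
            if bad:
                raise ValueError(f"{gene_id}: invalid characters {sorted(bad)}")
            clean[gene_id] = s
        self.records = clean

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)


def count_occurrences(sequence: str, word: str) -> int:
    """Overlapping occurrences of ``word`` in ``sequence`` (N never matches)."""
    seq = sequence.upper()
    n, start = 0, 0
    while True:
        i = seq.find(word, start)
        if i < 0:
            return n
        n += 1
        start = i + 1  # step one position: overlapping windows


@dataclass
class OccurrenceIndex:
    """Per-gene occurrence counts and presence flags for a set of DNA words.

    ``counts`` is a genes x words integer DataFrame; presence is derived
    (count > 0).
    """

    counts: pd.DataFrame

    @property
    def words(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def count(self, gene_id: str, word: str) -> int:
        return int(self.counts.at[gene_id, word])

    def has_word(self, gene_id: str, word: str) -> bool:
        return self.count(gene_id, word) > 0

    def carriers(self, word: str) -> set[str]:
        """Genes whose 3'UTR contains the word at least once."""
        if word not in self.counts.columns:
            raise KeyError(f"word {word!r} not in index")
        col = self.counts[word]
        return set(col.index[col > 0])

    def presence_vector(self, word: str, gene_order: Sequence[str]) -> np.ndarray:
        """Boolean presence for genes in a given order (for landscape cuts)."""
        if word not in self.counts.columns:
            raise KeyError(f"word {word!r} not in index")
        return (self.counts[word].reindex(list(gene_order)) > 0).to_numpy()


def scan_occurrences(universe: UTRUniverse, words: Iterable[str]) -> OccurrenceIndex:
    """Index overlapping occurrences of each word in each 3'UTR.

    Words must be uppercase DNA of length >= 4.  Positions containing N never
    match because N is not in any word's alphabet.
    """
    word_list = list(dict.fromkeys(words))
    if not word_list:
        raise ValueError("empty word set")
    for w in word_list:
        if len(w) < 4 or set(w) - DNA_ALPHABET:
            raise ValueError(f"invalid DNA word {w!r} (uppercase ACGT, length >= 4)")
    data = {
        w: [count_occurrences(seq, w) for seq in universe.records.values()]
        for w in word_list
    }
    counts = pd.DataFrame(data, index=universe.gene_ids, dtype=np.int64)
    return OccurrenceIndex(counts=counts)


def background_presence_rate(
    index: OccurrenceIndex, word: str, universe_size: int | None = None
) -> float:
    """Fraction of the universe whose 3'UTR contains the word.

    ``universe_size`` defaults to the number of indexed genes; it may be
    passed explicitly when the index covers a subset of a larger annotated
    universe.  Report as a percentage to one decimal with
    ``round(100 * rate, 1)``.
    """
    n = len(index.gene_ids) if universe_size is None else universe_size
    if n <= 0:
        raise ValueError("universe_size must be positive")
    return len(index.carriers(word)) / n
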