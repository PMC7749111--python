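"""Orthography-to-phoneme conversion for a small CV language.

The target language has ten consonants (two written as digraphs) and five
vowel qualities, each with a short and a long counterpart; long vowels are
marked orthographically with a macron.  Because the orthography is fully
transparent, written forms are tokenized deterministically into phoneme
symbols, with each digraph and each long vowel counting as a single phoneme.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "PhonemeInventory",
    "PhonemeString",
    "default_inventory",
    "load_inventory",
    "tokenize_orthography",
    "detokenize",
    "collapse_vowel_length",
    "detect_macron",
    "validate_legality",
    "TokenizationError",
]


class TokenizationError(ValueError):
    """Raised when orthographic text contains material outside the inventory."""


@dataclass(frozen=True)
class PhonemeInventory:
    """Symbol sets and orthographic mappings of the phoneme inventory.

    ``consonants``, ``short_vowels`` and ``long_vowels`` are disjoint sets of
    phoneme symbols.  ``orthography`` maps each symbol to its written form
    (digraph consonants map to two characters, long vowels to a macron-marked
    vowel).  ``long_to_short`` maps every long vowel to its short counterpart.
    ``boundary_start`` / ``boundary_end`` are reserved symbols used only for
    trigram padding and never occur inside a :class:`PhonemeString`.
    """

    consonants: frozenset[str]
    short_vowels: frozenset[str]
    long_vowels: frozenset[str]
    orthography: dict[str, str]
    long_to_short: dict[str, str]
    boundary_start: str = "<"
    boundary_end: str = ">"
    # derived, filled in __post_init__
    _ortho_to_symbol: dict[str, str] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        overlap = (
            (self.consonants & self.short_vowels)
            | (self.consonants & self.long_vowels)
            | (self.short_vowels & self.long_vowels)
        )
        if overlap:
            raise ValueError(f"symbol classes overlap: {sorted(overlap)}")
        if {self.boundary_start, self.boundary_end} & self.symbols:
            raise ValueError("boundary symbols must not appear in the inventory")
        if set(self.long_to_short) != self.long_vowels:
            raise ValueError("every long vowel needs exactly one short counterpart")
        if not set(self.long_to_short.values()) <= self.short_vowels:
            raise ValueError("long vowels must map onto short vowels")
        object.__setattr__(
            self, "_ortho_to_symbol", {o: s for s, o in self.orthography.items()}
        )

    @property
    def symbols(self) -> frozenset[str]:
        return self.consonants | self.short_vowels | self.long_vowels

    @property
    def vowels(self) -> frozenset[str]:
        return self.short_vowels | self.long_vowels

    def symbol_order(self) -> list[str]:
        """Deterministic symbol ordering (consonants, short vowels, long vowels)."""
        return (
            sorted(self.consonants)
            + sorted(self.short_vowels)
            + sorted(self.long_vowels)
        )

    @property
    def digraph_map(self) -> dict[str, str]:
        """Orthographic digraphs (two written characters, one consonant symbol)."""
        return {
            o: s
            for s, o in self.orthography.items()
            if s in self.consonants and len(o) == 2
        }


@dataclass(frozen=True)
class PhonemeString:
    """An ordered phoneme-symbol sequence with its source orthography."""

    symbols: tuple[str, ...]
    source_orthography: str

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("a phoneme string has at least one symbol")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


def load_inventory(path) -> PhonemeInventory:
    """Read an inventory from a tab-separated file.

    Columns: symbol, class (consonant | short_vowel | long_vowel),
    orthography, short_counterpart (long vowels only).
    """
    consonants, short_vowels, long_vowels = set(), set(), set()
    orthography: dict[str, str] = {}
    long_to_short: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["symbol", "class", "orthography"]:
            raise ValueError(f"unexpected inventory header: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"inventory line {lineno}: need >= 3 columns")
            symbol, klass, ortho = parts[0], parts[1], parts[2]
            orthography[symbol] = unicodedata.normalize("NFC", ortho)
            if klass == "consonant":
                consonants.add(symbol)
            elif klass == "short_vowel":
                short_vowels.add(symbol)
            elif klass == "long_vowel":
                long_vowels.add(symbol)
                if len(parts) < 4 or not parts[3]:
                    raise ValueError(
                        f"inventory line {lineno}: long vowel lacks short counterpart"
                    )
                long_to_short[symbol] = parts[3]
            else:
                raise ValueError(f"inventory line {lineno}: unknown class {klass!r}")
    return PhonemeInventory(
        consonants=frozenset(consonants),
        short_vowels=frozenset(short_vowels),
        long_vowels=frozenset(long_vowels),
        orthography=orthography,
        long_to_short=long_to_short,
    )


_DEFAULT_INVENTORY: PhonemeInventory | None = None


def default_inventory() -> PhonemeInventory:
    """The shipped 10-consonant, 5+5-vowel inventory (cached)."""
    global _DEFAULT_INVENTORY
    if _DEFAULT_INVENTORY is None:
        ref = resources.files("protolex.data") / "inventory_maori.tsv"
        with resources.as_file(ref) as path:
            _DEFAULT_INVENTORY = load_inventory(path)
    return _DEFAULT_INVENTORY


def tokenize_orthography(text: str, inv: PhonemeInventory | None = None) -> PhonemeString:
    """Greedy longest-match tokenization of orthographic text.

    Digraphs take precedence over single characters, so e.g. a written
    consonant digraph consumes two characters and yields one symbol; a
    macron-marked vowel yields one long-vowel symbol.  Case is folded before
    matching (stimuli are written; case carries no phonology).
    """
    if inv is None:
        inv = default_inventory()
    if not text:
        raise TokenizationError("empty orthographic string")
    norm = unicodedata.normalize("NFC", text.casefold())
    # orthographies sorted by length descending => longest match first
    units = sorted(inv._ortho_to_symbol, key=len, reverse=True)
    symbols: list[str] = []
    i = 0
    while i < len(norm):
        for unit in units:
            if norm.startswith(unit, i):
                symbols.append(inv._ortho_to_symbol[unit])
                i += len(unit)
                break
        else:
            raise TokenizationError(
                f"unknown character {norm[i]!r} at position {i} in {text!r}"
            )
    return PhonemeString(symbols=tuple(symbols), source_orthography=text)


def detokenize(ps: PhonemeString, inv: PhonemeInventory | None = None) -> str:
    """Write a phoneme string back to orthography (inverse of tokenization)."""
    if inv is None:
        inv = default_inventory()
    return "".join(inv.orthography[s] for s in ps.symbols)


def collapse_vowel_length(
    ps: PhonemeString, inv: PhonemeInventory | None = None
) -> PhonemeString:
    """Replace every long vowel by its short counterpart.

    Length (in phonemes) and consonant positions are preserved; the operation
    is idempotent.  Used to model raters who do not track vowel length in
    their phonotactics.
    """
    if inv is None:
        inv = default_inventory()
    symbols = tuple(inv.long_to_short.get(s, s) for s in ps.symbols)
    if symbols == ps.symbols:
        return ps
    return PhonemeString(symbols=symbols, source_orthography=ps.source_orthography)


def detect_macron(text: str, inv: PhonemeInventory | None = None) -> bool:
    """True iff the written form contains at least one macron-marked vowel.

    The visual presence of a macron is used as a binary regression covariate,
    separate from any phonotactic effect of vowel length.
    """
    if inv is None:
        inv = default_inventory()
    ps = tokenize_orthography(text, inv)
    return any(s in inv.long_vowels for s in ps.symbols)


def validate_legality(ps: PhonemeString, inv: PhonemeInventory | None = None) -> bool:
    """Open-syllable legality: no consonant clusters and a final vowel."""
    if inv is None:
        inv = default_inventory()
    prev_consonant = False
    for s in ps.symbols:
        is_c = s in inv.consonants
        if is_c and prev_consonant:
            return False
        prev_consonant = is_c
    return ps.symbols[-1] in inv.vowels
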