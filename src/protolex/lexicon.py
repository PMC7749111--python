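"""Lexicon I/O, morph inventories, token streams, and flagged subsets.

A lexicon holds word *types* with corpus token frequencies, optional morph
segmentations (``morph1+morph2`` in the file format) and an optional
borrowed-into-the-ambient-language flag.  A frequency-weighted expansion of
the types stands in for the *token stream* of experience: trigram training
uses the frequencies as weights, which yields exactly the counts literal
repetition would, without materializing the stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .phonology import (
    PhonemeInventory,
    PhonemeString,
    default_inventory,
    tokenize_orthography,
    TokenizationError,
)

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "read_lexicon",
    "write_lexicon",
    "morph_inventory",
    "subset_by_flag",
    "LexiconError",
]

_HEADER = ["form", "frequency", "segmentation", "borrowed"]


class LexiconError(ValueError):
    """Malformed lexicon file or operation precondition failure."""


@dataclass(frozen=True)
class LexiconEntry:
    form: str
    phonemes: PhonemeString
    frequency: float
    segmentation: tuple[str, ...] | None = None
    borrowed: bool | None = None

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise LexiconError(f"{self.form!r}: negative frequency")
        if self.segmentation is not None and "".join(self.segmentation) != self.form:
            raise LexiconError(
                f"{self.form!r}: segmentation {self.segmentation} does not "
                "concatenate to the form"
            )


class Lexicon:
    """An ordered collection of word types, unique on orthographic form."""

    def __init__(self, entries: list[LexiconEntry], inv: PhonemeInventory | None = None):
        self.inventory = inv if inv is not None else default_inventory()
        self.entries: list[LexiconEntry] = list(entries)
        self._by_form: dict[str, LexiconEntry] = {}
        for e in self.entries:
            if e.form in self._by_form:
                raise LexiconError(f"duplicate form {e.form!r}")
            self._by_form[e.form] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, form: str) -> bool:
        return form in self._by_form

    def __getitem__(self, form: str) -> LexiconEntry:
        return self._by_form[form]

    def __eq__(self, other) -> bool:
        return isinstance(other, Lexicon) and self.entries == other.entries

    @property
    def forms(self) -> list[str]:
        return [e.form for e in self.entries]

    @property
    def total_tokens(self) -> float:
        """Total token-stream weight (sum of entry frequencies)."""
        return float(sum(e.frequency for e in self.entries))

    def sequences_and_weights(self, weighting: str = "type"):
        """(PhonemeString, weight) pairs for trigram training.

        ``weighting='type'`` gives each type weight 1 (dictionary statistics);
        ``weighting='token'`` weights each type by its corpus frequency
        (stream-of-experience statistics).
        """
        if weighting == "type":
            return [(e.phonemes, 1.0) for e in self.entries]
        if weighting == "token":
            return [(e.phonemes, float(e.frequency)) for e in self.entries]
        raise ValueError(f"unknown weighting {weighting!r}")


def read_lexicon(path, inv: PhonemeInventory | None = None) -> Lexicon:
    """Read a tab-separated lexicon (columns form/frequency/segmentation/borrowed).

    Empty segmentation and borrowed cells mean "missing".  Malformed rows are
    rejected with their line number; duplicate or untokenizable forms are
    rejected naming the offending form.
    """
    if inv is None:
        inv = default_inventory()
    entries: list[LexiconEntry] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise LexiconError(f"expected header {_HEADER}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise LexiconError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            form, freq_s, seg_s, borrowed_s = parts
            try:
                freq = float(freq_s)
            except ValueError:
                raise LexiconError(f"line {lineno}: bad frequency {freq_s!r}") from None
            try:
                ps = tokenize_orthography(form, inv)
            except TokenizationError as exc:
                raise LexiconError(f"line {lineno} ({form!r}): {exc}") from None
            seg = tuple(seg_s.split("+")) if seg_s else None
            borrowed = None if borrowed_s == "" else borrowed_s == "1"
            try:
                entries.append(
                    LexiconEntry(form, ps, freq, segmentation=seg, borrowed=borrowed)
                )
            except LexiconError as exc:
                raise LexiconError(f"line {lineno}: {exc}") from None
    return Lexicon(entries, inv)


def write_lexicon(lex: Lexicon, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for e in lex.entries:
            freq = f"{e.frequency:g}"
            seg = "+".join(e.segmentation) if e.segmentation is not None else ""
            borrowed = "" if e.borrowed is None else ("1" if e.borrowed else "0")
            fh.write(f"{e.form}\t{freq}\t{seg}\t{borrowed}\n")


def morph_inventory(lex: Lexicon, count: str = "occurrence") -> Lexicon:
    """Collapse a segmented lexicon into its morph types.

    With ``count='occurrence'`` (default), a morph's frequency is the sum of
    the frequencies of the words containing it, counted once per occurrence —
    a morph appearing twice in one word contributes that word's frequency
    twice.  This is the statistic a learner hearing the stream experiences.
    ``count='type'`` instead counts each containing word type once per
    occurrence with weight 1.

    Every entry must carry a segmentation; a word without one is rejected by
    name rather than silently treated as simplex.
    """
    if count not in ("occurrence", "type"):
        raise ValueError(f"unknown count mode {count!r}")
    totals: dict[str, float] = {}
    for e in lex.entries:
        if e.segmentation is None:
            raise LexiconError(f"word {e.form!r} has no segmentation")
        w = e.frequency if count == "occurrence" else 1.0
        for morph in e.segmentation:
            totals[morph] = totals.get(morph, 0.0) + w
    entries = [
        LexiconEntry(m, tokenize_orthography(m, lex.inventory), f)
        for m, f in totals.items()
    ]
    entries.sort(key=lambda e: (-e.frequency, e.form))
    return Lexicon(entries, lex.inventory)


def subset_by_flag(lex: Lexicon, flag: str = "borrowed") -> Lexicon:
    """Entries whose flag is true, frequencies preserved."""
    if flag != "borrowed":
        raise ValueError(f"unknown flag {flag!r}")
    return Lexicon([e for e in lex.entries if e.borrowed], lex.inventory)
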