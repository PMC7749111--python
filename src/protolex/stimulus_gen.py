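"""Nonword generation, score matching, frequency bins and participant lists.

Experimental stimuli pair real words with nonwords of the same phoneme
length and a closely matched phonotactic score, so that rating differences
between words and nonwords cannot be explained by phonotactics alone.
Nonwords are sampled from a trigram model (so they span a similar range of
phonotactic probabilities as the words), constrained to be phonotactically
legal and absent from the lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .phonology import PhonemeString, detokenize, validate_legality
from .phonotactics import TrigramModel

__all__ = [
    "StimulusItem",
    "generate_nonword",
    "generate_nonword_pool",
    "assign_frequency_bins",
    "build_matched_pairs",
    "build_participant_list",
    "write_stimuli",
    "read_stimuli",
    "MatchingError",
]


class MatchingError(ValueError):
    """Raised when stimulus construction cannot satisfy its constraints."""


@dataclass(frozen=True)
class StimulusItem:
    form: str
    phonemes: PhonemeString
    is_word: bool
    phonotactic_score: float
    length: int
    frequency_bin: int | None = None
    pair_id: str | None = None


def _sampling_tables(model: TrigramModel) -> np.ndarray:
    """Cumulative outcome probabilities per context, cached on the model."""
    cum = getattr(model, "_sampling_cum", None)
    if cum is None:
        probs = 2.0 ** model._log2_probs()
        # contexts with no mass and no smoothing cannot be sampled from
        probs = np.nan_to_num(probs, nan=0.0)
        cum = np.cumsum(probs, axis=2)
        model._sampling_cum = cum
    return cum


def generate_nonword(
    model: TrigramModel,
    length: int,
    exclusions: set[str],
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> PhonemeString:
    """Sample a legal nonword of exactly ``length`` phonemes from the model.

    Symbols are drawn one at a time from the trigram conditionals until the
    end boundary; a draw is rejected unless it has the target length, passes
    the open-syllable legality check, and its orthography is absent from
    ``exclusions`` (the lexicon plus previously generated items).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if model.smoothing_k <= 0 and not np.any(model.counts):
        raise ValueError("nonword generation needs a smoothed or trained model")
    cum = _sampling_tables(model)
    inv = model.inventory
    start, end = model.start_id, model.end_id
    for _ in range(max_attempts):
        c2, c1 = start, start
        ids: list[int] = []
        while True:
            row = cum[c2, c1]
            if row[-1] <= 0:  # dead-end context under an unsmoothed model
                ids = []
                break
            u = rng.random() * row[-1]
            out = int(np.searchsorted(row, u, side="right"))
            if out == end:
                break
            ids.append(out)
            if len(ids) > length:  # cannot recover: reject early
                break
            c2, c1 = c1, out
        if len(ids) != length:
            continue
        symbols = tuple(model.symbols[i] for i in ids)
        ps = PhonemeString(symbols=symbols, source_orthography="")
        if not validate_legality(ps, inv):
            continue
        form = detokenize(ps, inv)
        if form in exclusions:
            continue
        return PhonemeString(symbols=symbols, source_orthography=form)
    raise MatchingError(
        f"no legal novel nonword of length {length} found in {max_attempts} "
        "attempts; increase the budget or use a shorter length"
    )


def generate_nonword_pool(
    model: TrigramModel,
    lengths,
    lexicon: Lexicon,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> list[PhonemeString]:
    """Generate one nonword per requested length, excluding the lexicon and
    each other."""
    exclusions = set(lexicon.forms)
    out: list[PhonemeString] = []
    for ln in lengths:
        ps = generate_nonword(model, int(ln), exclusions, rng, max_attempts)
        exclusions.add(ps.source_orthography)
        out.append(ps)
    return out


def assign_frequency_bins(words: Lexicon, n_bins: int = 5) -> np.ndarray:
    """Frequency bin (1 = most frequent) per word, aligned with entry order.

    Words are ranked by descending frequency (ties broken by entry order) and
    split into ``n_bins`` near-equal bins, the remainder going to the earliest
    (most frequent) bins.
    """
    n = len(words)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n < n_bins:
        raise MatchingError(f"{n} words cannot fill {n_bins} frequency bins")
    freqs = np.array([e.frequency for e in words], dtype=float)
    order = np.argsort(-freqs, kind="stable")
    base, extra = divmod(n, n_bins)
    bins = np.empty(n, dtype=int)
    pos = 0
    for b in range(1, n_bins + 1):
        size = base + (1 if b <= extra else 0)
        bins[order[pos : pos + size]] = b
        pos += size
    return bins


def build_matched_pairs(
    words: list[StimulusItem],
    nonword_pool: list[StimulusItem],
    tolerance: float = 0.25,
) -> list[tuple[StimulusItem, StimulusItem]]:
    """Greedily pair each word with its best score-matched nonword.

    Words are processed in the given order; each takes the unused pool
    nonword of equal phoneme length minimizing the absolute score difference,
    subject to the difference not exceeding ``tolerance`` (in mean-log2
    units).  The nonword inherits the word's frequency bin and pair id.
    """
    used = np.zeros(len(nonword_pool), dtype=bool)
    by_length: dict[int, list[int]] = {}
    for i, nw in enumerate(nonword_pool):
        by_length.setdefault(nw.length, []).append(i)
    pairs: list[tuple[StimulusItem, StimulusItem]] = []
    unmatched: list[str] = []
    for w_idx, word in enumerate(words):
        best_i, best_d = None, None
        for i in by_length.get(word.length, []):
            if used[i]:
                continue
            d = abs(nonword_pool[i].phonotactic_score - word.phonotactic_score)
            if d <= tolerance and (best_d is None or d < best_d):
                best_i, best_d = i, d
        if best_i is None:
            unmatched.append(word.form)
            continue
        used[best_i] = True
        pid = f"P{w_idx:05d}"
        w = replace(word, pair_id=pid)
        nw = replace(
            nonword_pool[best_i], pair_id=pid, frequency_bin=word.frequency_bin
        )
        pairs.append((w, nw))
    if unmatched:
        raise MatchingError(
            f"{len(unmatched)} word(s) unmatched within tolerance {tolerance}: "
            + ", ".join(unmatched[:20])
        )
    return pairs


def build_participant_list(
    pairs: list[tuple[StimulusItem, StimulusItem]],
    rng: np.random.Generator,
    per_bin: int = 30,
    n_bins: int = 5,
) -> list[StimulusItem]:
    """One participant's randomized stimulus list.

    Samples ``per_bin`` pairs per frequency bin without replacement, pools
    the words and nonwords, and shuffles them so paired items are not
    adjacent.  Default parameters give 2 * 30 * 5 = 300 items.
    """
    by_bin: dict[int, list[tuple[StimulusItem, StimulusItem]]] = {}
    for pair in pairs:
        by_bin.setdefault(pair[0].frequency_bin, []).append(pair)
    items: list[StimulusItem] = []
    for b in range(1, n_bins + 1):
        avail = by_bin.get(b, [])
        if len(avail) < per_bin:
            raise MatchingError(
                f"frequency bin {b} has {len(avail)} pairs, needs {per_bin}"
            )
        chosen = rng.choice(len(avail), size=per_bin, replace=False)
        for idx in chosen:
            items.extend(avail[idx])
    perm = rng.permutation(len(items))
    return [items[i] for i in perm]


def write_stimuli(items: list[StimulusItem], path) -> None:
    df = pd.DataFrame(
        {
            "pair_id": [it.pair_id for it in items],
            "form": [it.form for it in items],
            "is_word": [int(it.is_word) for it in items],
            "length": [it.length for it in items],
            "bin": [it.frequency_bin if it.frequency_bin is not None else "" for it in items],
            "score": [it.phonotactic_score for it in items],
        }
    )
    df.to_csv(path, index=False)


def read_stimuli(path, inv=None) -> list[StimulusItem]:
    from .phonology import tokenize_orthography

    df = pd.read_csv(path, keep_default_na=False)
    items = []
    for row in df.itertuples(index=False):
        ps = tokenize_orthography(str(row.form), inv)
        items.append(
            StimulusItem(
                form=str(row.form),
                phonemes=ps,
                is_word=bool(int(row.is_word)),
                phonotactic_score=float(row.score),
                length=len(ps),
                frequency_bin=int(row.bin) if str(row.bin) != "" else None,
                pair_id=str(row.pair_id) if str(row.pair_id) != "" else None,
            )
        )
    return items
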