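"""Trigram phonotactic models and stimulus scoring.

A phonotactic score is the mean log2 probability per trigram of a form under
a smoothed trigram model of phoneme sequences.  Models can be trained over
any weighted collection of sequences — dictionary types, frequency-weighted
token streams, or morph inventories — and forms can be scored either
*unparsed* (one padded sequence) or *parsed* (the best-scoring segmentation
into independently padded segments, found by dynamic programming).

Training counts accumulate over padded sequences: two start boundaries are
prepended and one end boundary appended, so word edges are first-class
phonotactic events.  Conditional probabilities use add-k smoothing,

    P(s | s2, s1) = (count(s2, s1, s) + k) / (count(s2, s1, .) + k * V),

with V the size of the outcome alphabet (all inventory symbols plus the end
boundary).  The outcome alphabet is always the full inventory, whether or
not vowel length was collapsed before training, so that collapsed and
uncollapsed models agree exactly on corpora without long vowels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .phonology import (
    PhonemeInventory,
    PhonemeString,
    collapse_vowel_length,
    default_inventory,
)

__all__ = [
    "TrigramModel",
    "PhonotacticScore",
    "train_trigram",
    "train_from_lexicon",
    "score_stimuli",
    "score_unparsed",
    "score_parsed",
    "standardize_scores",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class PhonotacticScore:
    """Mean log2 probability per trigram, with the trigram count it averages."""

    value: float
    n_trigrams: int


def _inventory_hash(inv: PhonemeInventory) -> str:
    payload = "\n".join(
        f"{s}\t{inv.orthography[s]}" for s in inv.symbol_order()
    ).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]


class TrigramModel:
    """Smoothed conditional probabilities of a phoneme given the two preceding.

    Counts are held densely: contexts range over inventory symbols plus the
    start boundary, outcomes over inventory symbols plus the end boundary.
    """

    def __init__(
        self,
        inventory: PhonemeInventory | None = None,
        smoothing_k: float = 0.01,
        collapsed: bool = False,
        counts: np.ndarray | None = None,
    ):
        if smoothing_k < 0:
            raise ValueError("smoothing_k must be nonnegative")
        self.inventory = inventory if inventory is not None else default_inventory()
        self.smoothing_k = float(smoothing_k)
        self.collapsed = bool(collapsed)
        self.symbols: tuple[str, ...] = tuple(self.inventory.symbol_order())
        self._id = {s: i for i, s in enumerate(self.symbols)}
        s = len(self.symbols)
        self.start_id = s  # context-only
        self.end_id = s  # outcome-only
        self.n_outcomes = s + 1  # V: symbols + end boundary
        shape = (s + 1, s + 1, s + 1)
        if counts is None:
            counts = np.zeros(shape)
        if counts.shape != shape:
            raise ValueError(f"counts must have shape {shape}")
        self.counts = counts
        self._logp: np.ndarray | None = None

    # -- encoding ---------------------------------------------------------

    def encode(self, ps: PhonemeString) -> np.ndarray:
        """Symbol ids of ``ps`` (after vowel-length collapse if the model is collapsed)."""
        if self.collapsed:
            ps = collapse_vowel_length(ps, self.inventory)
        try:
            return np.array([self._id[s] for s in ps.symbols], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"symbol {exc.args[0]!r} not in model inventory") from None

    def trigram_indices(self, ps: PhonemeString) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(s2, s1, outcome) id arrays for the padded sequence (length L+1)."""
        ids = self.encode(ps)
        padded = np.concatenate(([self.start_id, self.start_id], ids, [self.end_id]))
        return padded[:-2], padded[1:-1], padded[2:]

    # -- training ---------------------------------------------------------

    def add_sequence(self, ps: PhonemeString, weight: float = 1.0) -> None:
        if weight < 0:
            raise ValueError("weights must be nonnegative")
        i2, i1, out = self.trigram_indices(ps)
        np.add.at(self.counts, (i2, i1, out), weight)
        self._logp = None

    # -- probabilities ----------------------------------------------------

    def _log2_probs(self) -> np.ndarray:
        """Dense log2 conditional probability table (contexts x outcomes)."""
        if self._logp is None:
            k = self.smoothing_k
            ctx = self.counts.sum(axis=2, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                if k > 0:
                    self._logp = np.log2(self.counts + k) - np.log2(
                        ctx + k * self.n_outcomes
                    )
                else:
                    p = np.where(ctx > 0, self.counts / np.where(ctx > 0, ctx, 1.0), 0.0)
                    self._logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), -np.inf)
        return self._logp

    def prob(self, context: tuple[str, str], symbol: str) -> float:
        """P(symbol | context); boundary symbols name the padding events."""
        c2, c1 = (self._context_id(c) for c in context)
        out = (
            self.end_id
            if symbol == self.inventory.boundary_end
            else self._id[symbol]
        )
        return float(2.0 ** self._log2_probs()[c2, c1, out])

    def _context_id(self, symbol: str) -> int:
        if symbol == self.inventory.boundary_start:
            return self.start_id
        return self._id[symbol]

    def logprob_trigrams(self, ps: PhonemeString) -> np.ndarray:
        """Per-trigram log2 probabilities over the padded sequence (length L+1)."""
        i2, i1, out = self.trigram_indices(ps)
        return self._log2_probs()[i2, i1, out]


def train_trigram(
    source,
    inv: PhonemeInventory | None = None,
    smoothing_k: float = 0.01,
    collapsed: bool = False,
) -> TrigramModel:
    """Train a trigram model over weighted sequences.

    ``source`` is an iterable of ``(PhonemeString, weight)`` pairs, e.g. from
    :meth:`protolex.lexicon.Lexicon.sequences_and_weights`.  Weights must be
    nonnegative and not all zero.
    """
    model = TrigramModel(inv, smoothing_k=smoothing_k, collapsed=collapsed)
    total = 0.0
    n = 0
    for ps, w in source:
        model.add_sequence(ps, w)
        total += w
        n += 1
    if n == 0:
        raise ValueError("empty training source")
    if total <= 0:
        raise ValueError("training weights must not all be zero")
    return model


def train_from_lexicon(
    lexicon,
    weighting: str = "type",
    collapsed: bool = False,
    smoothing_k: float = 0.01,
) -> TrigramModel:
    """Train over a lexicon's types (``weighting='type'``) or its
    frequency-weighted token stream (``weighting='token'``)."""
    return train_trigram(
        lexicon.sequences_and_weights(weighting),
        lexicon.inventory,
        smoothing_k=smoothing_k,
        collapsed=collapsed,
    )


def score_stimuli(model: TrigramModel, phoneme_strings, parsed: bool = False) -> np.ndarray:
    """Phonotactic score values for a batch of forms (unparsed or best-parse)."""
    if parsed:
        return np.array([score_parsed(model, ps)[0].value for ps in phoneme_strings])
    return np.array([score_unparsed(model, ps).value for ps in phoneme_strings])


def score_unparsed(model: TrigramModel, ps: PhonemeString) -> PhonotacticScore:
    """Mean log2 trigram probability of the unsegmented padded form.

    With k = 0 an unseen trigram yields an explicit score of negative
    infinity rather than being dropped.
    """
    lp = model.logprob_trigrams(ps)
    return PhonotacticScore(value=float(lp.mean()), n_trigrams=lp.size)


def _segmentation_key(total: float, n_segments: int, lengths: tuple[int, ...]):
    """Sort key: higher total, then fewer segments, then leftmost-longest."""
    return (total, -n_segments, lengths)


def score_parsed(
    model: TrigramModel, ps: PhonemeString
) -> tuple[PhonotacticScore, tuple[PhonemeString, ...]]:
    """Best-segmentation score of a form under a morph-trained model.

    A dynamic program over split points maximizes the *total* log2
    probability, where each segment is scored as an independently padded
    sequence; the returned value divides that maximum by the total number of
    trigram terms across segments (phoneme length + number of segments).
    Ties break toward fewer segments, then leftmost-longest segments, so
    output is deterministic.
    """
    L = len(ps)
    ids_src = ps.symbols
    # segment log-probs for every (i, j) substring; L <= a dozen in practice
    seg_lp = {}
    for i in range(L):
        for j in range(i + 1, L + 1):
            sub = PhonemeString(ids_src[i:j], source_orthography="")
            seg_lp[(i, j)] = float(model.logprob_trigrams(sub).sum())
    # DP over prefixes; state = (total, n_segments, segment-length tuple)
    best: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, ())] + [None] * L
    for i in range(1, L + 1):
        cand_best = None
        for j in range(i):
            total_j, nseg_j, lens_j = best[j]
            cand = (total_j + seg_lp[(j, i)], nseg_j + 1, lens_j + (i - j,))
            if cand_best is None or _segmentation_key(*cand) > _segmentation_key(*cand_best):
                cand_best = cand
        best[i] = cand_best
    total, nseg, lengths = best[L]
    n_terms = L + nseg
    segments = []
    pos = 0
    for ln in lengths:
        segments.append(PhonemeString(ids_src[pos : pos + ln], source_orthography=""))
        pos += ln
    value = total / n_terms
    return PhonotacticScore(value=float(value), n_trigrams=n_terms), tuple(segments)


def standardize_scores(values) -> np.ndarray:
    """Z-score a set of phonotactic scores (mean 0, sd 1 within the set).

    Uses the population standard deviation; constant input is rejected since
    a degenerate predictor carries no information for the regressions.
    """
    x = np.asarray([v.value if isinstance(v, PhonotacticScore) else v for v in values], dtype=float)
    if x.size < 2:
        raise ValueError("need at least two scores to standardize")
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize constant or non-finite scores")
    return (x - x.mean()) / sd


def save_model(model: TrigramModel, path) -> None:
    """Plain-text trigram count table with a metadata header."""
    start, end = "<s>", "</s>"
    names = list(model.symbols) + [start]
    out_names = list(model.symbols) + [end]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# inventory_hash\t{_inventory_hash(model.inventory)}\n")
        fh.write(f"# smoothing_k\t{model.smoothing_k!r}\n")
        fh.write(f"# collapsed\t{int(model.collapsed)}\n")
        fh.write("s2\ts1\ts\tcount\n")
        nz = np.argwhere(model.counts > 0)
        for a, b, c in nz:
            fh.write(
                f"{names[a]}\t{names[b]}\t{out_names[c]}\t"
                f"{float(model.counts[a, b, c])!r}\n"
            )


def load_model(path, inv: PhonemeInventory | None = None) -> TrigramModel:
    if inv is None:
        inv = default_inventory()
    meta = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, val = line[2:].split("\t")
                meta[key] = val
            elif line and not line.startswith("s2\t"):
                rows.append(line.split("\t"))
    if meta.get("inventory_hash") != _inventory_hash(inv):
        raise ValueError("model was saved under a different phoneme inventory")
    model = TrigramModel(
        inv,
        smoothing_k=float(meta["smoothing_k"]),
        collapsed=bool(int(meta["collapsed"])),
    )
    start, end = "<s>", "</s>"
    for a, b, c, w in rows:
        ia = model.start_id if a == start else model._id[a]
        ib = model.start_id if b == start else model._id[b]
        ic = model.end_id if c == end else model._id[c]
        model.counts[ia, ib, ic] += float(w)
    return model
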