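import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protolex.phonology import PhonemeString, default_inventory, tokenize_orthography as tok
from protolex.phonotactics import (
    PhonotacticScore,
    TrigramModel,
    load_model,
    save_model,
    score_parsed,
    score_stimuli,
    score_unparsed,
    standardize_scores,
    train_from_lexicon,
    train_trigram,
    _segmentation_key,
)

START, END = "<", ">"


def hand_counts(corpus):
    """Independent trigram oracle: literal padded counts and ratio probabilities."""
    counts = {}
    ctx = {}
    for word, w in corpus:
        seq = [START, START] + list(tok(word).symbols) + [END]
        for i in range(2, len(seq)):
            tri = (seq[i - 2], seq[i - 1], seq[i])
            counts[tri] = counts.get(tri, 0.0) + w
            ctx[tri[:2]] = ctx.get(tri[:2], 0.0) + w
    return {tri: c / ctx[tri[:2]] for tri, c in counts.items()}


TOY_CORPORA = [
    [("a", 1.0)],
    [("a", 1.0), ("e", 1.0)],
    [("kai", 2.0), ("kau", 1.0), ("tai", 1.0), ("whātai", 3.0), ("ngā", 1.0)],
]


@pytest.mark.parametrize("corpus", TOY_CORPORA)
def test_trigram_probabilities_match_hand_counts(corpus):
    model = train_trigram([(tok(w), f) for w, f in corpus], smoothing_k=0.0)
    for (s2, s1, s), p in hand_counts(corpus).items():
        assert model.prob((s2, s1), s) == pytest.approx(p, abs=1e-12)


@pytest.mark.parametrize("corpus", TOY_CORPORA)
def test_smoothed_context_distributions_sum_to_one(corpus):
    model = train_trigram([(tok(w), f) for w, f in corpus], smoothing_k=0.5)
    probs = 2.0 ** model._log2_probs()
    sums = probs.sum(axis=2)
    assert np.allclose(sums, 1.0, atol=1e-12)


def test_two_singleton_words_split_start_probability():
    model = train_trigram([(tok("a"), 1.0), (tok("e"), 1.0)], smoothing_k=0.0)
    assert model.prob((START, START), "a") == pytest.approx(0.5)
    assert model.prob((START, START), "e") == pytest.approx(0.5)
    assert model.prob((START, "a"), END) == pytest.approx(1.0)


def test_score_unparsed_examples():
    m1 = train_trigram([(tok("a"), 1.0)], smoothing_k=0.0)
    assert score_unparsed(m1, tok("a")) == PhonotacticScore(0.0, 2)
    m2 = train_trigram([(tok("a"), 1.0), (tok("e"), 1.0)], smoothing_k=0.0)
    assert score_unparsed(m2, tok("a")).value == pytest.approx(-0.5)
    assert score_unparsed(m2, tok("e")).value == pytest.approx(-0.5)


def test_unseen_trigram_is_explicit_negative_infinity():
    model = train_trigram([(tok("kai"), 1.0)], smoothing_k=0.0)
    assert score_unparsed(model, tok("tai")).value == -np.inf
    smoothed = train_trigram([(tok("kai"), 1.0)], smoothing_k=0.01)
    assert np.isfinite(score_unparsed(smoothed, tok("tai")).value)


def brute_force_parse(model, ps):
    """Exhaustive oracle over all 2^(L-1) split patterns, same tie-break key."""
    L = len(ps)
    best = None
    for mask in range(2 ** (L - 1)):
        cuts = [0] + [i for i in range(1, L) if mask & (1 << (i - 1))] + [L]
        total = 0.0
        lengths = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            seg = PhonemeString(ps.symbols[a:b], "")
            total += float(model.logprob_trigrams(seg).sum())
            lengths.append(b - a)
        cand = (total, len(lengths), tuple(lengths))
        if best is None or _segmentation_key(*cand) > _segmentation_key(*best):
            best = cand
    total, nseg, lengths = best
    return total / (L + nseg), lengths


@pytest.fixture(scope="module")
def morph_model(small_lexicon):
    from protolex.lexicon import morph_inventory

    return train_from_lexicon(morph_inventory(small_lexicon), smoothing_k=0.01)


def test_parsed_matches_brute_force(morph_model, rng):
    inv = default_inventory()
    symbols = sorted(inv.symbols)
    for trial in range(60):
        L = int(rng.integers(1, 9))
        ps = PhonemeString(tuple(rng.choice(symbols, size=L)), "")
        score, segs = score_parsed(morph_model, ps)
        expected_value, expected_lengths = brute_force_parse(morph_model, ps)
        assert score.value == pytest.approx(expected_value, abs=1e-9)
        assert tuple(len(s) for s in segs) == expected_lengths


def test_parsed_single_symbol_equals_unparsed(morph_model):
    ps = PhonemeString(("a",), "")
    parsed, segs = score_parsed(morph_model, ps)
    assert parsed == score_unparsed(morph_model, ps)
    assert len(segs) == 1


def test_parsed_beats_unparsed_on_morph_concatenation(small_lexicon, morph_model):
    from protolex.lexicon import morph_inventory

    morphs = morph_inventory(small_lexicon)
    m1, m2 = morphs.entries[0], morphs.entries[1]
    ps = PhonemeString(m1.phonemes.symbols + m2.phonemes.symbols, "")
    parsed, _ = score_parsed(morph_model, ps)
    assert parsed.value >= score_unparsed(morph_model, ps).value - 1e-12


def test_trigram_monotonicity():
    base = [(tok("kai"), 1.0), (tok("tau"), 1.0)]
    extra_weights = [0.0, 0.5, 1.0, 4.0]
    probs = []
    for w in extra_weights:
        model = train_trigram(base + [(tok("kai"), w)], smoothing_k=0.1)
        probs.append(model.prob(("k", "a"), "i"))
    assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


def test_collapsed_equals_uncollapsed_without_long_vowels():
    corpus = [(tok("kai"), 2.0), (tok("pouaka"), 1.0), (tok("whenua"), 1.5)]
    plain = train_trigram(corpus, smoothing_k=0.2, collapsed=False)
    collapsed = train_trigram(corpus, smoothing_k=0.2, collapsed=True)
    for word in ["kai", "whenua", "noa", "pua"]:
        assert score_unparsed(plain, tok(word)).value == pytest.approx(
            score_unparsed(collapsed, tok(word)).value, abs=1e-12
        )


def test_collapsed_model_merges_vowel_length():
    corpus = [(tok("kā"), 1.0), (tok("ka"), 1.0)]
    collapsed = train_trigram(corpus, smoothing_k=0.0, collapsed=True)
    # both words collapse onto [k, a]: the short-vowel path carries all mass
    assert collapsed.prob(("<", "k"), "a") == pytest.approx(1.0)


def test_standardize_scores():
    out = standardize_scores([1.0, 3.0])
    assert out.tolist() == [-1.0, 1.0]
    x = np.random.default_rng(0).normal(size=50)
    z = standardize_scores(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(standardize_scores(3.0 * x + 7.0), z)
    with pytest.raises(ValueError):
        standardize_scores([2.0, 2.0, 2.0])


def test_model_save_load_roundtrip(tmp_path, small_lexicon):
    model = train_from_lexicon(small_lexicon, weighting="token", collapsed=True,
                               smoothing_k=0.05)
    path = tmp_path / "model.tsv"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.smoothing_k == model.smoothing_k
    assert loaded.collapsed == model.collapsed
    assert np.allclose(loaded.counts, model.counts)
    ps = small_lexicon.entries[0].phonemes
    assert score_unparsed(loaded, ps) == score_unparsed(model, ps)
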