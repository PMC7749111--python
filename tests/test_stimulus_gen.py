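import numpy as np
import pytest
from scipy import stats

from protolex.lexicon import Lexicon, LexiconEntry
from protolex.phonology import tokenize_orthography as tok, validate_legality
from protolex.phonotactics import train_from_lexicon
from protolex.stimulus_gen import (
    MatchingError,
    StimulusItem,
    assign_frequency_bins,
    build_matched_pairs,
    build_participant_list,
    generate_nonword,
    read_stimuli,
    write_stimuli,
)


@pytest.fixture(scope="module")
def word_model(small_lexicon):
    return train_from_lexicon(small_lexicon, smoothing_k=0.01, collapsed=True)


def test_generate_nonword_postconditions(word_model, small_lexicon, rng):
    exclusions = set(small_lexicon.forms)
    for length in (3, 5, 7):
        for _ in range(50):
            ps = generate_nonword(word_model, length, exclusions, rng)
            assert len(ps) == length
            assert validate_legality(ps)
            assert ps.source_orthography not in exclusions
            exclusions.add(ps.source_orthography)


def test_generate_nonword_deterministic(word_model, small_lexicon):
    excl = set(small_lexicon.forms)
    a = [
        generate_nonword(word_model, 5, excl, np.random.default_rng(7)).source_orthography
        for _ in range(1)
    ]
    b = [
        generate_nonword(word_model, 5, excl, np.random.default_rng(7)).source_orthography
        for _ in range(1)
    ]
    assert a == b


def test_generate_nonword_budget_error(word_model):
    with pytest.raises(MatchingError, match="budget|attempts"):
        # length-1 nonwords are only the five vowels; exclude everything
        vowels = {"a", "e", "i", "o", "u", "ā", "ē", "ī", "ō", "ū"}
        generate_nonword(word_model, 1, vowels, np.random.default_rng(0),
                         max_attempts=200)


def make_words(freqs):
    forms = ["kai", "tau", "po", "ra", "miti", "nui", "hau", "wai", "ngata", "pea"]
    return Lexicon(
        [LexiconEntry(f, tok(f), fr) for f, fr in zip(forms, freqs)]
    )


def test_assign_frequency_bins_ranking():
    words = make_words([100, 90, 80, 70, 60, 50, 40, 30, 20, 10])
    bins = assign_frequency_bins(words, n_bins=5)
    assert bins.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]


def test_bin1_most_frequent_bin5_least_frequent(rng):
    freqs = rng.integers(1, 10_000, size=10).tolist()
    words = make_words(freqs)
    bins = assign_frequency_bins(words, n_bins=5)
    assert bins[int(np.argmax(freqs))] == 1
    assert bins[int(np.argmin(freqs))] == 5


def test_assign_frequency_bins_remainder_and_errors():
    words = make_words([7, 6, 5, 4, 3, 2, 1])
    bins = assign_frequency_bins(words, n_bins=5)
    assert np.bincount(bins, minlength=6)[1:].tolist() == [2, 2, 1, 1, 1]
    with pytest.raises(MatchingError):
        assign_frequency_bins(Lexicon(words.entries[:3]), n_bins=5)


def item(form, score, is_word, bin=None):
    ps = tok(form)
    return StimulusItem(form, ps, is_word, score, len(ps), frequency_bin=bin)


def test_matched_pairs_nearest_within_tolerance():
    words = [item("kai", -3.00, True, bin=1)]
    pool = [item("pau", -3.01, False), item("tou", -2.50, False)]
    pairs = build_matched_pairs(words, pool, tolerance=0.2)
    assert pairs[0][1].form == "pau"
    assert pairs[0][1].frequency_bin == 1
    assert pairs[0][0].pair_id == pairs[0][1].pair_id


def test_matched_pairs_zero_tolerance_error():
    words = [item("kai", -3.00, True, bin=1)]
    pool = [item("pau", -3.01, False)]
    with pytest.raises(MatchingError, match="kai"):
        build_matched_pairs(words, pool, tolerance=0.0)


def test_all_pairs_within_tolerance(e1_bundle):
    by_pair = {}
    for it in e1_bundle.stimuli:
        by_pair.setdefault(it.pair_id, []).append(it)
    tol = e1_bundle.ground_truth["matching_tolerance"]
    for pid, pair in by_pair.items():
        assert len(pair) == 2
        w, nw = (pair[0], pair[1]) if pair[0].is_word else (pair[1], pair[0])
        assert w.is_word and not nw.is_word
        assert w.length == nw.length
        assert w.frequency_bin == nw.frequency_bin
        assert abs(w.phonotactic_score - nw.phonotactic_score) <= tol + 1e-12


def test_word_and_nonword_scores_overlap(e1_bundle):
    words = [it.phonotactic_score for it in e1_bundle.stimuli if it.is_word]
    nws = [it.phonotactic_score for it in e1_bundle.stimuli if not it.is_word]
    ks = stats.ks_2samp(words, nws).statistic
    assert ks < 0.2  # "span a similar range": matched sets nearly coincide


def test_participant_list_composition(e1_bundle, rng):
    pairs = []
    seen = {}
    for it in e1_bundle.stimuli:
        seen.setdefault(it.pair_id, []).append(it)
    for pid, pair in seen.items():
        w, nw = (pair[0], pair[1]) if pair[0].is_word else (pair[1], pair[0])
        pairs.append((w, nw))
    lst = build_participant_list(pairs, rng, per_bin=30, n_bins=5)
    assert len(lst) == 300
    assert sum(it.is_word for it in lst) == 150
    per_bin = {}
    for it in lst:
        per_bin[it.frequency_bin] = per_bin.get(it.frequency_bin, 0) + 1
    assert per_bin == {b: 60 for b in range(1, 6)}


def test_participant_list_seeding(e1_bundle):
    pairs = []
    seen = {}
    for it in e1_bundle.stimuli:
        seen.setdefault(it.pair_id, []).append(it)
    pairs = [tuple(p) for p in seen.values()]
    l1 = build_participant_list(pairs, np.random.default_rng(1))
    l2 = build_participant_list(pairs, np.random.default_rng(1))
    l3 = build_participant_list(pairs, np.random.default_rng(2))
    assert [it.form for it in l1] == [it.form for it in l2]
    assert [it.form for it in l1] != [it.form for it in l3]
    # different seeds still yield 60 items per bin
    per_bin = {}
    for it in l3:
        per_bin[it.frequency_bin] = per_bin.get(it.frequency_bin, 0) + 1
    assert set(per_bin.values()) == {60}


def test_participant_list_insufficient_pairs(rng):
    pairs = [(item("kai", -3.0, True, bin=1), item("pau", -3.0, False, bin=1))]
    with pytest.raises(MatchingError, match="bin"):
        build_participant_list(pairs, rng, per_bin=30)


def test_stimuli_file_roundtrip(tmp_path, e1_bundle):
    path = tmp_path / "stimuli.csv"
    write_stimuli(e1_bundle.stimuli, path)
    loaded = read_stimuli(path)
    assert [it.form for it in loaded] == [it.form for it in e1_bundle.stimuli]
    assert [it.frequency_bin for it in loaded] == [
        it.frequency_bin for it in e1_bundle.stimuli
    ]
    assert np.allclose(
        [it.phonotactic_score for it in loaded],
        [it.phonotactic_score for it in e1_bundle.stimuli],
    )
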