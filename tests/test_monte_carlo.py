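import numpy as np
import pandas as pd
import pytest

from protolex.lexicon import Lexicon, LexiconEntry
from protolex.monte_carlo import (
    SCHEMES,
    MonteCarloConfig,
    bootstrap_percentile_interval,
    run_monte_carlo,
    subsample,
    summarize_curves,
)
from protolex.phonology import tokenize_orthography as tok
from protolex.phonotactics import score_stimuli, standardize_scores, train_from_lexicon
from protolex.stimulus_gen import StimulusItem, generate_nonword
from protolex.synthetic import RaterSpec, simulate_ratings


@pytest.mark.parametrize("scheme", SCHEMES)
def test_subsample_saturation(small_lexicon, scheme, rng):
    sub = subsample(small_lexicon, len(small_lexicon), scheme, rng)
    assert sub == small_lexicon


def test_subsample_sizes_and_range(small_lexicon, rng):
    sub = subsample(small_lexicon, 10, "unweighted", rng)
    assert len(sub) == 10
    assert all(e.form in small_lexicon for e in sub)
    with pytest.raises(ValueError):
        subsample(small_lexicon, 0, "unweighted", rng)
    with pytest.raises(ValueError):
        subsample(small_lexicon, len(small_lexicon) + 1, "unweighted", rng)
    with pytest.raises(ValueError):
        subsample(small_lexicon, 5, "nonsense", rng)


def test_n_highest_frequency_deterministic(small_lexicon):
    a = subsample(small_lexicon, 25, "n_highest_frequency", np.random.default_rng(1))
    b = subsample(small_lexicon, 25, "n_highest_frequency", np.random.default_rng(99))
    assert a == b
    cutoff = min(e.frequency for e in a)
    outside = [e.frequency for e in small_lexicon if e.form not in a]
    assert max(outside) <= cutoff


def test_frequency_weighted_inclusion_probability():
    lex = Lexicon(
        [
            LexiconEntry("kai", tok("kai"), 99.0),
            LexiconEntry("po", tok("po"), 1.0),
            LexiconEntry("ra", tok("ra"), 1.0),
        ]
    )
    rng = np.random.default_rng(42)
    hits = sum(
        subsample(lex, 1, "frequency_weighted", rng).entries[0].form == "kai"
        for _ in range(10_000)
    )
    # exact inclusion probability 99/101 ~ 0.980
    assert hits / 10_000 == pytest.approx(99 / 101, abs=0.01)


@pytest.fixture(scope="module")
def mc_setup(small_lexicon):
    model = train_from_lexicon(small_lexicon, collapsed=True, smoothing_k=0.01)
    rng = np.random.default_rng(2024)
    excl = set(small_lexicon.forms)
    items = []
    for ln in [3, 4, 5, 6] * 15:
        ps = generate_nonword(model, ln, excl, rng)
        excl.add(ps.source_orthography)
        items.append(StimulusItem(ps.source_orthography, ps, False, 0.0, ln))
    z = standardize_scores(score_stimuli(model, [it.phonemes for it in items]))
    ratings = simulate_ratings(
        items,
        RaterSpec(slopes={"NMS": 1.5}, sigma_p=0.8, word_effect=0.0),
        {"NMS": 8},
        np.random.default_rng(7),
        z_scores=z,
    )
    return items, ratings


def test_run_monte_carlo_reproducible(small_lexicon, mc_setup):
    items, ratings = mc_setup
    cfg = MonteCarloConfig(sizes=(100,), schemes=("unweighted",), n_reps=2, seed=5)
    r1 = run_monte_carlo(small_lexicon, items, ratings, cfg)
    r2 = run_monte_carlo(small_lexicon, items, ratings, cfg)
    pd.testing.assert_frame_equal(r1.rows, r2.rows)
    assert len(r1.rows) == 2
    assert r1.rows["aic"].nunique() == 2  # random scheme varies across replicates


def test_full_size_equals_baseline(small_lexicon, mc_setup):
    items, ratings = mc_setup
    cfg = MonteCarloConfig(
        sizes=(len(small_lexicon),), schemes=SCHEMES, n_reps=2, seed=5
    )
    res = run_monte_carlo(small_lexicon, items, ratings, cfg)
    baseline = res.baselines["aic"].iloc[0]
    assert np.allclose(res.rows["aic"], baseline)


def test_scheme_variance_structure(small_lexicon, mc_setup):
    items, ratings = mc_setup
    cfg = MonteCarloConfig(sizes=(150,), schemes=SCHEMES, n_reps=4, seed=9)
    res = run_monte_carlo(small_lexicon, items, ratings, cfg)
    var = res.rows.groupby("scheme")["aic"].var()
    assert var["n_highest_frequency"] == pytest.approx(0.0, abs=1e-18)
    assert var["unweighted"] > 0
    assert var["frequency_weighted"] > 0


def test_bootstrap_interval_properties(rng):
    lo, hi = bootstrap_percentile_interval([3.0, 3.0, 3.0], rng=rng)
    assert lo == hi == 3.0
    x = rng.normal(size=400)
    lo, hi = bootstrap_percentile_interval(x, rng=rng)
    assert lo <= x.mean() <= hi
    with pytest.raises(ValueError):
        bootstrap_percentile_interval([1.0])


def test_bootstrap_interval_matches_normal_limit():
    rng = np.random.default_rng(3)
    x = rng.normal(size=1000)
    lo, hi = bootstrap_percentile_interval(x, n_boot=4000, rng=rng)
    half = (hi - lo) / 2
    assert half == pytest.approx(1.96 / np.sqrt(1000), rel=0.2)


def test_summarize_curves(small_lexicon, mc_setup):
    items, ratings = mc_setup
    cfg = MonteCarloConfig(
        sizes=(150, len(small_lexicon)), schemes=("n_highest_frequency",), n_reps=1,
        seed=5,
    )
    res = run_monte_carlo(small_lexicon, items, ratings, cfg)
    summary = summarize_curves(res, seed=0)
    # single-replicate cells: mean equals the replicate value
    merged = summary.merge(res.rows, on=["scheme", "size", "group", "parsed"])
    assert np.allclose(merged["mean_aic"], merged["aic"])
    at_full = summary[summary["size"] == len(small_lexicon)]
    assert np.allclose(at_full["delta_baseline"], 0.0, atol=1e-9)
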