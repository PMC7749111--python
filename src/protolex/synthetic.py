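"""Synthetic language and rater simulation with known ground truth.

The real study materials (a proprietary dictionary word list and human
ratings) cannot be redistributed, so every pipeline stage here is exercised
on a synthetic stand-in with the same structure: a macron-marked CV-language
lexicon built by compounding a few thousand morphs, Zipfian token
frequencies, and 1-5 ratings drawn from a latent-utility model whose slope
on phonotactic score differs by participant group.

Morphs are sampled from a ground-truth trigram grammar over the shipped
inventory (legality-constrained, so every generated form is an open-syllable
sequence); words concatenate 1-3 morphs ("heavy use of compounding") and
keep their segmentations as ground truth.  Ratings follow the exact
proportional-odds generative model the fitters assume — latent utility

    u = alpha_p + beta_g * z(score) + delta * is_word + gamma * macron + eps,

with participant intercepts alpha_p ~ N(0, sigma_p^2) and standard-logistic
eps (a Gaussian-noise switch exists as a misspecification stressor) — so
parameter recovery is a well-posed check of the fitting machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import Lexicon, LexiconEntry, morph_inventory, write_lexicon
from .phonology import (
    PhonemeInventory,
    PhonemeString,
    default_inventory,
    detect_macron,
    tokenize_orthography,
    validate_legality,
)
from .phonotactics import (
    TrigramModel,
    score_stimuli,
    standardize_scores,
    train_from_lexicon,
)
from .stimulus_gen import (
    StimulusItem,
    assign_frequency_bins,
    build_matched_pairs,
    build_participant_list,
    generate_nonword,
    write_stimuli,
)

__all__ = [
    "LanguageSpec",
    "RaterSpec",
    "generate_language",
    "simulate_ratings",
    "Experiment1Config",
    "Experiment2Config",
    "make_experiment1_dataset",
    "make_experiment2_dataset",
]


@dataclass(frozen=True)
class LanguageSpec:
    """Parameters of the synthetic language generator.

    Scales anchor to the study language at a configurable fraction: the full
    setting is ~3,600 morphs compounding into ~18,700 word types; the default
    desk scale keeps the same shape at a fraction of the size.
    """

    n_morphs: int = 1200
    n_words: int = 4000
    morph_length_range: tuple[int, int] = (2, 5)
    compounding_probs: tuple[float, ...] = (0.50, 0.35, 0.15)  # P(1..3 morphs/word)
    zipf_exponent: float = 1.0
    morph_zipf_exponent: float = 0.8  # skew of morph reuse inside words
    long_vowel_weight: float = 0.25  # relative grammar weight of long vowels
    seed: int = 0

    def __post_init__(self):
        if self.n_morphs < 1 or self.n_words < 1:
            raise ValueError("n_morphs and n_words must be positive")
        if not np.isclose(sum(self.compounding_probs), 1.0):
            raise ValueError("compounding probabilities must sum to 1")


@dataclass(frozen=True)
class RaterSpec:
    """Generative parameters of the simulated ordinal raters.

    Group slopes default to beta_MS = beta_NMS = 1.5 and beta_US = 0.3 —
    the qualitative pattern of near-identical sharp slopes for exposed
    groups and a small slope for the unexposed group.  All magnitudes are
    synthetic defaults, not estimates.
    """

    slopes: dict = field(
        default_factory=lambda: {"NMS": 1.5, "MS": 1.5, "US": 0.3}
    )
    word_effect: float = 1.0  # delta: real words rated above matched nonwords
    macron_effect: float = 0.3  # gamma: visual-macron covariate
    sigma_p: float = 1.0  # between-participant intercept sd
    cutpoints: tuple[float, ...] = (-2.25, -0.75, 0.75, 2.25)
    parsed: bool = False  # whether the generative score is the parsed one
    exposure_coef: float = 0.0  # optional slope modulation by self-reported exposure
    noise: str = "logistic"  # "gaussian" available as a misspecification stressor

    def __post_init__(self):
        if self.sigma_p < 0:
            raise ValueError("sigma_p must be nonnegative")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cutpoints must be strictly increasing")
        if self.noise not in ("logistic", "gaussian"):
            raise ValueError("noise must be 'logistic' or 'gaussian'")


def _ground_truth_grammar(
    inv: PhonemeInventory, rng: np.random.Generator, long_vowel_weight: float
) -> TrigramModel:
    """A random legality-constrained trigram grammar to sample morphs from."""
    model = TrigramModel(inv, smoothing_k=0.0, collapsed=False)
    symbols = model.symbols
    consonant = np.array([s in inv.consonants for s in symbols])
    long_v = np.array([s in inv.long_vowels for s in symbols])
    S = len(symbols)
    # outcome weights per context; illegal continuations stay at zero
    w = rng.gamma(0.6, size=(S + 1, S + 1, S + 1))
    w[:, :, :S] *= np.where(long_v, long_vowel_weight, 1.0)[None, None, :]
    # no consonant (or end boundary) after a consonant
    w[:, consonant.nonzero()[0][:, None], np.append(consonant, True).nonzero()[0]] = 0.0
    # no immediate end at the very start (empty morph)
    w[model.start_id, model.start_id, model.end_id] = 0.0
    model.counts = w
    model._logp = None
    return model


def generate_language(spec: LanguageSpec, inv: PhonemeInventory | None = None) -> Lexicon:
    """Generate a segmented, Zipf-weighted lexicon with known ground truth.

    Morphs come from a random trigram grammar (rejection-sampled to the
    configured length range); words concatenate morphs drawn with Zipfian
    reuse probabilities; duplicate word forms merge (first segmentation
    kept); token frequencies follow a Zipf law over generation rank, so that
    earlier-generated words — built disproportionately from frequent morphs —
    are also the most frequent types.
    """
    if inv is None:
        inv = default_inventory()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    grammar = _ground_truth_grammar(inv, rng, spec.long_vowel_weight)
    lo, hi = spec.morph_length_range
    morphs: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 2000 * spec.n_morphs
    while len(morphs) < spec.n_morphs:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not generate {spec.n_morphs} distinct morphs in "
                f"{max_attempts} attempts; inventory too small for this many"
            )
        length = int(rng.integers(lo, hi + 1))
        try:
            ps = generate_nonword(grammar, length, seen, rng, max_attempts=50)
        except Exception:
            continue
        seen.add(ps.source_orthography)
        morphs.append(ps.source_orthography)

    morph_p = (1.0 + np.arange(spec.n_morphs)) ** -spec.morph_zipf_exponent
    morph_p /= morph_p.sum()
    n_per_word = np.arange(1, len(spec.compounding_probs) + 1)

    forms: list[str] = []
    segs: list[tuple[str, ...]] = []
    known: set[str] = set()
    attempts = 0
    max_attempts = 50 * spec.n_words
    while len(forms) < spec.n_words and attempts < max_attempts:
        attempts += 1
        k = int(rng.choice(n_per_word, p=spec.compounding_probs))
        idx = rng.choice(spec.n_morphs, size=k, p=morph_p, replace=True)
        seg = tuple(morphs[i] for i in idx)
        form = "".join(seg)
        if form in known:
            continue
        known.add(form)
        forms.append(form)
        segs.append(seg)

    n = len(forms)
    scale = 10.0 * n  # most frequent type ~10n tokens => rank-n type ~10
    freqs = np.maximum(1, np.round(scale * (1.0 + np.arange(n)) ** -spec.zipf_exponent))
    entries = [
        LexiconEntry(
            form=f,
            phonemes=tokenize_orthography(f, inv),
            frequency=float(fr),
            segmentation=s,
        )
        for f, s, fr in zip(forms, segs, freqs)
    ]
    lex = Lexicon(entries, inv)
    for e in lex.entries:
        assert validate_legality(e.phonemes, inv)
    return lex


def simulate_ratings(
    stimuli: list[StimulusItem],
    spec: RaterSpec,
    n_per_group: dict[str, int],
    rng: np.random.Generator,
    z_scores: np.ndarray | None = None,
    participant_lists: dict[str, list[StimulusItem]] | None = None,
) -> pd.DataFrame:
    """Draw an ordinal ratings table from the latent-utility model.

    Every participant rates every stimulus unless ``participant_lists``
    assigns each participant id its own list.  ``z_scores`` (aligned with
    ``stimuli``) are the generative standardized phonotactic scores; when
    omitted they are standardized from the items' stored scores.
    """
    if z_scores is None:
        z_scores = standardize_scores([it.phonotactic_score for it in stimuli])
    z_by_form = {it.form: z for it, z in zip(stimuli, z_scores)}
    meta_by_form = {
        it.form: (it.is_word, it.frequency_bin, detect_macron(it.form))
        for it in stimuli
    }
    tau = np.asarray(spec.cutpoints)
    rows = []
    for group, n_p in n_per_group.items():
        beta_g = spec.slopes[group]
        for j in range(n_p):
            pid = f"{group}_{j:03d}"
            alpha = rng.normal(0.0, spec.sigma_p)
            exposure = float(rng.uniform(0.0, 1.0))
            items = (
                participant_lists[pid] if participant_lists is not None else stimuli
            )
            m = len(items)
            if spec.noise == "logistic":
                eps = rng.logistic(0.0, 1.0, size=m)
            else:
                eps = rng.normal(0.0, np.pi / np.sqrt(3.0), size=m)
            for it, e in zip(items, eps):
                z = z_by_form[it.form]
                is_word, fbin, macron = meta_by_form[it.form]
                slope = beta_g + spec.exposure_coef * exposure
                u = (
                    alpha
                    + slope * z
                    + spec.word_effect * float(is_word)
                    + spec.macron_effect * float(macron)
                    + e
                )
                rating = 1 + int(np.sum(u > tau))
                rows.append(
                    (pid, group, it.form, rating, z, int(is_word),
                     fbin if fbin is not None else -1, int(macron), exposure)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "group", "form", "rating", "z_score",
            "is_word", "bin", "macron", "exposure",
        ],
    )


# ---------------------------------------------------------------------------
# end-to-end dataset bundles


@dataclass(frozen=True)
class Experiment1Config:
    """Word-identification bundle: matched word/nonword pairs in 5 bins.

    The desk scale uses 200 word/nonword pairs; ``full_scale`` switches to
    the full 1,000 + 1,000 stimulus set.
    """

    language: LanguageSpec = LanguageSpec()
    raters: RaterSpec = RaterSpec(slopes={"NMS": 1.5})
    n_pairs: int = 200
    full_scale: bool = False
    n_participants: int = 20
    per_bin: int = 30
    n_bins: int = 5
    length_range: tuple[int, int] = (3, 12)
    matching_tolerance: float = 0.25
    smoothing_k: float = 0.01
    collapsed: bool = True
    seed: int = 0


@dataclass(frozen=True)
class Experiment2Config:
    """Well-formedness bundle: nonwords of single lengths, three groups.

    Desk scale uses 40 nonwords per length 3-8; ``full_scale`` uses the
    published per-length counts (240 or 320).  Desk participant counts keep
    the study's NMS:MS:US ratio at reduced scale.
    """

    language: LanguageSpec = LanguageSpec()
    raters: RaterSpec = RaterSpec()
    lengths: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    n_per_length: int = 40
    full_scale: bool = False
    n_participants: dict = field(
        default_factory=lambda: {"NMS": 30, "MS": 12, "US": 24}
    )
    source: str = "types"  # generative score source: types | tokens | morphs
    smoothing_k: float = 0.01
    collapsed: bool = True
    seed: int = 0


@dataclass
class Bundle:
    lexicon: Lexicon
    morphs: Lexicon
    stimuli: list[StimulusItem]
    z_scores: np.ndarray
    ratings: pd.DataFrame
    ground_truth: dict


def _write_bundle(bundle: Bundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_lexicon(bundle.lexicon, out / "lexicon.tsv")
    write_lexicon(bundle.morphs, out / "morphs.tsv")
    write_stimuli(bundle.stimuli, out / "stimuli.csv")
    bundle.ratings.to_csv(out / "ratings.csv", index=False)
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.ground_truth, fh, indent=2, sort_keys=True)


def _stimulus_model(lex: Lexicon, cfg) -> TrigramModel:
    return train_from_lexicon(
        lex, weighting="type", collapsed=cfg.collapsed, smoothing_k=cfg.smoothing_k
    )


def make_experiment1_dataset(
    config: Experiment1Config | None = None, out_dir=None
) -> Bundle:
    """Generate the full word-identification bundle with a known generator.

    Pipeline: synthetic language -> dictionary trigram model -> stratified
    word sample with frequency bins -> score-matched nonword pool ->
    per-participant randomized 300-item lists -> simulated ratings.
    """
    cfg = config if config is not None else Experiment1Config()
    n_pairs = 1000 if cfg.full_scale else cfg.n_pairs
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    lex = generate_language(cfg.language)
    morphs = morph_inventory(lex)
    model = _stimulus_model(lex, cfg)

    lo, hi = cfg.length_range
    eligible = [e for e in lex.entries if lo <= len(e.phonemes) <= hi]
    # trim score outliers: a word in the extreme tail of the phonotactic
    # distribution has no realistic chance of a sampled score-matched nonword
    all_scores = score_stimuli(model, [e.phonemes for e in eligible])
    s_lo, s_hi = np.percentile(all_scores, [1.0, 99.0])
    eligible = [e for e, s in zip(eligible, all_scores) if s_lo <= s <= s_hi]
    if len(eligible) < n_pairs:
        raise ValueError(f"only {len(eligible)} eligible words for {n_pairs} pairs")
    # stratified across the frequency ranking so all five bins are populated
    take = np.linspace(0, len(eligible) - 1, n_pairs).round().astype(int)
    chosen = [eligible[i] for i in sorted(set(take.tolist()))]
    sub = Lexicon(chosen, lex.inventory)
    bins = assign_frequency_bins(sub, cfg.n_bins)
    word_scores = score_stimuli(model, [e.phonemes for e in chosen])
    word_items = [
        StimulusItem(
            form=e.form, phonemes=e.phonemes, is_word=True,
            phonotactic_score=float(s), length=len(e.phonemes),
            frequency_bin=int(b),
        )
        for e, s, b in zip(chosen, word_scores, bins)
    ]

    pairs = None
    pool_factor = 4
    exclusions = set(lex.forms)
    pool_items: list[StimulusItem] = []
    for _ in range(3):  # enlarge the pool if matching fails
        length_cycle = [it.length for it in word_items]
        target = len(word_items) * pool_factor
        new_lengths = (length_cycle * pool_factor)[len(pool_items) : target]
        for ln in new_lengths:
            ps = generate_nonword(model, int(ln), exclusions, rng)
            exclusions.add(ps.source_orthography)
            pool_items.append(
                StimulusItem(
                    form=ps.source_orthography, phonemes=ps, is_word=False,
                    phonotactic_score=float(
                        score_stimuli(model, [ps])[0]
                    ),
                    length=len(ps),
                )
            )
        try:
            pairs = build_matched_pairs(word_items, pool_items, cfg.matching_tolerance)
            break
        except Exception:
            pool_factor *= 2
    if pairs is None:
        pairs = build_matched_pairs(word_items, pool_items, cfg.matching_tolerance)

    stimuli = [it for pair in pairs for it in pair]
    z = standardize_scores([it.phonotactic_score for it in stimuli])
    lists = {}
    groups = list(cfg.raters.slopes)
    n_per_group = {g: cfg.n_participants for g in groups}
    for g in groups:
        for j in range(cfg.n_participants):
            lists[f"{g}_{j:03d}"] = build_participant_list(
                pairs, rng, per_bin=cfg.per_bin, n_bins=cfg.n_bins
            )
    ratings = simulate_ratings(
        stimuli, cfg.raters, n_per_group, rng, z_scores=z, participant_lists=lists
    )
    gt = {
        "experiment": 1,
        "seed": cfg.seed,
        "language": asdict(cfg.language),
        "raters": asdict(cfg.raters),
        "n_pairs": n_pairs,
        "per_bin": cfg.per_bin,
        "n_bins": cfg.n_bins,
        "matching_tolerance": cfg.matching_tolerance,
        "smoothing_k": cfg.smoothing_k,
        "collapsed": cfg.collapsed,
        "score_source": "types",
        "n_participants": n_per_group,
    }
    bundle = Bundle(lex, morphs, stimuli, z, ratings, gt)
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def make_experiment2_dataset(
    config: Experiment2Config | None = None, out_dir=None
) -> Bundle:
    """Generate the well-formedness bundle (nonwords only, three groups)."""
    cfg = config if config is not None else Experiment2Config()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    lex = generate_language(cfg.language)
    morphs = morph_inventory(lex)
    gen_model = _stimulus_model(lex, cfg)

    per_length = {3: 240, 4: 320, 5: 320, 6: 320, 7: 320, 8: 240} if cfg.full_scale else {
        ln: cfg.n_per_length for ln in cfg.lengths
    }
    exclusions = set(lex.forms)
    items: list[StimulusItem] = []
    for ln in cfg.lengths:
        for _ in range(per_length[ln]):
            ps = generate_nonword(gen_model, ln, exclusions, rng)
            exclusions.add(ps.source_orthography)
            items.append(
                StimulusItem(
                    form=ps.source_orthography, phonemes=ps, is_word=False,
                    phonotactic_score=0.0, length=ln,
                )
            )

    if cfg.source == "types":
        src_model, parsed = gen_model, False
    elif cfg.source == "tokens":
        src_model = train_from_lexicon(
            lex, weighting="token", collapsed=cfg.collapsed, smoothing_k=cfg.smoothing_k
        )
        parsed = False
    elif cfg.source == "morphs":
        src_model = train_from_lexicon(
            morphs, weighting="type", collapsed=cfg.collapsed,
            smoothing_k=cfg.smoothing_k,
        )
        parsed = True
    else:
        raise ValueError(f"unknown score source {cfg.source!r}")
    values = score_stimuli(src_model, [it.phonemes for it in items], parsed=parsed)
    from dataclasses import replace as _replace

    items = [
        _replace(it, phonotactic_score=float(v)) for it, v in zip(items, values)
    ]
    z = standardize_scores(values)
    ratings = simulate_ratings(items, cfg.raters, cfg.n_participants, rng, z_scores=z)
    gt = {
        "experiment": 2,
        "seed": cfg.seed,
        "language": asdict(cfg.language),
        "raters": asdict(cfg.raters),
        "lengths": list(cfg.lengths),
        "per_length": {str(k): v for k, v in per_length.items()},
        "score_source": cfg.source,
        "parsed": parsed,
        "smoothing_k": cfg.smoothing_k,
        "collapsed": cfg.collapsed,
        "n_participants": dict(cfg.n_participants),
    }
    bundle = Bundle(lex, morphs, items, z, ratings, gt)
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle
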