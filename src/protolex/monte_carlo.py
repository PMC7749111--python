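"""Monte Carlo lexicon subsampling with AIC model comparison.

How small can the vocabulary behind someone's phonotactic knowledge be?
Repeatedly subsample a lexicon (or morph set) at a range of sizes under
three schemes — uniform over types, frequency-weighted, or deterministically
the N most frequent types — retrain the trigram phonotactics on each
subsample, rescore the stimuli, refit the per-group ordinal regressions,
and collate the AIC of each fit against the full-source baseline, with
bootstrap percentile intervals across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .ordinal import OrdinalFitError, fit_clm
from .phonotactics import score_stimuli, standardize_scores, train_from_lexicon

__all__ = [
    "SCHEMES",
    "MonteCarloConfig",
    "MonteCarloResult",
    "subsample",
    "run_monte_carlo",
    "bootstrap_percentile_interval",
    "summarize_curves",
]

log = logging.getLogger(__name__)

SCHEMES = ("unweighted", "frequency_weighted", "n_highest_frequency")


def subsample(
    source: Lexicon, size: int, scheme: str, rng: np.random.Generator | None = None
) -> Lexicon:
    """A vocabulary (type set) of ``size`` entries drawn under a scheme.

    ``unweighted`` samples types uniformly without replacement;
    ``frequency_weighted`` samples without replacement with inclusion
    biased toward frequent types (sequential weighted sampling, implemented
    via exponential sort keys); ``n_highest_frequency`` deterministically
    takes the top ``size`` types by frequency (ties broken by entry order).
    """
    n = len(source)
    if not 1 <= size <= n:
        raise ValueError(f"size {size} out of range 1..{n}")
    if scheme == "n_highest_frequency":
        freqs = np.array([e.frequency for e in source.entries])
        order = np.argsort(-freqs, kind="stable")[:size]
        keep = np.sort(order)
    elif scheme == "unweighted":
        if rng is None:
            raise ValueError("random schemes need an rng")
        keep = np.sort(rng.choice(n, size=size, replace=False))
    elif scheme == "frequency_weighted":
        if rng is None:
            raise ValueError("random schemes need an rng")
        w = np.array([e.frequency for e in source.entries], dtype=float)
        if np.any(w <= 0):
            w = np.maximum(w, 1e-12)
        # Efraimidis-Spirakis keys: smallest Exp(1)/w first == sequential
        # weighted sampling without replacement proportional to frequency
        keys = rng.exponential(size=n) / w
        keep = np.sort(np.argsort(keys, kind="stable")[:size])
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    return Lexicon([source.entries[i] for i in keep], source.inventory)


@dataclass(frozen=True)
class MonteCarloConfig:
    """Desk-scale defaults; the published protocol used 1,000 replicates."""

    sizes: tuple[int, ...]
    schemes: tuple[str, ...] = SCHEMES
    n_reps: int = 100
    groups: tuple[str, ...] = ("NMS",)
    parsed: tuple[bool, ...] = (False,)
    seed: int = 0
    smoothing_k: float = 0.01
    collapsed: bool = True
    weighting: str = "type"
    max_failure_rate: float = 0.05


@dataclass
class MonteCarloResult:
    rows: pd.DataFrame  # scheme, size, replicate, group, parsed, aic
    baselines: pd.DataFrame  # group, parsed, aic (full source)
    config: MonteCarloConfig = None


def _fit_aic(ratings_g: pd.DataFrame) -> float:
    fit = fit_clm(ratings_g, ["z_score"])
    return fit.aic


def run_monte_carlo(
    source: Lexicon,
    stimuli,
    ratings: pd.DataFrame,
    config: MonteCarloConfig,
) -> MonteCarloResult:
    """Subsample -> retrain -> rescore -> refit, over the full design grid.

    ``stimuli`` is a list of items with ``form`` and ``phonemes`` attributes
    covering every form in ``ratings``.  Replicate seeds derive from the
    master seed by a counter-based scheme, so results are bit-for-bit
    reproducible and could be computed in any order.  A replicate whose fit
    fails is recorded as NaN; more than ``max_failure_rate`` failures in any
    cell aborts with diagnostics.
    """
    forms = [it.form for it in stimuli]
    phonemes = [it.phonemes for it in stimuli]
    pos = {f: i for i, f in enumerate(forms)}
    missing = set(ratings["form"]) - set(forms)
    if missing:
        raise ValueError(f"ratings reference unscored stimuli: {sorted(missing)[:5]}")
    group_tables = {}
    for g in config.groups:
        tg = ratings[ratings["group"] == g].copy()
        if tg.empty:
            raise ValueError(f"no ratings for group {g!r}")
        group_tables[g] = (tg, np.array([pos[f] for f in tg["form"]]))

    def aics_for_model(model, parsed_flag):
        values = score_stimuli(model, phonemes, parsed=parsed_flag)
        z = standardize_scores(values)
        out = {}
        for g, (tg, idx) in group_tables.items():
            tg["z_score"] = z[idx]
            try:
                out[g] = _fit_aic(tg)
            except (OrdinalFitError, ValueError) as exc:
                log.warning("fit failure for group %s: %s", g, exc)
                out[g] = np.nan
        return out

    baselines = []
    for parsed_flag in config.parsed:
        full_model = train_from_lexicon(
            source, config.weighting, config.collapsed, config.smoothing_k
        )
        for g, aic in aics_for_model(full_model, parsed_flag).items():
            baselines.append((g, parsed_flag, aic))

    rows = []
    for si, scheme in enumerate(config.schemes):
        for zi, size in enumerate(config.sizes):
            n_fail = 0
            n_cell = 0
            for rep in range(config.n_reps):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=config.seed, spawn_key=(si, zi, rep))
                )
                sub = subsample(source, size, scheme, rng)
                model = train_from_lexicon(
                    sub, config.weighting, config.collapsed, config.smoothing_k
                )
                for parsed_flag in config.parsed:
                    for g, aic in aics_for_model(model, parsed_flag).items():
                        rows.append((scheme, size, rep, g, parsed_flag, aic))
                        n_cell += 1
                        n_fail += int(np.isnan(aic))
            if n_cell and n_fail / n_cell > config.max_failure_rate:
                raise RuntimeError(
                    f"{n_fail}/{n_cell} fit failures in cell "
                    f"(scheme={scheme}, size={size}); aborting"
                )
            log.info("scheme=%s size=%d done (%d reps)", scheme, size, config.n_reps)
    return MonteCarloResult(
        rows=pd.DataFrame(
            rows, columns=["scheme", "size", "replicate", "group", "parsed", "aic"]
        ),
        baselines=pd.DataFrame(baselines, columns=["group", "parsed", "aic"]),
        config=config,
    )


def bootstrap_percentile_interval(
    values,
    level: float = 0.95,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile interval of the mean over bootstrap resamples."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least two finite values")
    if rng is None:
        rng = np.random.default_rng(0)
    means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def summarize_curves(
    result: MonteCarloResult,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean AIC with bootstrap intervals and delta to the full-source baseline,
    per (scheme, size, group, parsed) cell — the plot data behind the AIC
    curves."""
    base = {
        (r.group, r.parsed): r.aic for r in result.baselines.itertuples(index=False)
    }
    out = []
    grouped = result.rows.groupby(["scheme", "size", "group", "parsed"], sort=True)
    for i, ((scheme, size, group, parsed), df) in enumerate(grouped):
        vals = df["aic"].to_numpy()
        finite = vals[np.isfinite(vals)]
        mean = float(finite.mean()) if finite.size else np.nan
        if finite.size >= 2:
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
            lo, hi = bootstrap_percentile_interval(finite, level, n_boot, rng)
        else:
            lo = hi = mean
        out.append(
            {
                "scheme": scheme,
                "size": size,
                "group": group,
                "parsed": parsed,
                "mean_aic": mean,
                "ci_low": lo,
                "ci_high": hi,
                "delta_baseline": mean - base[(group, parsed)],
                "n_finite": int(finite.size),
            }
        )
    return pd.DataFrame(out)
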