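import numpy as np
import pandas as pd
import pytest

from protolex.ordinal import (
    OrdinalFitError,
    build_design,
    compare_by_aic,
    fit_clm,
    fit_clmm,
    predict_probs,
)

TAU = np.array([-2.25, -0.75, 0.75, 2.25])


def simulate_clm(rng, n, beta, tau=TAU):
    z = rng.normal(size=n)
    u = beta * z + rng.logistic(size=n)
    y = 1 + (u[:, None] > tau).sum(axis=1)
    return pd.DataFrame({"rating": y, "z_score": z})


def simulate_clmm(rng, n_groups, n_items, beta, sigma, tau=TAU):
    frames = []
    for g in range(n_groups):
        df = simulate_clm(rng, n_items, beta, tau)
        alpha = rng.normal(0.0, sigma)
        u = alpha + beta * df["z_score"].to_numpy() + rng.logistic(size=n_items)
        df["rating"] = 1 + (u[:, None] > tau).sum(axis=1)
        df["participant_id"] = f"p{g:03d}"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def test_null_slope_within_3_se(rng):
    df = simulate_clm(rng, 4000, beta=0.0)
    fit = fit_clm(df, ["z_score"])
    beta = fit.coefficients["z_score"]
    assert abs(beta) < 3 * fit.se["z_score"]
    # cutpoints match the marginal cumulative logits at beta ~ 0
    props = df["rating"].value_counts(normalize=True).sort_index().cumsum()[:4]
    marginal = np.log(props / (1 - props))
    assert np.allclose(fit.cutpoints, marginal, atol=0.05)


def test_matches_statsmodels_ordered_model(rng):
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    df = simulate_clm(rng, 2000, beta=1.2)
    df["x2"] = rng.normal(size=len(df))
    fit = fit_clm(df, ["z_score", "x2"])
    sm = OrderedModel(df["rating"], df[["z_score", "x2"]], distr="logit").fit(
        method="bfgs", disp=0
    )
    assert fit.coefficients["z_score"] == pytest.approx(sm.params["z_score"], abs=1e-4)
    assert fit.coefficients["x2"] == pytest.approx(sm.params["x2"], abs=1e-4)
    assert fit.loglik == pytest.approx(sm.llf, abs=1e-4)


def test_duplicated_data_doubles_loglik(rng):
    df = simulate_clm(rng, 800, beta=1.0)
    fit1 = fit_clm(df, ["z_score"])
    fit2 = fit_clm(pd.concat([df, df], ignore_index=True), ["z_score"])
    assert fit2.coefficients["z_score"] == pytest.approx(
        fit1.coefficients["z_score"], abs=1e-5
    )
    assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-6)


def test_rank_deficiency_is_an_error(rng):
    df = simulate_clm(rng, 200, beta=1.0)
    df["copy"] = df["z_score"]
    with pytest.raises(OrdinalFitError, match="rank"):
        fit_clm(df, ["z_score", "copy"])


def test_loglik_trace_nondecreasing(rng):
    df = simulate_clm(rng, 2000, beta=1.5)
    fit = fit_clm(df, ["z_score"])
    trace = np.array(fit.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-8)


def test_predicted_probabilities_sum_to_one(rng):
    df = simulate_clm(rng, 500, beta=1.0)
    fit = fit_clm(df, ["z_score"])
    probs = predict_probs(fit, df, ["z_score"])
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(probs >= 0)


def test_design_interactions_and_categoricals(rng):
    df = pd.DataFrame(
        {
            "z_score": [0.5, -1.0, 2.0, 0.0, 1.1, -0.4, 0.9, -2.2],
            "group": ["MS", "NMS", "US", "NMS", "MS", "US", "NMS", "MS"],
        }
    )
    X, names = build_design(df, ["z_score", "group", "group:z_score"])
    assert names == [
        "z_score",
        "group[T.NMS]",
        "group[T.US]",
        "group[T.NMS]:z_score",
        "group[T.US]:z_score",
    ]
    assert X[1, 3] == pytest.approx(-1.0)  # NMS row: dummy * z
    assert X[2, 4] == pytest.approx(2.0)


def test_clmm_zero_variance_boundary(rng):
    df = simulate_clmm(rng, n_groups=30, n_items=200, beta=1.0, sigma=0.0)
    mixed = fit_clmm(df, ["z_score"])
    fixed = fit_clm(df, ["z_score"])
    assert mixed.sigma < 0.05
    assert mixed.coefficients["z_score"] == pytest.approx(
        fixed.coefficients["z_score"], abs=0.02
    )


def test_clmm_quadrature_refinement(rng):
    df = simulate_clmm(rng, n_groups=15, n_items=60, beta=1.2, sigma=0.8)
    f15 = fit_clmm(df, ["z_score"], n_quad=15)
    f31 = fit_clmm(df, ["z_score"], n_quad=31)
    assert abs(f15.loglik - f31.loglik) < 1e-3


def test_clmm_aic_counts_variance_parameter(rng):
    df = simulate_clmm(rng, n_groups=10, n_items=40, beta=1.0, sigma=0.7)
    mixed = fit_clmm(df, ["z_score"])
    assert mixed.n_params == 1 + 4 + 1  # slope + cutpoints + variance
    assert mixed.aic == pytest.approx(2 * mixed.n_params - 2 * mixed.loglik)


def test_compare_by_aic(rng):
    df = simulate_clm(rng, 1500, beta=1.5)
    df["noise"] = rng.normal(size=len(df))
    informative = fit_clm(df, ["z_score"])
    null_like = fit_clm(df, ["noise"])
    table = compare_by_aic({"informative": informative, "noise_only": null_like})
    assert table["model"].tolist() == ["informative", "noise_only"]
    assert table["delta_aic"].iloc[0] == 0.0
    same = compare_by_aic({"a": informative, "b": informative})
    assert np.allclose(same["delta_aic"], 0.0)


def test_compare_by_aic_rejects_mismatched_responses(rng):
    fit_a = fit_clm(simulate_clm(rng, 300, 1.0), ["z_score"])
    fit_b = fit_clm(simulate_clm(rng, 301, 1.0), ["z_score"])
    with pytest.raises(ValueError, match="response"):
        compare_by_aic({"a": fit_a, "b": fit_b})
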