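"""Mixed-model pipeline: designs, F tests, Satterthwaite df, post-hocs."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slipfreq.analysis import (
    DESIGNS,
    _RandomInterceptGLS,
    analyze_design,
    estimated_marginal_means,
    fit_mixed_model,
    get_contrast,
    long_format,
    partial_eta_sq,
    posthoc_tukey,
    select_representative_measure,
)
from slipfreq.measures import DEFAULT_PHONEME_MEASURE, DEFAULT_SYLLABLE_MEASURE
from slipfreq.simulate import david_scenario, run_pipeline


@pytest.fixture(scope="module")
def planted_table(sim_lexicon):
    table, cases, _ = run_pipeline(
        sim_lexicon, david_scenario(220, seed=6), controls_seed=17
    )
    return table


def test_partial_eta_sq_closed_form():
    assert partial_eta_sq(0.0, 1, 50) == 0.0
    assert partial_eta_sq(10.0, 1, 90) == pytest.approx(0.1)
    # monotone in F and bounded
    grid = [partial_eta_sq(F, 2, 40) for F in (0.5, 1, 5, 50, 5000)]
    assert all(0 <= v <= 1 for v in grid)
    assert grid == sorted(grid)
    with pytest.raises(ValueError):
        partial_eta_sq(-1.0, 1, 10)


def test_long_format_row_counts(planted_table):
    n_cases = planted_table["case"].nunique()
    frame_a = long_format(planted_table, "partial_A", "phoneme")
    assert len(frame_a) == 4 * n_cases  # 2 unit types x key/control
    frame_b = long_format(planted_table, "partial_B", "syllable")
    assert len(frame_b) == 6 * n_cases
    word_cases = planted_table.loc[
        (planted_table.unit_type == "error")
        & (planted_table.outcome == "word"), "case"
    ].nunique()
    frame_o = long_format(planted_table, "overall", "word")
    assert frame_o["case"].nunique() == word_cases
    assert len(frame_o) <= 6 * word_cases


def test_long_format_covariates_are_row_wise(planted_table):
    """A phoneme-level row carries the same condition row's syllable and
    word frequencies as covariates (not the key side's)."""
    frame = long_format(planted_table, "partial_A", "phoneme")
    merged = frame.merge(
        planted_table,
        on=["case", "unit_type", "key_control"],
        suffixes=("", "_orig"),
    )
    centered = merged["syllfreq_orig"] - merged["syllfreq_orig"].mean()
    assert np.allclose(merged["syllfreq"], centered, atol=1e-9)


def test_long_format_rejects_level_outside_design(planted_table):
    with pytest.raises(ValueError):
        long_format(planted_table, "partial_B", "word")


def test_zero_variance_equals_ols_ancova(planted_table):
    """With the random-intercept variance forced to zero, the Wald F on the
    GLS surface equals the OLS ANCOVA F."""
    import patsy
    import statsmodels.api as sm

    frame = long_format(planted_table, "partial_A", "phoneme").head(400)
    y, X = patsy.dmatrices(
        "y ~ C(unit_type, Sum) * C(key_control, Sum) + syllfreq", frame,
        return_type="dataframe",
    )
    groups = pd.factorize(frame["case"])[0]
    ols = sm.OLS(np.asarray(y).ravel(), np.asarray(X)).fit()
    gls = _RandomInterceptGLS(np.asarray(X), np.asarray(y).ravel(), groups)
    sigma2 = ols.ssr / ols.df_resid
    beta = gls.beta(0.0, sigma2)
    cov = gls.covbeta(0.0, sigma2)
    assert np.allclose(beta, ols.params, atol=1e-8)
    for j in range(1, X.shape[1]):
        t_mine = beta[j] / np.sqrt(cov[j, j])
        assert t_mine == pytest.approx(ols.tvalues[j], rel=1e-8)


def test_mixed_model_recovers_planted_interaction(planted_table):
    """Weak sources with strong targets: Key-Control x Unit-Type interaction
    plus a negative source-vs-control post-hoc contrast."""
    res = analyze_design(planted_table, "partial_A", "phoneme")
    anova = res.model.anova.set_index("effect")
    inter = anova.loc["C(unit_type, Sum):C(key_control, Sum)"]
    assert inter["p"] < 0.05
    ws = get_contrast(res.contrasts, "source:key", "source:control")
    assert ws["estimate"] < 0 and ws["p_tukey"] < 0.05
    david = get_contrast(res.contrasts, "source:key", "target:key")
    assert david["estimate"] < 0 and david["p_tukey"] < 0.05
    assert not res.model.singular
    # eta^2 recomputable from the table
    for _, row in res.model.anova.iterrows():
        assert row["partial_eta_sq"] == pytest.approx(
            partial_eta_sq(row["F"], row["df1"], row["df2"])
        )


def test_residual_df_fallback_agrees_on_f(planted_table):
    """F statistics carry the weight: identical under either df method."""
    frame = long_format(planted_table, "partial_A", "phoneme")
    sat = fit_mixed_model(frame, covariates=("syllfreq",), df_method="satterthwaite")
    res = fit_mixed_model(frame, covariates=("syllfreq",), df_method="residual")
    assert np.allclose(sat.anova["F"], res.anova["F"], rtol=1e-9)
    assert (res.anova["df2"] == res.residual_df).all()
    assert (sat.anova["df2"] <= res.residual_df + 1e-9).all()


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_satterthwaite_matches_lmertest(planted_table, tmp_path):
    """Independent oracle: lme4 + lmerTest on the same model frame."""
    frame = long_format(planted_table, "partial_A", "phoneme")
    csv = tmp_path / "frame.csv"
    frame.to_csv(csv, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        """
        suppressMessages({library(lme4); library(lmerTest)})
        d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
        d$unit_type <- factor(d$unit_type); d$key_control <- factor(d$key_control)
        contrasts(d$unit_type) <- contr.sum(nlevels(d$unit_type))
        contrasts(d$key_control) <- contr.sum(nlevels(d$key_control))
        m <- lmer(y ~ unit_type*key_control + wordfreq + syllfreq + underspec
                  + (1|case), data=d, REML=TRUE)
        a <- anova(m, type=3)
        write.csv(data.frame(term=rownames(a), F=a$`F value`, df2=a$DenDF), stdout(),
                  row.names=FALSE)
        """
    )
    out = subprocess.run(
        ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
    )
    lines = [l for l in out.stdout.splitlines() if "," in l]
    oracle = pd.read_csv(pd.io.common.StringIO("\n".join(lines)))
    res = fit_mixed_model(frame, covariates=("wordfreq", "syllfreq", "underspec"))
    name_map = {
        "unit_type": "C(unit_type, Sum)",
        "key_control": "C(key_control, Sum)",
        "unit_type:key_control": "C(unit_type, Sum):C(key_control, Sum)",
        "wordfreq": "wordfreq",
        "syllfreq": "syllfreq",
        "underspec": "underspec",
    }
    mine = res.anova.set_index("effect")
    for _, row in oracle.iterrows():
        ours = mine.loc[name_map[row["term"]]]
        assert ours["F"] == pytest.approx(row["F"], rel=1e-4)
        assert ours["df2"] == pytest.approx(row["df2"], rel=0.02)


def test_tukey_identical_cell_means():
    rng = np.random.default_rng(5)
    n = 120
    frame = pd.DataFrame(
        {
            "case": np.repeat(np.arange(n // 4), 4),
            "unit_type": np.tile(["target", "target", "source", "source"], n // 4),
            "key_control": np.tile(["key", "control"], n // 2),
        }
    )
    frame["y"] = rng.normal(size=n)  # no structure at all
    res = fit_mixed_model(frame, covariates=(), df_method="residual")
    beta = res.beta.copy()
    beta[beta.index != "Intercept"] = 0.0
    res.beta = beta  # force exactly equal cell means
    posthocs = posthoc_tukey(res)
    assert np.allclose(posthocs["estimate"], 0)
    assert (posthocs["p_tukey"] > 0.999).all()


def test_tukey_two_cell_family_equals_t_test():
    """With k = 2 cells the studentized-range correction vanishes."""
    rng = np.random.default_rng(11)
    n_case = 80
    d = pd.DataFrame(
        {
            "case": np.repeat(np.arange(n_case), 2),
            "unit_type": "source",
            "key_control": np.tile(["key", "control"], n_case),
        }
    )
    d["y"] = rng.normal(size=len(d)) + (d["key_control"] == "key") * 0.3
    res = fit_mixed_model(d, covariates=(), df_method="residual")
    posthocs = posthoc_tukey(res)
    assert len(posthocs) == 1
    row = posthocs.iloc[0]
    p_t = 2 * stats.t.sf(abs(row["t"]), row["df"])
    assert row["p_tukey"] == pytest.approx(p_t, rel=1e-6)
    assert row["p_tukey"] >= p_t - 1e-12  # adjusted never below unadjusted


def test_emmeans_average_at_covariate_means(planted_table):
    res = analyze_design(planted_table, "partial_A", "syllable")
    emm = res.emmeans
    assert len(emm) == 4
    # grand mean of the cell means tracks the grand mean of the outcome
    frame = long_format(planted_table, "partial_A", "syllable")
    cell = frame.groupby(["unit_type", "key_control"])["y"].mean()
    assert emm["emmean"].mean() == pytest.approx(cell.mean(), abs=0.05)


def test_design_specs():
    assert DESIGNS["overall"].word_outcomes_only
    assert DESIGNS["partial_A"].unit_types == ("target", "source")
    assert DESIGNS["partial_B"].levels == ("syllable", "phoneme")
    assert "wordfreq" not in DESIGNS["partial_B"].covariates["phoneme"]


def test_select_representative_measure(planted_table):
    pinned = select_representative_measure(planted_table, "syllable", pin_default=True)
    assert pinned == DEFAULT_SYLLABLE_MEASURE
    assert select_representative_measure(
        planted_table, "phoneme", pin_default=True
    ) == DEFAULT_PHONEME_MEASURE
    chosen = select_representative_measure(planted_table, "syllable")
    assert chosen.level == "syllable"
    # duplicated dominant family: PC1 must pick it
    rng = np.random.default_rng(0)
    from slipfreq.measures import SYLLABLE_MEASURES

    n = 400
    latent = rng.lognormal(3, 1, size=n)
    fake = pd.DataFrame(
        {m.tag: rng.lognormal(0, 0.1, size=n) for m in SYLLABLE_MEASURES}
    )
    for m in SYLLABLE_MEASURES[:6]:
        fake[m.tag] = latent * rng.lognormal(0, 0.05, size=n)
    picked = select_representative_measure(fake, "syllable")
    assert picked in SYLLABLE_MEASURES[:6]
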