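"""NB mixed-model fitting: reductions, oracles, joins, cross-validation."""
import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from icemeta import annotation as ann
from icemeta import association as assoc
from icemeta import synthetic as syn


# ---------------------------------------------------------------------------
# Reduction to plain NB regression
# ---------------------------------------------------------------------------

def test_sigma_zero_data_reduces_to_plain_nb():
    import statsmodels.api as sm

    df, _ = syn.simulate_association_dataset(
        betas={"NPOC": 0.5}, sigma_u=0.0, n_obs=600, seed=4
    )
    fit = assoc.fit_count_association(df)
    assert fit.sigma_u < assoc.SIGMA_COLLAPSE
    assert fit.reduced_to_fixed_effects

    Z = np.column_stack(
        [np.ones(len(df))]
        + [
            (df[c] - df[c].mean()) / df[c].std(ddof=0)
            for c in syn.COVARIATES
        ]
    )
    plain = sm.NegativeBinomial(df["species_count"].values, Z).fit(disp=0)
    ref = np.asarray(plain.params[:9])
    diff = np.abs(ref - fit.params["coef"].values)
    assert (diff <= 1e-3 + 1e-3 * np.abs(ref)).all()


def test_single_habitat_falls_back_with_warning():
    df, _ = syn.simulate_association_dataset(sigma_u=0.0, n_obs=120, seed=5)
    one = df[df["habitat"] == "soil"].reset_index(drop=True)
    with pytest.warns(UserWarning, match="fixed-effects-only"):
        fit = assoc.fit_count_association(one)
    assert not fit.random_intercept_used
    assert fit.sigma_u == 0.0


def test_constant_covariate_rejected():
    df, _ = syn.simulate_association_dataset(n_obs=60, seed=6)
    df["Na"] = 10.0
    with pytest.raises(assoc.AssociationError, match="constant"):
        assoc.fit_count_association(df)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def test_recovers_planted_effect_and_variance_components():
    df, truth = syn.simulate_association_dataset(
        betas={"NPOC": 0.5, "Na": 0.3}, sigma_u=0.5, dispersion=2.0,
        n_obs=900, seed=7,
    )
    fit = assoc.fit_count_association(df)
    assert fit.converged
    assert fit.coef("NPOC") == pytest.approx(0.5, abs=0.15)
    assert fit.coef("Na") == pytest.approx(0.3, abs=0.15)
    assert fit.theta == pytest.approx(2.0, rel=0.5)
    assert 0.1 < fit.sigma_u < 1.5


def test_sign_and_significance_recovered_in_most_replicates():
    reps = assoc.replicate_fits(
        betas={"NPOC": 0.5}, n_replicates=20, n_obs=600, sigma_u=0.5, seed=8
    )
    npoc = reps[reps["covariate"] == "NPOC"]
    hit = ((npoc["coef"] > 0) & npoc["significant"]).mean()
    assert hit >= 0.9


def test_natural_scale_backtransform_consistent():
    df, _ = syn.simulate_association_dataset(betas={"Na": 0.4}, n_obs=500, seed=9)
    fit = assoc.fit_count_association(df)
    sd = df["Na"].std(ddof=0)
    assert fit.params_natural.loc["Na", "coef"] == pytest.approx(
        fit.coef("Na") / sd, rel=1e-9
    )
    # p-values are scale-invariant
    pd.testing.assert_series_equal(
        fit.params["pvalue"], fit.params_natural["pvalue"]
    )


# ---------------------------------------------------------------------------
# Independent oracle: glmmTMB fits the same marginal likelihood
# ---------------------------------------------------------------------------

@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_matches_glmmtmb_on_shared_dataset(tmp_path):
    df, _ = syn.simulate_association_dataset(
        betas={"NPOC": 0.5, "Na": 0.3}, sigma_u=0.6, dispersion=2.0,
        n_obs=240, seed=10,
    )
    fit = assoc.fit_count_association(df)

    zdf = df[["habitat", "species_count"]].copy()
    for c in syn.COVARIATES:
        zdf[f"z{c}"] = (df[c] - df[c].mean()) / df[c].std(ddof=0)
    data_path = tmp_path / "assoc.tsv"
    zdf.to_csv(data_path, sep="\t", index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(textwrap.dedent("""
        suppressMessages({library(glmmTMB); library(jsonlite)})
        args <- commandArgs(trailingOnly = TRUE)
        d <- read.delim(args[1])
        d$habitat <- factor(d$habitat)
        f <- glmmTMB(
          species_count ~ zNa + zK + zCa + zMg + zCl + zSO4 + zNPOC + zAA +
            (1 | habitat),
          data = d, family = nbinom2)
        out <- list(
          coef = as.list(fixef(f)$cond),
          sigma_u = attr(VarCorr(f)$cond$habitat, "stddev")[[1]],
          theta = sigma(f))
        cat(toJSON(out, auto_unbox = TRUE, digits = 10))
    """))
    proc = subprocess.run(
        ["Rscript", str(rscript), str(data_path)],
        capture_output=True, text=True, timeout=300,
    )
    assert proc.returncode == 0, proc.stderr
    ref = json.loads(proc.stdout)
    assert fit.coef("const") == pytest.approx(ref["coef"]["(Intercept)"], abs=0.02)
    for c in syn.COVARIATES:
        assert fit.coef(c) == pytest.approx(ref["coef"][f"z{c}"], abs=0.02)
    assert fit.theta == pytest.approx(ref["theta"], rel=0.05)
    assert fit.sigma_u == pytest.approx(ref["sigma_u"], abs=0.05)


# ---------------------------------------------------------------------------
# Joining summaries to geochemistry
# ---------------------------------------------------------------------------

def _summary(sample, counts):
    src = {c: 0 for c in ann.SOURCE_CATEGORIES}
    src.update(counts)
    return ann.CategorySummary(
        sample_label=sample, source_counts=src,
        physiology_counts={c: 0 for c in ann.PHYSIOLOGY_CATEGORIES},
        domain_counts={}, phylum_counts={}, trophic_counts={},
        n_taxa=sum(src.values()), n_labeled=sum(src.values()),
    )


def test_full_join_is_habitat_by_depth_cross_product():
    depths = [f"d{i}" for i in range(5)]
    summaries = [_summary(d, {"marine": 3, "soil_sediment": 1}) for d in depths]
    geo = syn.simulate_geochemistry(depths, seed=2)
    table = assoc.prepare_association_table(summaries, geo)
    assert len(table) == 6 * 5
    # brute-force check of one cell
    row = table[(table["habitat"] == "marine") & (table["depth_label"] == "d2")]
    assert row["species_count"].iloc[0] == 3
    assert row["Na"].iloc[0] == geo.set_index("depth_label").loc["d2", "Na"]


def test_unmatched_depths_dropped_with_warning():
    summaries = [_summary("d0", {"marine": 2}), _summary("missing", {"marine": 2})]
    geo = syn.simulate_geochemistry(["d0"], seed=3)
    with pytest.warns(UserWarning, match="missing"):
        table = assoc.prepare_association_table(summaries, geo)
    assert set(table["depth_label"]) == {"d0"}


def test_empty_geochemistry_rejected():
    with pytest.raises(assoc.AssociationError):
        assoc.prepare_association_table([_summary("d0", {})], pd.DataFrame())


def test_no_overlapping_depths_rejected():
    geo = syn.simulate_geochemistry(["other"], seed=4)
    with pytest.warns(UserWarning):
        with pytest.raises(assoc.AssociationError, match="overlap"):
            assoc.prepare_association_table([_summary("d0", {})], geo)
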