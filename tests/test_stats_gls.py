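"""GLS workflow tests: reduction to OLS, variance-ratio recovery, the
likelihood-ratio machinery, backward selection, and an independent
cross-check of the likelihood surface against R's nlme::gls."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from fspibr import stats_gls as sg


def sim_factorial(rng, n_per_cell=10, species_effect=0.0,
                  treatment_effect=0.0, interaction=0.0,
                  sd=(1.0, 1.0)):
    """Balanced 2x2 factorial with per-species residual SDs."""
    rows = []
    for si, sp in enumerate(("native", "invasive")):
        for ti, tr in enumerate(("CT", "HW")):
            mu = (1.0 + si * species_effect + ti * treatment_effect
                  + si * ti * interaction)
            y = mu + rng.normal(0.0, sd[si], n_per_cell)
            rows += [(sp, tr, v) for v in y]
    return pd.DataFrame(rows, columns=["species", "treatment", "y"])


FULL = sg.ModelSpec(response="y")


class TestFitGls:
    def test_identity_structure_reduces_to_ols(self, rng):
        data = sim_factorial(rng, species_effect=0.5, treatment_effect=0.3)
        fit = sg.fit_gls(data, sg.ModelSpec(response="y", method="ML"))
        X = np.column_stack([
            np.ones(len(data)),
            (data.species == "native").to_numpy(float),
            (data.treatment == "HW").to_numpy(float),
            ((data.species == "native") & (data.treatment == "HW")
             ).to_numpy(float)])
        ols = sm.OLS(data["y"].to_numpy(), X).fit()
        # coefficient sets agree up to factor-level naming/order
        assert np.allclose(sorted(fit.params), sorted(ols.params),
                           atol=1e-8)
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-8)

    def test_variance_ratio_recovery(self, rng):
        # known 4:1 variance (2:1 SD) ratio between species, n = 200
        data = sim_factorial(rng, n_per_cell=50, sd=(1.0, 2.0))
        fit = sg.fit_gls(
            data, sg.ModelSpec(response="y", variance="species",
                               method="REML"))
        ratio = max(fit.weights.values()) / min(fit.weights.values())
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_weights_keyed_by_stratum(self, rng):
        data = sim_factorial(rng, n_per_cell=30, sd=(1.0, 2.0))
        fit = sg.fit_gls(
            data, sg.ModelSpec(response="y", variance="species_treatment",
                               method="REML"))
        assert len(fit.weights) == 4
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_tiny_stratum_rejected(self, rng):
        bad = sim_factorial(rng, n_per_cell=5).reset_index(drop=True)
        bad.loc[0, "species"] = "ghost"  # a variance stratum of size 1
        with pytest.raises(ValueError, match="<2 observations"):
            sg.fit_gls(bad, sg.ModelSpec(response="y", fixed=("treatment",),
                                         variance="species"))

    def test_singular_design_rejected(self, rng):
        data = sim_factorial(rng)
        data["treatment"] = data["species"]  # perfectly collinear factors
        with pytest.raises(ValueError, match="singular|levels"):
            sg.fit_gls(data, FULL)

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="interaction"):
            sg.ModelSpec(response="y", fixed=("species",
                                              "species:treatment"))


class TestNlmeCrossCheck:
    def test_loglik_aic_and_weights_match_nlme(self, rng, tmp_path):
        """Same fixture, two routes: this implementation vs R nlme::gls
        (ML and REML, with and without per-species variance weights)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not found on PATH")
        data = sim_factorial(rng, n_per_cell=10, species_effect=0.8,
                             sd=(1.0, 2.0))
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(nlme)); suppressMessages(library(jsonlite))
        d <- read.csv('{csv}')
        out <- list()
        for (m in c('ML','REML')) {{
          f1 <- gls(y ~ species*treatment, data=d, method=m)
          f2 <- gls(y ~ species*treatment, data=d,
                    weights=varIdent(form=~1|species), method=m)
          out[[m]] <- list(ll1=as.numeric(logLik(f1)), aic1=AIC(f1),
                           ll2=as.numeric(logLik(f2)), aic2=AIC(f2),
                           ratio=as.numeric(coef(f2$modelStruct$varStruct,
                                                 unconstrained=FALSE)),
                           beta=as.numeric(coef(f2)))
        }}
        cat(toJSON(out, auto_unbox=TRUE, digits=12))
        """
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        want = json.loads(res.stdout)
        for method in ("ML", "REML"):
            f1 = sg.fit_gls(data, sg.ModelSpec(response="y", method=method))
            f2 = sg.fit_gls(data, sg.ModelSpec(response="y",
                                               variance="species",
                                               method=method))
            w = want[method]
            assert f1.loglik == pytest.approx(w["ll1"], abs=1e-5)
            assert f1.aic == pytest.approx(w["aic1"], abs=1e-4)
            assert f2.loglik == pytest.approx(w["ll2"], abs=1e-5)
            assert f2.aic == pytest.approx(w["aic2"], abs=1e-4)
            ratio = max(f2.weights.values()) / min(f2.weights.values())
            r_ratio = w["ratio"] if np.ndim(w["ratio"]) == 0 else w["ratio"]
            r_ratio = float(np.atleast_1d(r_ratio)[0])
            r_ratio = r_ratio if r_ratio >= 1 else 1 / r_ratio
            assert ratio == pytest.approx(r_ratio, rel=1e-4)
            assert np.allclose(sorted(np.abs(f2.params)),
                               sorted(np.abs(w["beta"])), atol=1e-6)


class TestLrTest:
    def test_identical_models_give_zero(self, rng):
        data = sim_factorial(rng)
        spec = sg.ModelSpec(response="y", fixed=("species",), method="ML")
        fit = sg.fit_gls(data, spec)
        bigger = sg.fit_gls(data, sg.ModelSpec(
            response="y", fixed=("species", "treatment"), method="ML"))
        lr = sg.lr_test(bigger, fit)
        assert lr.df == 1 and lr.L_ratio >= 0

    def test_hand_computed_nested_pair(self, rng):
        data = sim_factorial(rng, species_effect=1.0)
        full = sg.fit_gls(data, sg.ModelSpec(
            response="y", fixed=("species",), method="ML"))
        null = sg.fit_gls(data, sg.ModelSpec(
            response="y", fixed=(), method="ML"))
        # ML likelihood ratio for nested OLS fits: n * log(RSS0 / RSS1)
        y = data["y"].to_numpy()
        n = len(y)
        rss0 = ((y - y.mean()) ** 2).sum()
        grp = data.groupby("species")["y"].transform("mean")
        rss1 = ((y - grp) ** 2).sum()
        want = n * np.log(rss0 / rss1)
        lr = sg.lr_test(full, null)
        assert lr.L_ratio == pytest.approx(want, rel=1e-10)
        assert lr.df == 1

    def test_reml_pair_rejected(self, rng):
        data = sim_factorial(rng)
        full = sg.fit_gls(data, sg.ModelSpec(response="y", method="REML"))
        red = sg.fit_gls(data, sg.ModelSpec(
            response="y", fixed=("species", "treatment"), method="REML"))
        with pytest.raises(ValueError, match="ML"):
            sg.lr_test(full, red)

    def test_non_nested_rejected(self, rng):
        data = sim_factorial(rng)
        a = sg.fit_gls(data, sg.ModelSpec(response="y", fixed=("species",),
                                          method="ML"))
        b = sg.fit_gls(data, sg.ModelSpec(response="y", fixed=("treatment",),
                                          method="ML"))
        b2 = sg.fit_gls(data, sg.ModelSpec(
            response="y", fixed=("species", "treatment"), method="ML"))
        with pytest.raises(ValueError, match="nested"):
            sg.lr_test(b2, sg.fit_gls(data, sg.ModelSpec(
                response="y", fixed=("species",), variance="species",
                method="ML")))
        with pytest.raises(ValueError):
            sg.lr_test(a, b2)  # reduced has more parameters


class TestVarianceStructureSelection:
    def test_single_candidate_returned_unchanged(self, rng):
        data = sim_factorial(rng)
        spec = sg.select_variance_structure(data, FULL,
                                            candidates=("identity",))
        assert spec.variance == "identity"

    def test_strong_heteroscedasticity_selects_species(self, rng):
        data = sim_factorial(rng, n_per_cell=50, sd=(1.0, 3.0))
        spec = sg.select_variance_structure(
            data, FULL, candidates=("identity", "species"))
        assert spec.variance == "species"

    def test_identity_required(self, rng):
        with pytest.raises(ValueError, match="identity"):
            sg.select_variance_structure(sim_factorial(rng), FULL,
                                         candidates=("species",))


class TestBackwardSelection:
    def test_strong_interaction_retained_with_mains(self, rng):
        data = sim_factorial(rng, n_per_cell=40, species_effect=0.2,
                             treatment_effect=0.2, interaction=2.0)
        sel = sg.backward_select(data, FULL)
        assert set(sel.spec.fixed) == {"species", "treatment",
                                      "species:treatment"}
        assert sel.fit.method == "REML"

    def test_intercept_only_truth_empties_model(self, rng):
        data = sim_factorial(rng, n_per_cell=40)
        sel = sg.backward_select(data, FULL)
        assert sel.spec.fixed == ()
        assert all(t.removed for t in sel.trail)

    def test_mains_never_dropped_before_interaction(self):
        assert sg._droppable(("species", "treatment",
                              "species:treatment")) == ["species:treatment"]
        assert set(sg._droppable(("species", "treatment"))) == \
            {"species", "treatment"}

    def test_trail_reports_df_lratio_p(self, rng):
        data = sim_factorial(rng, n_per_cell=30, species_effect=1.5)
        sel = sg.backward_select(data, FULL)
        assert "species" in sel.spec.fixed
        for t in sel.trail:
            assert t.df >= 1 and t.L_ratio >= 0 and 0 <= t.p <= 1
        kept = [t for t in sel.trail if not t.removed]
        assert len(kept) <= 1  # selection stops at the first retained term
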