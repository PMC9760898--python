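import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import isodimorph as iso
from isodimorph.meta_model import ModelSpec


def two_point_frame():
    return pd.DataFrame({
        "study_id": ["a", "b"], "species": ["x", "y"],
        "value": [0.0, 2.0], "sampling_variance": [1.0, 1.0],
    })


class TestFitMultilevel:
    def test_zero_components_equal_v_gives_arithmetic_mean(self):
        df = pd.DataFrame({
            "study_id": list("abcd"), "species": list("wxyz"),
            "value": [1.0, 2.0, 3.0, 6.0], "sampling_variance": [0.5] * 4,
        })
        m = iso.fit_multilevel(df, ModelSpec(random_levels=("study",)),
                               fixed_sigma2={"study": 0.0})
        assert m.beta[0] == pytest.approx(3.0)
        assert m.n_param == 1  # no estimated components

    def test_two_point_reml_matches_grid_search(self):
        m = iso.fit_multilevel(two_point_frame(),
                               ModelSpec(random_levels=("study",)))
        grid = np.arange(0.0, 10.0, 1e-4)
        crit = np.array([m.criterion_at({"study": s}) for s in grid])
        assert m.sigma2["study"] == pytest.approx(grid[crit.argmin()], abs=1e-3)
        # two-point method-of-moments solution: (y1-y2)^2/2 - v = 1
        assert m.sigma2["study"] == pytest.approx(1.0, abs=1e-3)
        assert m.beta[0] == pytest.approx(1.0)

    def test_twelve_obs_moderator_matches_2d_grid(self, twelve_effects):
        m = iso.fit_multilevel(twelve_effects,
                               ModelSpec(formula="value ~ x",
                                         random_levels=("study",)))
        grid = np.arange(0.0, 5.0, 1e-3)
        crit = np.array([m.criterion_at({"study": s}) for s in grid])
        assert m.sigma2["study"] == pytest.approx(grid[crit.argmin()], abs=1e-3)
        # and the coefficient vector is the GLS solution at that optimum
        V = np.diag(twelve_effects["sampling_variance"] + m.sigma2["study"])
        X = np.column_stack([np.ones(12), twelve_effects["x"]])
        y = twelve_effects["value"].to_numpy()
        beta = np.linalg.solve(X.T @ np.linalg.inv(V) @ X,
                               X.T @ np.linalg.inv(V) @ y)
        assert np.allclose(m.beta, beta, atol=1e-6)

    def test_balanced_equal_v_closed_form(self):
        y = np.array([0.1, 0.5, -0.3, 0.8, 1.2, -0.6])
        v = 0.09
        df = pd.DataFrame({"study_id": [f"s{i}" for i in range(6)],
                           "species": "sp", "value": y,
                           "sampling_variance": v})
        m = iso.fit_multilevel(df, ModelSpec(random_levels=("study",)))
        assert m.sigma2["study"] == pytest.approx(
            max(0.0, y.var(ddof=1) - v), rel=1e-5)

    def test_profile_surface_no_better_point(self, default_dataset):
        df = default_dataset["effects"]
        m = iso.fit_multilevel(df, ModelSpec(formula="value ~ dimorphism"),
                               default_dataset["corr"])
        opt = m.criterion_at(m.sigma2)
        rng = np.random.default_rng(0)
        probes = rng.uniform(0.0, 2.0, size=(100, 3))
        for p in probes:
            probe = dict(zip(m.sigma2.keys(), p))
            assert m.criterion_at(probe) >= opt - 1e-6

    def test_identity_phylo_confounded_with_species_sum_recovered(self):
        rng = np.random.default_rng(8)
        n_sp = 25
        sp = [f"sp{i}" for i in range(n_sp)]
        u = rng.normal(0, np.sqrt(0.6), n_sp)
        rows = []
        for i, s in enumerate(sp):
            for k in range(3):
                rows.append({"study_id": s, "species": s,
                             "value": u[i] + rng.normal(0, 0.2),
                             "sampling_variance": 0.04})
        df = pd.DataFrame(rows)
        ident = iso.PhyloCorrelation(tuple(sp), np.eye(n_sp))
        m2 = iso.fit_multilevel(df, ModelSpec(random_levels=("species", "phylo")),
                                ident)
        m1 = iso.fit_multilevel(df, ModelSpec(random_levels=("species",)))
        total2 = m2.sigma2["species"] + m2.sigma2["phylo"]
        assert total2 == pytest.approx(m1.sigma2["species"], rel=1e-3, abs=1e-4)

    def test_rank_deficient_design_names_aliased_column(self, twelve_effects):
        df = twelve_effects.assign(x2=lambda d: 2.0 * d["x"])
        with pytest.raises(ValueError, match="x2"):
            iso.fit_multilevel(df, ModelSpec(formula="value ~ x + x2",
                                             random_levels=("study",)))

    def test_deterministic_given_inputs(self, default_dataset):
        df = default_dataset["effects"]
        spec = ModelSpec(formula="value ~ dimorphism")
        a = iso.fit_multilevel(df, spec, default_dataset["corr"])
        b = iso.fit_multilevel(df, spec, default_dataset["corr"])
        assert a.to_dict() == b.to_dict()


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R oracle not on PATH")
def test_fit_matches_metafor_oracle(tmp_path):
    """Independent cross-check: coefficients, standard errors, variance
    components and REML log-likelihood agree with metafor's rma.mv on the
    same data and phylogenetic correlation matrix."""
    truth = iso.SimTruth(seed=7, n_studies=40, n_species=40)
    records, tree = iso.simulate_dataset(truth)
    df = iso.effect_table(records, "MD", "N15")
    corr = iso.correlation_from_tree(tree, sorted(df["species"].unique()))
    m = iso.fit_multilevel(df, ModelSpec(formula="value ~ dimorphism"), corr)

    df.to_csv(tmp_path / "d.csv", index=False)
    pd.DataFrame(corr.matrix, index=corr.species,
                 columns=corr.species).to_csv(tmp_path / "A.csv")
    script = f"""
    suppressMessages(library(metafor))
    d <- read.csv("{tmp_path}/d.csv")
    A <- as.matrix(read.csv("{tmp_path}/A.csv", row.names=1, check.names=FALSE))
    d$phylo <- d$species
    m <- rma.mv(value ~ dimorphism, V=sampling_variance, data=d,
                random=list(~1|study_id, ~1|species, ~1|phylo),
                R=list(phylo=A), Rscale="none", method="REML")
    cat(jsonlite::toJSON(list(beta=unname(coef(m)), se=unname(m$se),
        sigma2=m$sigma2, loglik=as.numeric(logLik(m))), digits=10))
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    assert np.allclose(m.beta, ref["beta"], atol=1e-4)
    assert np.allclose(m.se, ref["se"], atol=1e-4)
    assert sum(m.sigma2.values()) == pytest.approx(sum(ref["sigma2"]), abs=1e-3)
    assert m.loglik == pytest.approx(ref["loglik"][0], abs=1e-4)


class TestHeterogeneity:
    def test_zero_components_zero_i2(self):
        m = iso.fit_multilevel(two_point_frame(),
                               ModelSpec(random_levels=("study",)),
                               fixed_sigma2={"study": 0.0})
        rep = iso.i_squared(m)
        assert rep.i2_total == 0.0

    def test_fifty_percent_when_components_equal_typical_v(self):
        df = pd.DataFrame({
            "study_id": list("abcde"), "species": list("vwxyz"),
            "value": [0.2, -0.1, 0.4, 0.0, 0.3],
            "sampling_variance": [0.1, 0.2, 0.15, 0.12, 0.18],
        })
        m0 = iso.fit_multilevel(df, ModelSpec(random_levels=("study",)),
                                fixed_sigma2={"study": 0.0})
        vbar = iso.i_squared(m0).typical_v
        m = iso.fit_multilevel(df, ModelSpec(random_levels=("study",)),
                               fixed_sigma2={"study": vbar})
        rep = iso.i_squared(m)
        assert rep.i2_total == pytest.approx(50.0)
        # typical v follows the harmonic-style formula
        w = 1.0 / df["sampling_variance"]
        expect = (len(df) - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
        assert vbar == pytest.approx(expect)

    def test_per_level_values_sum_to_total(self, default_dataset):
        m = iso.fit_multilevel(default_dataset["effects"], ModelSpec(),
                               default_dataset["corr"])
        rep = iso.i_squared(m)
        assert sum(rep.i2_per_level.values()) == pytest.approx(rep.i2_total)
        assert 0.0 <= rep.i2_total <= 100.0

    def test_requires_intercept_only(self, default_dataset):
        m = iso.fit_multilevel(default_dataset["effects"],
                               ModelSpec(formula="value ~ dimorphism"),
                               default_dataset["corr"])
        with pytest.raises(ValueError):
            iso.i_squared(m)


class TestAicc:
    def test_direct_formula(self):
        assert iso.aicc(0.0, 1, 10) == pytest.approx(2.5)
        assert iso.aicc(-252.0, 4, 282) == pytest.approx(512.144, abs=1e-2)

    def test_useless_parameter_increases_aicc(self):
        assert iso.aicc(-100.0, 3, 50) < iso.aicc(-100.0, 4, 50)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            iso.aicc(0.0, 5, 6)


class TestModelSelection:
    def test_single_spec_one_row(self, default_dataset):
        t = iso.model_selection_table(["value ~ 1"], default_dataset["effects"],
                                      corr=default_dataset["corr"])
        assert len(t) == 1 and t["rank"].iloc[0] == 1
        assert t.attrs["method"] == "ML"

    def test_sorted_ascending_with_tie_ranks(self, default_dataset):
        t = iso.model_selection_table(
            ["value ~ dimorphism", "value ~ 1", "value ~ dimorphism + mean_size"],
            default_dataset["effects"], corr=default_dataset["corr"])
        assert t["aicc"].is_monotonic_increasing
        assert list(t["rank"]) == sorted(t["rank"])


class TestPredictAndInference:
    def test_prediction_at_zero_moderators_is_intercept(self, default_dataset):
        m = iso.fit_multilevel(default_dataset["effects"],
                               ModelSpec(formula="value ~ dimorphism"),
                               default_dataset["corr"])
        pred = iso.predict_with_band(m, pd.DataFrame({"dimorphism": [0.0]}))
        assert pred["estimate"].iloc[0] == pytest.approx(m.beta[0])
        assert pred["ci_low"].iloc[0] == pytest.approx(m.ci_low[0], abs=1e-8)

    def test_band_matches_quadratic_form_oracle(self, default_dataset):
        m = iso.fit_multilevel(default_dataset["effects"],
                               ModelSpec(formula="value ~ dimorphism"),
                               default_dataset["corr"])
        grid = pd.DataFrame({"dimorphism": [-2.0, -1.0, 0.0, 1.0, 2.0]})
        pred = iso.predict_with_band(m, grid)
        for i, d in enumerate(grid["dimorphism"]):
            x = np.array([1.0, d])
            assert pred["se"].iloc[i] == pytest.approx(
                np.sqrt(x @ m.cov_beta @ x), rel=1e-10)

    def test_band_narrowest_near_moderator_mean(self, default_dataset):
        df = default_dataset["effects"]
        m = iso.fit_multilevel(df, ModelSpec(formula="value ~ dimorphism"),
                               default_dataset["corr"])
        xbar = -m.cov_beta[0, 1] / m.cov_beta[1, 1]  # GLS minimizer
        grid = pd.DataFrame({"dimorphism": [xbar - 2, xbar, xbar + 2]})
        pred = iso.predict_with_band(m, grid)
        assert pred["se"].iloc[1] < pred["se"].iloc[0]
        assert pred["se"].iloc[1] < pred["se"].iloc[2]

    def test_wald_z_and_ci(self):
        df = two_point_frame()
        m = iso.fit_multilevel(df, ModelSpec(random_levels=("study",)))
        inf = iso.wald_inference(m)
        # beta=0 -> p=1 case via a symmetric dataset
        sym = pd.DataFrame({"study_id": ["a", "b"], "species": ["x", "y"],
                            "value": [-1.0, 1.0], "sampling_variance": [1.0, 1.0]})
        ms = iso.fit_multilevel(sym, ModelSpec(random_levels=("study",)))
        assert iso.wald_inference(ms)["p"].iloc[0] == pytest.approx(1.0)
        assert set(inf.columns) == {"estimate", "z", "p", "ci_low", "ci_high"}

    def test_ci_from_estimate_and_se(self):
        # 0.126 +- 1.96 * 0.0332 reproduces a (0.061, 0.191) interval
        from scipy import stats
        z = stats.norm.ppf(0.975)
        assert 0.126 - z * 0.0332 == pytest.approx(0.0609, abs=1e-3)
        assert 0.126 + z * 0.0332 == pytest.approx(0.1911, abs=1e-3)

    def test_beta_at_1_96_se_gives_p_05(self):
        df = two_point_frame()
        m = iso.fit_multilevel(df, ModelSpec(random_levels=("study",)))
        from scipy import stats
        z = m.beta[0] / m.se[0]
        assert m.pval[0] == pytest.approx(2 * stats.norm.sf(abs(z)))


def test_serialization_round_trip(default_dataset):
    m = iso.fit_multilevel(default_dataset["effects"],
                           ModelSpec(formula="value ~ dimorphism"),
                           default_dataset["corr"])
    d = json.loads(m.to_json())
    assert d["coefficients"]["dimorphism"]["estimate"] == pytest.approx(
        m.beta[1])
    assert set(d["sigma2"]) == {"study", "species", "phylo"}
    assert d["n_param"] == 2 + 3
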