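"""Joint SFS polarization, expected spectra, composite likelihood, fitting."""

import math

import numpy as np
import pytest
from scipy import stats

import declinescan as ds
from conftest import build_gm


def _split_pops(gm, p1="pop1", p2="pop2"):
    a = gm.subset_samples([s for s in gm.samples if s.startswith(p1)])
    b = gm.subset_samples([s for s in gm.samples if s.startswith(p2)])
    return a, b


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def test_polarize_counts_single_het_site():
    gm1 = build_gm(np.array([[1]], np.int8))           # one het individual
    gm2 = build_gm(np.array([[0]], np.int8))           # hom-ancestral
    og = build_gm(np.array([[0]], np.int8))            # hom-ref outgroup
    sfs, excl = ds.polarize_joint_sfs(gm1, gm2, og)
    assert sfs.counts[1, 0] == 1 and sfs.total_sites == 1
    assert sum(excl.values()) == 0


def test_polarize_outgroup_het_excluded():
    gm1 = build_gm(np.array([[1]], np.int8))
    gm2 = build_gm(np.array([[0]], np.int8))
    og = build_gm(np.array([[1]], np.int8))
    sfs, excl = ds.polarize_joint_sfs(gm1, gm2, og)
    assert sfs.total_sites == 0
    assert excl["outgroup_het_or_missing"] == 1


def test_polarize_hom_alt_outgroup_flips_derived():
    gm1 = build_gm(np.array([[1]], np.int8))   # het = 1 ancestral + 1 derived
    gm2 = build_gm(np.array([[2]], np.int8))   # hom-alt = hom-ancestral here
    og = build_gm(np.array([[2]], np.int8))    # ancestral allele is ALT
    sfs, _ = ds.polarize_joint_sfs(gm1, gm2, og)
    assert sfs.counts[1, 0] == 1


def test_polarize_matches_truth_with_perfect_outgroup():
    spec = ds.PopulationModelSpec.two_population_split(5000, 5000, 5000, 8000)
    gm = ds.simulate_coalescent(spec, {"pop1": 3, "pop2": 3}, 200, 5000, seed=2)
    gm1, gm2 = _split_pops(gm)
    og = ds.GenotypeMatrix(["og"], gm.sites.copy(),
                           np.zeros((gm.n_sites, 1), np.int8))
    sfs_p, _ = ds.polarize_joint_sfs(gm1, gm2, og)
    sfs_t = ds.truth_polarized_sfs(gm1, gm2)
    assert np.array_equal(sfs_p.counts, sfs_t.counts)


def test_joint_sfs_tsv_roundtrip(tmp_path):
    counts = np.arange(15).reshape(5, 3).astype(float)
    sfs = ds.JointSFS(2, 1, counts, sequence_length_bp=1e6)
    path = tmp_path / "sfs.tsv"
    sfs.to_tsv(path)
    back = ds.JointSFS.from_tsv(path)
    assert back.n1 == 2 and back.n2 == 1
    assert np.array_equal(back.counts, counts)
    assert np.array_equal(back.mask, sfs.mask)
    assert back.sequence_length_bp == 1e6
    assert back.total_sites == counts.sum() - counts[0, 0]


# ---------------------------------------------------------------------------
# expected SFS
# ---------------------------------------------------------------------------

def test_expected_sfs_deterministic():
    spec = ds.PopulationModelSpec.two_population_split(3000, 3000, 3000, 2000)
    a = ds.expected_sfs(spec, {"pop1": 2, "pop2": 2}, n_sims=200, seed=4)
    b = ds.expected_sfs(spec, {"pop1": 2, "pop2": 2}, n_sims=200, seed=4)
    assert np.array_equal(a, b)
    assert a[~np.isnan(a)].sum() == pytest.approx(1.0)


def test_expected_sfs_single_population_one_over_i():
    spec = ds.PopulationModelSpec.single_population(5000)
    p = ds.expected_sfs(spec, {"pop0": 2}, n_sims=4000, seed=5).ravel()
    expected = np.array([0, 1, 1 / 2, 1 / 3, 0.0])
    expected /= expected.sum()
    assert np.allclose(p, expected, atol=0.02)


def test_expected_sfs_deep_split_no_shared_polymorphism():
    ne = 1000.0
    spec = ds.PopulationModelSpec.two_population_split(ne, ne, ne, 10 * 2 * ne)
    p = ds.expected_sfs(spec, {"pop1": 2, "pop2": 2}, n_sims=2000, seed=6)
    shared = p[1:-1, 1:-1].sum()
    assert shared < 0.01


def test_expected_sfs_marginals_match_single_population_runs():
    """Row/column marginals reproduce each population's 1-D spectrum."""
    spec = ds.PopulationModelSpec.two_population_split(4000, 4000, 4000, 1000,
                                                       m12=1e-4, m21=1e-4)
    B = ds.joint_branch_lengths(spec, {"pop1": 2, "pop2": 2}, 6000, seed=7)
    marg1 = B.sum(axis=1)[1:-1]
    # independent simulation of the same quantity
    B2 = ds.joint_branch_lengths(spec, {"pop1": 2, "pop2": 2}, 6000, seed=77)
    marg1b = B2.sum(axis=1)[1:-1]
    assert np.allclose(marg1 / marg1.sum(), marg1b / marg1b.sum(), atol=0.03)


def test_expected_sfs_zero_diversity_errors():
    spec = ds.PopulationModelSpec.single_population(5000, mutation_rate=0.0)
    # branch lengths are still positive; error path needs all-masked cells
    mask = np.ones((5, 1), bool)
    with pytest.raises(ValueError, match="increase n_sims|masked|polymorphic"):
        ds.expected_sfs(spec, {"pop0": 2}, n_sims=10, seed=1, mask=mask)


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def test_cl_all_mass_single_cell_is_zero():
    counts = np.zeros((3, 3))
    counts[1, 1] = 50
    sfs = ds.JointSFS(1, 1, counts)
    expected = np.zeros((3, 3))
    expected[1, 1] = 1.0
    assert ds.composite_log_likelihood(sfs, expected) == pytest.approx(0.0)


def test_cl_uniform_expectation_closed_form():
    counts = np.zeros((3, 3))
    counts[1, 0] = 30
    counts[0, 1] = 12
    sfs = ds.JointSFS(1, 1, counts)
    k = (~sfs.mask).sum()
    expected = np.full((3, 3), 1.0 / k)
    assert ds.composite_log_likelihood(sfs, expected) == pytest.approx(
        42 * math.log(1 / k))


def test_cl_matches_multinomial_logpmf_up_to_constant():
    rng = np.random.default_rng(8)
    for _ in range(10):
        p = rng.dirichlet(np.ones(8))
        m = rng.multinomial(100, p)
        counts = np.zeros((3, 3))
        counts.ravel()[:8] = m  # cell (2,2) stays 0
        sfs = ds.JointSFS(1, 1, counts, mask=np.zeros((3, 3), bool))
        expected = np.zeros((3, 3))
        expected.ravel()[:8] = p
        cl = ds.composite_log_likelihood(sfs, expected, pseudo=1e-300)
        log_coeff = (math.lgamma(101)
                     - sum(math.lgamma(x + 1) for x in m))
        want = stats.multinomial.logpmf(np.append(m, 0),
                                        100, np.append(p, 0)) - log_coeff
        assert cl == pytest.approx(want, rel=1e-9)


def test_cl_gibbs_inequality():
    """CL is maximized at expected == empirical frequencies."""
    rng = np.random.default_rng(9)
    counts = rng.integers(0, 40, size=(3, 3)).astype(float)
    counts[0, 0] = 0
    sfs = ds.JointSFS(1, 1, counts)
    emp = counts / counts.sum()
    cl_emp = ds.composite_log_likelihood(sfs, emp, pseudo=1e-300)
    for _ in range(20):
        q = rng.dirichlet(np.ones(9)).reshape(3, 3)
        assert ds.composite_log_likelihood(sfs, q, pseudo=1e-300) <= cl_emp + 1e-9


def test_cl_shape_mismatch_raises():
    sfs = ds.JointSFS(1, 1, np.zeros((3, 3)))
    with pytest.raises(ValueError, match="shape"):
        ds.composite_log_likelihood(sfs, np.ones((5, 3)) / 15)


def test_cl_variance_shrinks_with_more_simulations():
    """Monte-Carlo CL variance decreases over 3 simulation levels."""
    spec = ds.PopulationModelSpec.two_population_split(4000, 4000, 4000, 2000)
    gm = ds.simulate_coalescent(spec, {"pop1": 2, "pop2": 2}, 300, 2000, seed=10)
    gm1, gm2 = _split_pops(gm)
    sfs = ds.truth_polarized_sfs(gm1, gm2)
    variances = []
    for n_sims in (40, 160, 640):
        cls = []
        for s in range(12):
            p = ds.expected_sfs(spec, {"pop1": 2, "pop2": 2}, n_sims,
                                seed=1000 + 13 * s, mask=sfs.mask)
            cls.append(ds.composite_log_likelihood(sfs, p))
        variances.append(np.var(cls))
    assert variances[0] > variances[1] > variances[2]


# ---------------------------------------------------------------------------
# fitting / AIC / bootstrap
# ---------------------------------------------------------------------------

def _one_param_model(theta_bounds=(200.0, 50_000.0)):
    def build(v):
        return ds.PopulationModelSpec.single_population(v["ne"])
    return ds.DemographicModel(
        "single_pop", build, (ds.FreeParameter("ne", *theta_bounds, "log"),))


def test_fit_one_parameter_self_consistency():
    """obs = expected counts at ne*: recovered within 5%."""
    ne_star = 4000.0
    model = _one_param_model()
    spec = model.spec({"ne": ne_star})
    seq_len = 5e6
    B = ds.joint_branch_lengths(spec, {"pop0": 3}, 6000, seed=11)
    lam = B * spec.mutation_rate * seq_len
    lam[0, 0] = 0
    sfs = ds.JointSFS(3, 0, lam, sequence_length_bp=seq_len)
    fit = ds.fit_model(sfs, model, {"pop0": 3}, n_sims_per_eval=400,
                       n_starts=2, max_cycles=20, seed=12,
                       medium_factor=4, polish_factor=10,
                       refine_points=(32, 32))
    assert abs(fit.estimates["ne"] / ne_star - 1) < 0.05


def test_fit_deterministic_under_seed():
    model = _one_param_model()
    spec = model.spec({"ne": 3000.0})
    gm = ds.simulate_coalescent(spec, {"pop0": 3}, 300, 2000, seed=13)
    sfs = ds.truth_polarized_sfs(
        gm, ds.GenotypeMatrix([], gm.sites, np.zeros((gm.n_sites, 0), np.int8)),
        sequence_length_bp=300 * 2000)
    kw = dict(n_sims_per_eval=80, n_starts=2, max_cycles=8, seed=14,
              medium_factor=2, polish_factor=1)
    f1 = ds.fit_model(sfs, model, {"pop0": 3}, **kw)
    f2 = ds.fit_model(sfs, model, {"pop0": 3}, **kw)
    assert f1.estimates == f2.estimates
    assert f1.max_cl == f2.max_cl


def test_fit_requires_free_parameter():
    model = ds.DemographicModel("fixed", lambda v: None, ())
    sfs = ds.JointSFS(1, 1, np.zeros((3, 3)))
    with pytest.raises(ValueError, match="free parameter"):
        ds.fit_model(sfs, model, {"pop0": 1})


def test_aic_arithmetic_and_penalty_ordering():
    f1 = ds.FitResult("m1", {}, max_cl=-100.0, aic=0.0, k=2, converged=True,
                      n_starts=1, objective="poisson")
    f1.aic = 2 * f1.k - 2 * f1.max_cl
    assert f1.aic == 204.0
    f2 = ds.FitResult("m2", {}, max_cl=-100.0, aic=2 * 3 + 200.0, k=3,
                      converged=True, n_starts=1, objective="poisson")
    rank = ds.compare_models_aic([f1, f2])
    assert rank.iloc[0]["model"] == "m1"  # equal CL: fewer parameters wins


def test_aic_rejects_mixed_observations():
    a = ds.FitResult("m1", {}, -1.0, 4.0, 1, True, 1, "poisson", obs_id=1)
    b = ds.FitResult("m2", {}, -1.0, 4.0, 1, True, 1, "poisson", obs_id=2)
    with pytest.raises(ValueError, match="different observed"):
        ds.compare_models_aic([a, b])


def test_bootstrap_ci_contract_and_degenerate_flag():
    model = ds.split_model_template(ne_bounds=(500, 20_000),
                                    t_bounds=(300, 10_000),
                                    with_migration=False)
    truth = ds.PopulationModelSpec.two_population_split(3000, 3000, 3000, 1500)
    gm = ds.simulate_coalescent(truth, {"pop1": 2, "pop2": 2}, 400, 2000, seed=15)
    gm1, gm2 = _split_pops(gm)
    sfs = ds.truth_polarized_sfs(gm1, gm2, sequence_length_bp=400 * 2000)
    fit = ds.fit_model(sfs, model, {"pop1": 2, "pop2": 2}, n_sims_per_eval=80,
                       n_starts=2, max_cycles=10, seed=16,
                       medium_factor=3, polish_factor=5, refine_points=(32, 32))
    out = ds.bootstrap_ci(fit, model, {"pop1": 2, "pop2": 2}, n_loci=400,
                          locus_length_bp=2000, n_boot=3,
                          refits_per_spectrum=1, n_sims_per_eval=60, seed=17)
    for name, (lo, hi) in out.ci.items():
        assert lo <= out.estimates[name] <= hi
    assert "degenerate" in out.ci_flag


def test_model_from_dict_placeholder_schema():
    raw = {
        "name": "split", "populations": ["pop1", "pop2"],
        "epochs": {"pop1": [[0, "$ne"], ["$t_split", "$ne"]],
                   "pop2": [[0, "$ne"]]},
        "splits": [["$t_split", "pop2", "pop1"]],
        "free_parameters": [
            {"name": "ne", "lower": 500, "upper": 50000},
            {"name": "t_split", "lower": 300, "upper": 30000},
        ],
    }
    model = ds.model_from_dict(raw)
    assert model.k == 2
    spec = model.spec({"ne": 4000, "t_split": 2500})
    assert spec.splits == ((2500.0, "pop2", "pop1"),)
    assert spec.epochs["pop1"] == ((0.0, 4000.0), (2500.0, 4000.0))
    with pytest.raises(ValueError, match="placeholder"):
        ds.model_from_dict({**raw, "splits": [["$oops", "pop2", "pop1"]]}
                           ).spec({"ne": 4000, "t_split": 2500})


def test_model_from_yaml_roundtrip(tmp_path):
    import yaml
    raw = {
        "populations": ["a"], "epochs": {"a": [[0, "$ne"]]},
        "free_parameters": [{"name": "ne", "lower": 100, "upper": 10000}],
    }
    path = tmp_path / "model.yaml"
    path.write_text(yaml.safe_dump(raw))
    model = ds.model_from_yaml(path)
    assert model.spec({"ne": 1234}).epochs["a"] == ((0.0, 1234.0),)
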