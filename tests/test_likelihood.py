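"""Analytic configuration probabilities vs closed forms and the MC oracle."""

import math
from itertools import combinations

import numpy as np
import pytest

from blockcoal.models import DemographyModel, panmictic
from blockcoal.likelihood import (
    CLASS_NAMES,
    LEAVES,
    PROB_FLOOR,
    branch_class_of,
    build_state_space,
    composite_loglik,
    config_distribution,
    config_probability,
    mc_config_probability,
    mc_config_table,
    tally_loglik,
)
from blockcoal.simulate import SimConfig, simulate_branch_lengths, simulate_spectrum_counts
from blockcoal.tabulate import BlockSpectrum, tally


def _pan_zero_prob(theta):
    # P(no mutation anywhere) = prod_k C(k,2) / (C(k,2) + k*theta), k=4,3,2
    out = 1.0
    for k in (4, 3, 2):
        pairs = k * (k - 1) / 2
        out *= pairs / (pairs + k * theta)
    return out


# ----------------------------------------------------------------------
# branch classes
# ----------------------------------------------------------------------


def test_branch_class_examples():
    assert branch_class_of({"v1"}) == "het_v"
    assert branch_class_of({"v1", "v2"}) == "fixed_diff"
    assert branch_class_of({"v1", "b1"}) == "shared_het"
    assert branch_class_of({"v1", "v2", "b1"}) == "het_b"  # folds to {b2}


def test_branch_class_folding_exhaustive():
    full = set(LEAVES)
    proper = [
        set(c)
        for r in (1, 2, 3)
        for c in combinations(LEAVES, r)
    ]
    assert len(proper) == 14
    for s in proper:
        assert branch_class_of(s) == branch_class_of(full - s)


def test_branch_class_rejects_trivial_subsets():
    with pytest.raises(ValueError):
        branch_class_of(set())
    with pytest.raises(ValueError):
        branch_class_of(set(LEAVES))
    with pytest.raises(ValueError):
        branch_class_of({"x1"})


# ----------------------------------------------------------------------
# state space
# ----------------------------------------------------------------------


def test_ancestral_states_are_set_partitions():
    # brute force: the single-deme epoch reaches every set partition of the
    # four leaves (Bell number B4 = 15)
    _, anc, _ = build_state_space(DemographyModel("d", t_split=1.0), lumped=False)
    assert len(anc.states) == 15


def test_div_presplit_states_never_mix_demes():
    pre, _, _ = build_state_space(DemographyModel("d", t_split=1.0), lumped=False)
    for state in pre.states:
        for deme, key in state:
            if deme == "V":
                assert all(x.startswith("v") for x in key)
            elif deme == "B":
                assert all(x.startswith("b") for x in key)


def test_generator_rows_sum_to_zero():
    from blockcoal.likelihood import _lineage_generator

    for model in (
        DemographyModel("d", t_split=1.0),
        DemographyModel("i", flow="im", donor="B", t_split=1.0, m=0.7),
    ):
        pre, anc, _ = build_state_space(model, lumped=True)
        for space in (pre, anc):
            Q = _lineage_generator(space, model).toarray()
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            off = Q - np.diag(np.diag(Q))
            assert (off >= 0).all()


def test_lumped_space_is_smaller_but_equivalent(im_model):
    pre_lab, _, _ = build_state_space(im_model, lumped=False)
    pre_lum, _, _ = build_state_space(im_model, lumped=True)
    assert len(pre_lum.states) < len(pre_lab.states)
    ta = config_distribution(im_model, 0.6, 2, lumped=True).table
    tb = config_distribution(im_model, 0.6, 2, lumped=False).table
    assert np.abs(ta - tb).max() < 1e-10


# ----------------------------------------------------------------------
# closed-form limits
# ----------------------------------------------------------------------


def test_zero_theta_limit():
    p = config_probability(panmictic(), 1e-10, (0, 0, 0, 0), k_max=1)
    assert p == pytest.approx(1.0, abs=1e-8)


def test_panmictic_zero_config_closed_form():
    p = config_probability(panmictic(), 0.5, (0, 0, 0, 0), k_max=2)
    assert p == pytest.approx(0.25, abs=1e-10)
    for theta in (0.1, 1.0, 2.3):
        p = config_probability(panmictic(), theta, (0, 0, 0, 0), k_max=1)
        assert p == pytest.approx(_pan_zero_prob(theta), abs=1e-10)


def test_panmictic_single_mutation_ratios():
    theta = 1e-6
    tab = config_distribution(panmictic(), theta, k_max=1)
    singles = [
        tab.prob((1, 0, 0, 0)),
        tab.prob((0, 1, 0, 0)),
        tab.prob((0, 0, 1, 0)),
        tab.prob((0, 0, 0, 1)),
    ]
    total = sum(singles)
    expected = (4 / 11, 4 / 11, 2 / 11, 1 / 11)
    for got, want in zip(singles, expected):
        assert got / total == pytest.approx(want, rel=1e-4)


def test_tsplit_zero_equal_sizes_is_panmictic():
    div = DemographyModel("d", t_split=1e-9)
    tab_div = config_distribution(div, 0.5, 2).table
    tab_pan = config_distribution(panmictic(), 0.5, 2).table
    assert np.abs(tab_div - tab_pan).max() < 1e-6


def test_migration_zero_equals_div():
    div = DemographyModel("d", t_split=0.8, deviating="B", c_x=0.5)
    im = DemographyModel(
        "i", flow="im", donor="B", deviating="B", t_split=0.8, c_x=0.5, m=0.0
    )
    td = config_distribution(div, 0.6, 2).table
    ti = config_distribution(im, 0.6, 2).table
    assert np.abs(td - ti).max() < 1e-10


def test_species_swap_symmetry():
    """Swapping species labels (deviating size + flow direction) mirrors the
    (het_b, het_v) axes of the table."""
    a = DemographyModel(
        "a", flow="im", donor="B", deviating="B", t_split=1.0, c_x=0.4, m=0.5
    )
    b = DemographyModel(
        "b", flow="im", donor="V", deviating="V", t_split=1.0, c_x=0.4, m=0.5
    )
    ta = config_distribution(a, 0.6, 2).table
    tb = config_distribution(b, 0.6, 2).table
    assert np.abs(ta - tb.swapaxes(0, 1)).max() < 1e-10


def test_gene_flow_increases_shared_het():
    # P(shared_het >= 1) grows weakly with m at fixed other parameters
    prev = -1.0
    for m in (0.0, 0.2, 0.5, 1.0, 2.0):
        model = DemographyModel("i", flow="im", donor="B", t_split=1.0, m=m)
        tab = config_distribution(model, 0.6, 1).table
        p_shared = 1.0 - tab[:, :, 0, :].sum()
        assert p_shared >= prev - 1e-12
        prev = p_shared


# ----------------------------------------------------------------------
# normalisation and oracle equivalence
# ----------------------------------------------------------------------


def test_table_normalisation_random_draws():
    rng = np.random.default_rng(77)
    scenarios = [
        panmictic(),
        DemographyModel("d", t_split=1.0),
        DemographyModel("i", flow="im", donor="V", t_split=1.0, m=0.5),
        DemographyModel(
            "a", flow="adm", donor="B", deviating="B",
            t_split=1.0, c_x=0.5, f=0.3, t_adm=0.5,
        ),
    ]
    for base in scenarios:
        for _ in range(3):
            kw = {"t_split": float(rng.uniform(0.1, 3.0))} if base.t_split else {}
            if base.deviating:
                kw["c_x"] = float(rng.uniform(0.2, 3.0))
            if base.flow == "im":
                kw["m"] = float(rng.uniform(0.0, 2.0))
            if base.flow == "adm":
                kw["f"] = float(rng.uniform(0.05, 0.95))
                kw["t_adm"] = kw["t_split"] * float(rng.uniform(0.1, 0.9))
            model = base.with_params(**kw) if kw else base
            theta = float(rng.uniform(0.1, 2.0))
            tab = config_distribution(model, theta, 1)
            assert abs(tab.total - 1.0) < 1e-8


def test_mc_oracle_matches_analytic(im_model, adm_model):
    taus = {m.model_id: simulate_branch_lengths(m, 30_000, seed=3) for m in (im_model, adm_model)}
    for model in (im_model, adm_model):
        est, se = mc_config_table(model, 0.6, 1, 0, taus=taus[model.model_id])
        tab = config_distribution(model, 0.6, 1).table
        z = np.abs(est - tab) / np.where(se > 0, se, np.inf)
        assert z.max() < 3.5


def test_mc_config_probability_panmictic():
    est, se = mc_config_probability(panmictic(), 0.5, (0, 0, 0, 0), 50_000, seed=5)
    assert abs(est - 0.25) < 3 * se
    assert 0.0 <= est <= 1.0
    est0, se0 = mc_config_probability(panmictic(), 1e-9, (0, 0, 0, 0), 500, seed=5)
    assert est0 == pytest.approx(1.0, abs=1e-6)
    assert se0 == pytest.approx(0.0, abs=1e-6)


def test_mc_deterministic_given_seed(im_model):
    a = mc_config_probability(im_model, 0.6, (1, 0, 0, 1), 2000, seed=8)
    b = mc_config_probability(im_model, 0.6, (1, 0, 0, 1), 2000, seed=8)
    assert a == b


# ----------------------------------------------------------------------
# table mechanics
# ----------------------------------------------------------------------


def test_kmax_zero_table_shape():
    tab = config_distribution(panmictic(), 0.5, 0)
    assert tab.table.shape == (2, 2, 2, 2)
    assert tab.table.size == 16
    assert tab.prob((0, 0, 0, 0)) == pytest.approx(0.25, abs=1e-10)


def test_overflow_cells_are_marginal_complements():
    tab = config_distribution(panmictic(), 1.0, 2)
    # marginal of class 0: P(count > k_max) equals 1 - sum of exact counts
    marg = tab.table.sum(axis=(1, 2, 3))
    assert marg.sum() == pytest.approx(1.0, abs=1e-10)
    assert tab.table[3].sum() == pytest.approx(1.0 - marg[:3].sum(), abs=1e-10)


def test_table_tsv(tmp_path):
    tab = config_distribution(panmictic(), 0.5, 0)
    p = tmp_path / "table.tsv"
    tab.to_tsv(p)
    lines = p.read_text().splitlines()
    assert len(lines) == 17
    assert lines[0].split("\t") == list(CLASS_NAMES) + ["probability"]


def test_invalid_inputs():
    with pytest.raises(ValueError):
        config_distribution(panmictic(), -1.0, 1)
    with pytest.raises(ValueError):
        config_distribution(panmictic(), 0.5, -1)
    tab = config_distribution(panmictic(), 0.5, 1)
    with pytest.raises(ValueError):
        tab.prob((0, 0, 0))
    with pytest.raises(ValueError):
        tab.prob((-1, 0, 0, 0))


# ----------------------------------------------------------------------
# composite likelihood
# ----------------------------------------------------------------------


def test_loglik_arithmetic():
    # force P((0,0,0,0)) = 0.5 by choosing theta accordingly: solve not
    # needed, use the panmictic closed form at a convenient theta
    # instead: lnCL of n copies is n * ln P
    t = tally([BlockSpectrum(0, 0, 0, 0)] * 3)
    theta = 0.5
    p = _pan_zero_prob(theta)
    got = composite_loglik(t, panmictic(), theta, k_max=1)
    assert got == pytest.approx(3 * math.log(p), rel=1e-10)


def test_loglik_linear_in_counts(im_model):
    counts = {(0, 0, 0, 0): 10, (1, 0, 0, 1): 4, (0, 2, 0, 0): 1}
    from blockcoal.tabulate import BsfsTally

    t1 = BsfsTally(counts=dict(counts))
    t2 = BsfsTally(counts={k: 2 * v for k, v in counts.items()})
    a = composite_loglik(t1, im_model, 0.6, 2)
    b = composite_loglik(t2, im_model, 0.6, 2)
    assert b == pytest.approx(2 * a, rel=1e-12)


def test_loglik_empty_tally_raises(im_model):
    from blockcoal.tabulate import BsfsTally

    with pytest.raises(ValueError):
        composite_loglik(BsfsTally(), im_model, 0.6, 1)


def test_loglik_floors_vanishing_probabilities(pan_model):
    # a wildly overloaded configuration has ~0 probability at tiny theta but
    # the floored lnCL stays finite
    from blockcoal.tabulate import BsfsTally

    t = BsfsTally(counts={(5, 5, 5, 5): 1})
    val = composite_loglik(t, pan_model, 1e-8, 1)
    assert math.isfinite(val)
    assert val >= math.log(PROB_FLOOR)


def test_true_params_beat_perturbed_on_average(im_model):
    """Composite-likelihood self-consistency: across replicate datasets the
    generating parameters outscore perturbed ones on average."""
    theta = 0.6
    tab_true = config_distribution(im_model, theta, 1)
    perturbed = im_model.with_params(t_split=1.4, m=0.9)
    tab_pert = config_distribution(perturbed, theta * 1.3, 1)
    wins = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = SimConfig(model=im_model, theta_block=theta, n_blocks=10_000, seed=500 + rep)
        counts = simulate_spectrum_counts(cfg)
        t = tally([BlockSpectrum(*map(int, c)) for c in counts])
        if tally_loglik(t.counts, tab_true) > tally_loglik(t.counts, tab_pert):
            wins += 1
    assert wins >= n_rep - 2
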