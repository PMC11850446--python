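"""Throughput sums, cycling, connectance, diversity and information indices."""

import math

import numpy as np
import pandas as pd
import pytest

from fwb import (
    CONSUMER,
    DETRITUS,
    PRODUCER,
    DietMatrix,
    FlowMatrix,
    FunctionalGroup,
    ModelDefinition,
    WebRecipe,
    connectance,
    finn_analysis,
    full_statistics,
    generate_web,
    information_indices,
    shannon_diversity,
    solve_balance,
    summary_statistics,
)

from conftest import make_w3, random_web


# ---------------------------------------------------------------------------
# flow sums and ratios
# ---------------------------------------------------------------------------

def test_w3_summary_sums(w3):
    b = solve_balance(w3)
    s = summary_statistics(b)
    assert s.sum_consumption == pytest.approx(105.0)
    assert s.sum_respiration == pytest.approx(63.0)
    assert s.sum_to_detritus == pytest.approx(937.0)
    assert s.TST == pytest.approx(1105.0)
    assert s.TPP == pytest.approx(1000.0)
    assert s.NSP == pytest.approx(937.0)
    assert s.TB == pytest.approx(31.0)
    assert s.TST == pytest.approx(
        s.sum_consumption + s.sum_exports + s.sum_respiration + s.sum_to_detritus
    )


def test_catch_becomes_export_and_raises_ee(w3):
    b0 = solve_balance(w3)
    w3["carn"].Y = 2.0
    b1 = solve_balance(w3)
    assert b1.flows.exports["carn"] == pytest.approx(2.0)
    assert b1.EE["carn"] > b0.EE["carn"]
    assert b1.EE["carn"] == pytest.approx(2.0 / 1.0, rel=1e-12)  # Y / P


# ---------------------------------------------------------------------------
# connectance
# ---------------------------------------------------------------------------

def test_w3_connectance(w3):
    # 2 links among 3 living groups
    assert connectance(w3) == pytest.approx(2.0 / 6.0)


def test_fully_connected_pair_has_connectance_one():
    groups = [
        FunctionalGroup("a", CONSUMER, B=1.0, PB=1.0, QB=5.0, UC=0.2),
        FunctionalGroup("b", CONSUMER, B=1.0, PB=1.0, QB=5.0, UC=0.2),
    ]
    diet = DietMatrix.empty(["a", "b"], ["a", "b"])
    diet.DC.loc["b", "a"] = 1.0
    diet.DC.loc["a", "b"] = 1.0
    assert connectance(ModelDefinition(groups, diet)) == pytest.approx(1.0)


def test_connectance_undefined_below_two_living_groups():
    m = ModelDefinition(
        [FunctionalGroup("p", PRODUCER, B=1.0, PB=10.0),
         FunctionalGroup("d", DETRITUS, B=1.0)],
        DietMatrix.empty(["p", "d"], []),
    )
    assert math.isnan(connectance(m))


# ---------------------------------------------------------------------------
# Finn cycling
# ---------------------------------------------------------------------------

def test_acyclic_web_has_zero_cycling(w3):
    b = solve_balance(w3)
    fin = finn_analysis(b.flows, w3)
    assert fin.FCI == pytest.approx(0.0, abs=1e-12)
    assert fin.throughput_cycled_incl == pytest.approx(0.0, abs=1e-12)
    assert fin.throughput_cycled_excl == pytest.approx(0.0, abs=1e-12)


def test_two_node_loop_matches_hand_leontief():
    """Detritus (import 4 + 6 recycled) <-> consumer eating 10: L diagonal
    2.5, cycled throughput 12 of compartmental throughput 20 -> 60%."""
    groups = [
        FunctionalGroup("det", DETRITUS, B=1.0, detritus_import=4.0),
        FunctionalGroup("cons", CONSUMER, B=1.0, PB=2.0, QB=10.0, UC=0.4),
    ]
    diet = DietMatrix.empty(["det", "cons"], ["cons"])
    diet.DC.loc["det", "cons"] = 1.0
    m = ModelDefinition(groups, diet)
    b = solve_balance(m)
    fin = finn_analysis(b.flows, m)
    assert np.allclose(np.diag(fin.analysis.L.to_numpy()), 2.5)
    assert fin.throughput_cycled_incl == pytest.approx(12.0)
    assert fin.FCI == pytest.approx(60.0)


def _power_series_cycled(G: np.ndarray, inflow: np.ndarray) -> float:
    """Path-enumeration oracle: L from the power series of G."""
    n = len(G)
    L = np.eye(n)
    term = np.eye(n)
    for _ in range(2000):
        term = term @ G
        L += term
        if np.abs(term).max() < 1e-16:
            break
    diag = np.diag(L)
    return float(np.sum(np.where(diag > 0, inflow * (diag - 1.0) / diag, 0.0)))


def test_fci_closed_form_equals_power_series():
    rng = np.random.default_rng(21)
    for _ in range(10):
        m = random_web(rng)
        b = solve_balance(m)
        fin = finn_analysis(b.flows, m)
        ca = fin.analysis
        oracle = _power_series_cycled(ca.G.to_numpy(), ca.inflow.to_numpy())
        assert fin.throughput_cycled_incl == pytest.approx(oracle, abs=1e-10)


def test_mean_path_length_definition(w3):
    w3["carn"].Y = 2.0
    b = solve_balance(w3)
    fin = finn_analysis(b.flows, w3)
    s = summary_statistics(b)
    assert fin.FML == pytest.approx(s.TST / (s.sum_exports + s.sum_respiration))


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def test_shannon_uniform_case():
    groups = [FunctionalGroup(f"c{i}", PRODUCER, B=3.0, PB=1.0) for i in range(4)]
    groups.append(FunctionalGroup("det", DETRITUS, B=99.0))
    m = ModelDefinition(groups, DietMatrix.empty([g.name for g in groups], []))
    assert shannon_diversity(solve_balance(m)) == pytest.approx(math.log(4))


def test_shannon_single_group_and_weighted_case():
    m1 = ModelDefinition(
        [FunctionalGroup("p", PRODUCER, B=5.0, PB=1.0),
         FunctionalGroup("det", DETRITUS, B=1.0)],
        DietMatrix.empty(["p", "det"], []),
    )
    assert shannon_diversity(solve_balance(m1)) == pytest.approx(0.0)
    groups = [
        FunctionalGroup("a", PRODUCER, B=2.0, PB=1.0),
        FunctionalGroup("b", PRODUCER, B=1.0, PB=1.0),
        FunctionalGroup("c", PRODUCER, B=1.0, PB=1.0),
        FunctionalGroup("det", DETRITUS, B=1.0),
    ]
    m2 = ModelDefinition(groups, DietMatrix.empty([g.name for g in groups], []))
    expect = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
    assert shannon_diversity(solve_balance(m2)) == pytest.approx(expect, abs=1e-4)


# ---------------------------------------------------------------------------
# information indices
# ---------------------------------------------------------------------------

def _flow_only(names, T, **kw) -> tuple[FlowMatrix, ModelDefinition]:
    idx = pd.Index(names, name="group")
    zeros = pd.Series(0.0, index=idx)
    fm = FlowMatrix(
        T=pd.DataFrame(T, index=idx, columns=idx),
        imports=kw.get("imports", zeros).copy(),
        exports=kw.get("exports", zeros).copy(),
        respiration=kw.get("respiration", zeros).copy(),
        to_detritus=zeros.copy(),
    )
    groups = [FunctionalGroup(n, CONSUMER, B=1.0, PB=1.0, QB=5.0, UC=0.2)
              for n in names]
    model = ModelDefinition(groups, DietMatrix.empty(names, names))
    return fm, model


def test_even_split_has_zero_ascendency():
    """One source feeding two sinks 5 + 5: A = 0, C = 10 flowbits."""
    T = np.zeros((3, 3))
    T[0, 1] = 5.0
    T[0, 2] = 5.0
    fm, m = _flow_only(["src", "a", "b"], T)
    C, A, ac = information_indices(fm, m)
    assert A == pytest.approx(0.0, abs=1e-12)
    assert C == pytest.approx(10.0)


def test_deterministic_chain_has_full_ascendency():
    T = np.zeros((3, 3))
    T[0, 1] = 10.0
    T[1, 2] = 10.0
    fm, m = _flow_only(["src", "a", "b"], T)
    C, A, ac = information_indices(fm, m)
    assert A == pytest.approx(C)
    assert ac == pytest.approx(100.0)


def test_information_inequality_on_random_webs():
    rng = np.random.default_rng(17)
    for _ in range(10):
        m = random_web(rng)
        b = solve_balance(m)
        C, A, ac = information_indices(b.flows, m)
        assert 0.0 <= A <= C + 1e-9
        assert 0.0 < ac <= 100.0


# ---------------------------------------------------------------------------
# structural invariances of the whole index suite
# ---------------------------------------------------------------------------

def _reorder(model: ModelDefinition, order: list[int]) -> ModelDefinition:
    groups = [model.groups[i].copy() for i in order]
    names = [g.name for g in groups]
    diet = DietMatrix.empty(names, [g.name for g in groups if g.is_consumer])
    for c in diet.DC.columns:
        for p in names:
            diet.DC.loc[p, c] = float(model.diet.DC.loc[p, c])
        diet.import_fraction[c] = float(model.diet.import_fraction[c])
    return ModelDefinition(groups, diet, dict(model.metadata))


def test_indices_invariant_to_group_reordering():
    m, _ = generate_web(WebRecipe(seed=3))
    rng = np.random.default_rng(0)
    order = list(rng.permutation(len(m.groups)))
    m2 = _reorder(m, order)
    s1 = full_statistics(solve_balance(m)).as_series()
    s2 = full_statistics(solve_balance(m2)).as_series()
    pd.testing.assert_series_equal(s1, s2, rtol=1e-9)


def test_zero_flow_group_is_inert():
    """Adding a group with no biomass or links changes no index."""
    m, _ = generate_web(WebRecipe(seed=4))
    s1 = full_statistics(solve_balance(m)).as_series()
    m.groups.append(FunctionalGroup("ghost", PRODUCER, B=0.0, PB=1.0))
    m.diet.DC.loc["ghost"] = 0.0
    s2 = full_statistics(solve_balance(m)).as_series()
    for k in s1.index:
        if k in ("CI",):   # N_living changes by construction
            continue
        v1, v2 = s1[k], s2[k]
        if isinstance(v1, float) and math.isnan(v1):
            assert math.isnan(v2)
        else:
            assert v2 == pytest.approx(v1, rel=1e-9), k
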