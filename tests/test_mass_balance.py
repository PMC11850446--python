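"""Mass-balance solver, budgets, diagnostics and diet auto-adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fwb import (
    CONSUMER,
    DETRITUS,
    PRODUCER,
    DietMatrix,
    FunctionalGroup,
    ModelDefinition,
    SolverError,
    auto_adjust_diet,
    compute_budget,
    detritus_budget,
    diagnose,
    solve_balance,
)

from conftest import make_w3, random_web


# ---------------------------------------------------------------------------
# solve_balance
# ---------------------------------------------------------------------------

def test_w3_hand_solved_ecotrophic_efficiencies(w3):
    """Predation on phyto = 10*10*1 = 100 over P = 1000 etc."""
    b = solve_balance(w3)
    assert b.EE["phyto"] == pytest.approx(0.100, abs=1e-12)
    assert b.EE["herb"] == pytest.approx(0.250, abs=1e-12)
    assert b.EE["carn"] == pytest.approx(0.0, abs=1e-12)


def test_producer_without_mortality_sinks_has_zero_ee():
    m = ModelDefinition(
        [FunctionalGroup("p", PRODUCER, B=5.0, PB=100.0),
         FunctionalGroup("d", DETRITUS, B=1.0)],
        DietMatrix.empty(["p", "d"], []),
    )
    assert solve_balance(m).EE["p"] == 0.0


@pytest.mark.parametrize("carn_qb,expected_ee", [(30.0, 1.5), (150.0, 7.5)])
def test_overconsumed_prey_returns_ee_above_one_flagged(carn_qb, expected_ee):
    """EE > 1 is returned as-is and flagged, never clamped or raised."""
    m = make_w3(carn_qb=carn_qb)
    b = solve_balance(m)
    assert b.EE["herb"] == pytest.approx(expected_ee, rel=1e-12)
    diag = diagnose(b)
    assert bool(diag.table.loc["herb", "flag_ee_gt_1"])
    assert not bool(diag.table.loc["carn", "flag_ee_gt_1"])


def test_solver_recovers_unknown_biomass():
    """With EE fixed at its solved value, the biomass unknowns invert back."""
    m = make_w3()
    solved = solve_balance(m)
    m2 = make_w3()
    m2["herb"].B = None
    m2["herb"].EE = float(solved.EE["herb"])
    back = solve_balance(m2)
    assert back.B["herb"] == pytest.approx(10.0, rel=1e-12)


def test_solver_rejects_ill_posed_groups():
    m = make_w3()
    m["herb"].B = None           # both unknown now
    with pytest.raises(SolverError, match="herb"):
        solve_balance(m)
    m2 = make_w3()
    m2["carn"].EE = 0.0          # nothing left to solve for
    with pytest.raises(SolverError, match="over-determined"):
        solve_balance(m2)


def test_negative_solved_biomass_is_an_error():
    # net immigration with no local sinks forces the balancing biomass < 0
    m = ModelDefinition(
        [FunctionalGroup("p", PRODUCER, B=None, PB=10.0, EE=0.5, NM=-10.0),
         FunctionalGroup("d", DETRITUS, B=1.0)],
        DietMatrix.empty(["p", "d"], []),
    )
    with pytest.raises(SolverError, match="negative"):
        solve_balance(m)


def test_equation_residuals_vanish_on_random_webs():
    """Substituting solved values back into the production balance -> ~0."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        m = random_web(rng)
        b = solve_balance(m)
        for g in m.living:
            lhs = b.P[g.name] * b.EE[g.name]
            rhs = g.Y + b.predation[g.name] + g.NM + g.BA
            assert abs(lhs - rhs) < 1e-9 * max(1.0, float(b.P.max()))


def test_predation_conservation():
    """Total predation equals total internal (non-import) consumption."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        m = random_web(rng)
        b = solve_balance(m)
        internal_q = sum(
            b.Q[g.name] * (1.0 - float(m.diet.import_fraction.get(g.name, 0.0)))
            for g in m.consumers
        )
        assert b.predation.sum() == pytest.approx(internal_q, rel=1e-12)


# ---------------------------------------------------------------------------
# budgets
# ---------------------------------------------------------------------------

def test_budget_arithmetic():
    b = compute_budget(Q=10.0, UC=0.2, P=2.0)
    assert b.R == pytest.approx(6.0)
    assert b.GE == pytest.approx(0.2)
    assert b.RA == pytest.approx(0.75)
    assert b.PR == pytest.approx(1.0 / 3.0)


@settings(derandomize=True, max_examples=200)
@given(
    q=st.floats(0.1, 1e4),
    uc=st.floats(0.0, 0.95),
    ge=st.floats(0.01, 1.5),
)
def test_budget_identity_holds_for_any_inputs(q, uc, ge):
    """Q = P + R + UC*Q by construction; GE and RA stay consistent."""
    p = ge * q
    b = compute_budget(Q=q, UC=uc, P=p)
    assert q == pytest.approx(p + b.R + uc * q, rel=1e-9)
    assert b.GE == pytest.approx(ge, rel=1e-12)
    # respiration is negative exactly when production exceeds assimilation
    assert (b.R < 0) == (ge > 1 - uc)


def test_budget_zero_respiration_sentinel():
    b = compute_budget(Q=10.0, UC=0.0, P=10.0)
    assert b.R == 0.0
    assert math.isnan(b.PR)


def test_w3_herbivore_respiration(w3):
    b = solve_balance(w3)
    assert b.R["herb"] == pytest.approx(60.0)
    assert b.R["carn"] == pytest.approx(3.0)
    # energy balance Q = P + R + UC*Q for every consumer
    for g in w3.consumers:
        q = b.Q[g.name]
        assert q == pytest.approx(b.P[g.name] + b.R[g.name] + g.UC * q, rel=1e-9)


def test_producer_respiration_is_optional_input():
    m = make_w3()
    m["phyto"].R = 123.0
    b = solve_balance(m)
    assert b.R["phyto"] == 123.0


# ---------------------------------------------------------------------------
# detritus budget
# ---------------------------------------------------------------------------

def test_w3_detritus_budget_components(w3):
    """900 (phyto unutilized) + 35 (herb) + 2 (carn) flow to detritus."""
    b = solve_balance(w3)
    db = detritus_budget(b)
    assert db.inflow == pytest.approx(937.0)
    assert db.unassimilated == pytest.approx(21.0)   # 20 herb + 1 carn
    assert db.unutilized == pytest.approx(916.0)     # 900 + 15 + 1
    assert db.outflow == 0.0
    assert db.EE == 0.0


def test_detritus_import_is_additive(w3):
    w3["detritus"].detritus_import = 5.0
    db = detritus_budget(solve_balance(w3))
    assert db.inflow == pytest.approx(942.0)


def test_detritivore_consuming_exact_inflow_gives_detritus_ee_one():
    groups = [
        FunctionalGroup("det", DETRITUS, B=1.0, detritus_import=4.0),
        FunctionalGroup("cons", CONSUMER, B=1.0, PB=2.0, QB=10.0, UC=0.4),
    ]
    diet = DietMatrix.empty(["det", "cons"], ["cons"])
    diet.DC.loc["det", "cons"] = 1.0
    b = solve_balance(ModelDefinition(groups, diet))
    db = detritus_budget(b)
    # inflow = import 4 + unassimilated 4 + unutilized 2 = 10 = consumption
    assert db.inflow == pytest.approx(10.0)
    assert db.EE == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def test_w3_diagnostics_clean(w3):
    assert diagnose(solve_balance(w3)).ok


def test_gross_efficiency_out_of_band_flagged(w3):
    w3["herb"].PB = 3.5          # GE = 0.35
    diag = diagnose(solve_balance(w3))
    assert bool(diag.table.loc["herb", "flag_ge_range"])
    assert diag.table.loc["herb", "GE"] == pytest.approx(0.35)


# ---------------------------------------------------------------------------
# auto-adjustment
# ---------------------------------------------------------------------------

def test_balanced_model_is_a_fixed_point(w3):
    res = auto_adjust_diet(w3)
    assert res.balanced and res.log == [] and res.iterations == 0
    assert (res.model.diet.DC.to_numpy() == w3.diet.DC.to_numpy()).all()


def test_adjustment_drives_ee_down_and_keeps_normalization():
    m = make_w3(carn_qb=150.0)   # EE_herb = 7.5
    res = auto_adjust_diet(m, max_iter=100)
    assert res.balanced
    b = solve_balance(res.model)
    assert b.EE["herb"] <= 1.0 + 1e-3
    assert res.model.diet.column_sum("carn") == pytest.approx(1.0, abs=1e-9)
    # the freed diet went to detritus (the carnivore's only alternative)
    assert res.model.diet.DC.loc["detritus", "carn"] > 0
    assert all(entry["new"] < entry["old"] for entry in res.log)


def test_shared_prey_reduced_proportionally_to_demand():
    """One over-consumed prey, two predators: per-predator demand reduction
    is proportional to each predator's share of total demand."""
    groups = [
        FunctionalGroup("det", DETRITUS, B=1.0),
        FunctionalGroup("p", PRODUCER, B=50.0, PB=10.0),
        FunctionalGroup("prey", CONSUMER, B=5.0, PB=2.0, QB=10.0, UC=0.2),
        FunctionalGroup("pred_a", CONSUMER, B=2.0, PB=1.0, QB=5.0, UC=0.2),
        FunctionalGroup("pred_b", CONSUMER, B=1.0, PB=1.0, QB=5.0, UC=0.2),
    ]
    diet = DietMatrix.empty([g.name for g in groups], ["prey", "pred_a", "pred_b"])
    diet.DC.loc["p", "prey"] = 1.0
    diet.DC.loc["prey", "pred_a"] = 1.0
    diet.DC.loc["prey", "pred_b"] = 1.0
    m = ModelDefinition(groups, diet)
    b = solve_balance(m)
    ee0 = float(b.EE["prey"])    # (10 + 5)/10 = 1.5
    assert ee0 == pytest.approx(1.5)
    res = auto_adjust_diet(m, max_iter=1)
    changes = {e["predator"]: e for e in res.log if e["prey"] == "prey"}
    assert set(changes) == {"pred_a", "pred_b"}
    # multiplicative trim: demand reduction per predator = Q_j * dDC,
    # so reductions stand in the same 2:1 ratio as the demands
    red_a = (changes["pred_a"]["old"] - changes["pred_a"]["new"]) * 2.0 * 5.0
    red_b = (changes["pred_b"]["old"] - changes["pred_b"]["new"]) * 1.0 * 5.0
    assert red_a / red_b == pytest.approx(2.0, rel=1e-12)
    # hand-trace: overshoot = 0.5/1.5, factor = 1 - 0.1/3
    assert changes["pred_a"]["new"] == pytest.approx(1.0 - 0.1 * (0.5 / 1.5))
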