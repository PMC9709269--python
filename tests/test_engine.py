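"""Engine-level unit and property tests: buffers, prims, selection, learning."""

from __future__ import annotations

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refbias.engine import (NIL, AmbiguousRetrieval, AssociationStore,
                            BufferSet, Chunk, EngineConfig, Operator, Prim,
                            RetrievalFailure, SlotError, activation,
                            apply_outcome, apply_reward, eval_conditions,
                            execute_actions, retrieve_chunk, select_operator,
                            slot)


# ---------------------------------------------------------------------------
# Slots, prims, chunks, buffers

def test_slot_parsing():
    assert slot("WM3") == ("WM", 3)
    assert slot("V1") == ("V", 1)
    assert slot("RT4") == ("RT", 4)
    assert slot("AC1") == ("AC", 1)


@pytest.mark.parametrize("bad", ["WM6", "V0", "RT5", "XX1", "WM", "wm1", ""])
def test_slot_parsing_rejects_bad_addresses(bad):
    with pytest.raises(SlotError):
        slot(bad)


def test_prim_validation():
    Prim("cmp_eq", slot("WM1"), slot("WM5"))  # valid
    with pytest.raises(SlotError):
        Prim("cmp_eq", slot("WM1"))  # needs two addresses
    with pytest.raises(SlotError):
        Prim("is_nil", slot("WM1"), slot("WM2"))  # single-slot condition
    with pytest.raises(SlotError):
        Prim("copy", "", slot("WM1"))  # bad source
    with pytest.raises(SlotError):
        Prim("set_const", "she")  # missing destination
    with pytest.raises(SlotError):
        Prim("teleport", slot("WM1"))  # unknown kind


def test_chunk_lexical_entry():
    c = Chunk.lexical_entry("kathy", "noun")
    assert c.meaning == "c-kathy"
    assert c.rt_values() == ("lexical-entry", "kathy", "noun", "c-kathy")


def test_buffer_context_is_wm1_to_wm3_only():
    b = BufferSet()
    b.WM[:] = ["leah", "fascinated", None, "she", "leah"]
    assert b.context() == ("leah", "fascinated")


# ---------------------------------------------------------------------------
# Condition evaluation

def _predict_subj():
    return Operator("predict-subj",
                    [Prim("not_nil", slot("WM3")), Prim("is_nil", slot("WM4")),
                     Prim("is_nil", slot("WM5"))],
                    [Prim("copy", slot("WM1"), slot("WM5"))])


def test_eval_conditions_predict_subj_true():
    b = BufferSet()
    b.WM[:] = ["leah", "fascinated", "kathy", None, None]
    assert eval_conditions(_predict_subj(), b)


def test_eval_conditions_predict_subj_false_when_wm5_filled():
    b = BufferSet()
    b.WM[:] = ["leah", "fascinated", "kathy", None, "leah"]
    assert not eval_conditions(_predict_subj(), b)


def test_eval_conditions_inequality():
    op = Operator("store-V1", [Prim("cmp_eq", slot("V1"), slot("RT2"))],
                  [Prim("copy", slot("RT2"), slot("WM1"))])
    b = BufferSet()
    b.V[0], b.RT[1] = "leah", "kathy"
    assert not eval_conditions(op, b)
    b.RT[1] = "leah"
    assert eval_conditions(op, b)


def test_cmp_eq_requires_both_slots_filled():
    """WM1 = WM5 must NOT hold when both are empty (gating at trial start)."""
    op = Operator("eq", [Prim("cmp_eq", slot("WM1"), slot("WM5"))], [])
    b = BufferSet()
    assert not eval_conditions(op, b)
    b.WM[0] = b.WM[4] = "leah"
    assert eval_conditions(op, b)


def test_cmp_ne_requires_both_slots_filled():
    op = Operator("ne", [Prim("cmp_ne", slot("WM4"), slot("V1"))], [])
    b = BufferSet()
    assert not eval_conditions(op, b)
    b.WM[3] = "leah"
    assert not eval_conditions(op, b)  # V1 still empty
    b.V[0] = "she"
    assert eval_conditions(op, b)


def test_eval_conditions_does_not_mutate_buffers():
    b = BufferSet()
    b.WM[:] = ["leah", "fascinated", "kathy", None, None]
    before = b.as_dict()
    eval_conditions(_predict_subj(), b)
    assert b.as_dict() == before


# ---------------------------------------------------------------------------
# Action execution and retrieval

def test_execute_actions_copy():
    b = BufferSet()
    b.WM[:] = ["leah", "fascinated", "kathy", None, None]
    execute_actions(_predict_subj(), b)
    assert b.WM[4] == "leah"


def test_execute_actions_copy_from_empty_slot_is_an_error():
    b = BufferSet()
    with pytest.raises(SlotError):
        execute_actions(_predict_subj(), b)


def test_execute_actions_ext_action_signal():
    op = Operator("go", [], [Prim("ext_action", "read-next", slot("AC1"))])
    b = BufferSet()
    _, signals = execute_actions(op, b)
    assert signals == ("read-next",)
    assert b.AC[0] == "read-next"


def test_execute_actions_rt_write_without_lexicon_signals_request():
    op = Operator("req", [], [Prim("set_const", "lexical-entry", slot("RT1")),
                              Prim("set_const", "pronoun", slot("RT3"))])
    b = BufferSet()
    _, signals = execute_actions(op, b)
    assert "retrieval-request" in signals


def test_execute_actions_rt_write_with_lexicon_resolves_chunk():
    lexicon = [Chunk.lexical_entry("leah", "noun"),
               Chunk("she", "lexical-entry", "she", "pronoun", "c-she")]
    op = Operator("req", [], [Prim("set_const", "lexical-entry", slot("RT1")),
                              Prim("set_const", "pronoun", slot("RT3"))])
    b = BufferSet()
    execute_actions(op, b, lexicon)
    assert b.RT == ["lexical-entry", "she", "pronoun", "c-she"]


def test_retrieve_chunk_unique_zero_and_ambiguous():
    lexicon = [Chunk.lexical_entry("leah", "noun"),
               Chunk.lexical_entry("kathy", "noun"),
               Chunk("she", "lexical-entry", "she", "pronoun", "c-she")]
    assert retrieve_chunk({"form": "leah"}, lexicon).form == "leah"
    assert retrieve_chunk({"pos": "pronoun"}, lexicon).form == "she"
    with pytest.raises(RetrievalFailure):
        retrieve_chunk({"form": "zzz"}, lexicon)
    with pytest.raises(AmbiguousRetrieval):
        retrieve_chunk({"pos": "noun"}, lexicon)
    with pytest.raises(RetrievalFailure):
        retrieve_chunk({}, lexicon)


# ---------------------------------------------------------------------------
# Activation and selection

def test_activation_empty_store_is_zero():
    op = _predict_subj()
    assert activation(op, ("leah", "fascinated", "kathy"),
                      AssociationStore()) == 0.0


def test_activation_is_additive_over_context():
    store = AssociationStore({("fascinated", "predict-subj"): 0.4,
                              ("leah", "predict-subj"): 0.1})
    op = _predict_subj()
    assert activation(op, ("leah", "fascinated", "kathy"),
                      store) == pytest.approx(0.5)


def test_activation_ignores_values_outside_wm1_to_wm3():
    store = AssociationStore({("leah", "predict-subj"): 0.9})
    b = BufferSet()
    b.WM[:] = ["mara", "fascinated", "kathy", None, "leah"]  # leah only in WM5
    assert activation(_predict_subj(), b.context(), store) == 0.0


def _two_competitors():
    cond = [Prim("not_nil", slot("WM3")), Prim("is_nil", slot("WM5"))]
    a = Operator("op-a", cond, [Prim("copy", slot("WM1"), slot("WM5"))])
    b = Operator("op-b", cond, [Prim("copy", slot("WM3"), slot("WM5"))])
    buffers = BufferSet()
    buffers.WM[:] = ["leah", "fascinated", "kathy", None, None]
    return (a, b), buffers


def test_symmetry_at_chance():
    """All-zero store: two condition-equivalent competitors split 50/50 +-3pp."""
    (a, b), buffers = _two_competitors()
    cfg = EngineConfig(noise_sd=0.1, rng_seed=7)
    rng = random.Random(123)
    store = AssociationStore()
    n = 10_000
    wins = sum(select_operator([a, b], buffers, store, cfg, rng).name == "op-a"
               for _ in range(n))
    assert abs(wins / n - 0.5) < 0.03


def test_selection_monotone_in_strength():
    (a, b), buffers = _two_competitors()
    cfg = EngineConfig(noise_sd=0.1)

    def win_rate(strength: float, draws: int = 4000) -> float:
        store = AssociationStore({("fascinated", "op-a"): strength})
        rng = random.Random(99)
        return sum(select_operator([a, b], buffers, store, cfg, rng).name
                   == "op-a" for _ in range(draws)) / draws

    r0, r1, r2 = win_rate(0.0), win_rate(0.2), win_rate(0.6)
    assert r0 < r1 < r2


def test_condition_gating_skips_highest_activation():
    """The highest-scoring candidate is skipped when its conditions fail."""
    cond_ok = [Prim("not_nil", slot("WM3"))]
    cond_fail = [Prim("cmp_eq", slot("WM3"), slot("WM5"))]  # WM5 empty
    winner = Operator("gated", cond_fail, [])
    runner_up = Operator("eligible", cond_ok, [])
    buffers = BufferSet()
    buffers.WM[:] = ["leah", "fascinated", "kathy", None, None]
    store = AssociationStore({("kathy", "gated"): 5.0})
    cfg = EngineConfig(noise_sd=0.0)
    chosen = select_operator([winner, runner_up], buffers, store, cfg,
                             random.Random(0))
    assert chosen.name == "eligible"


def test_select_operator_returns_none_when_all_gated():
    gated = Operator("gated", [Prim("not_nil", slot("V3"))], [])
    buffers = BufferSet()
    assert select_operator([gated], buffers, AssociationStore(),
                           EngineConfig(), random.Random(0)) is None


def test_selection_deterministic_under_seed():
    (a, b), buffers = _two_competitors()
    store = AssociationStore({("leah", "op-a"): 0.1})
    cfg = EngineConfig(noise_sd=0.2)
    rng1, rng2 = random.Random(42), random.Random(42)
    t1 = [select_operator([a, b], buffers, store, cfg, rng1).name
          for _ in range(200)]
    t2 = [select_operator([a, b], buffers, store, cfg, rng2).name
          for _ in range(200)]
    assert t1 == t2


# ---------------------------------------------------------------------------
# Learning

def test_delta_rule_single_step():
    store = AssociationStore()
    cfg = EngineConfig(alpha=0.2, reward=1.0)
    apply_reward(["predict-subj"], ("leah",), store, cfg)
    assert store.get("leah", "predict-subj") == pytest.approx(0.2)


def test_delta_rule_fixed_point_at_reward():
    store = AssociationStore({("leah", "predict-subj"): 1.0})
    cfg = EngineConfig(alpha=0.2, reward=1.0)
    apply_reward(["predict-subj"], ("leah",), store, cfg)
    assert store.get("leah", "predict-subj") == pytest.approx(1.0)


def test_non_fired_operators_unchanged():
    store = AssociationStore({("leah", "predict-obj"): 0.3})
    apply_reward(["predict-subj"], ("leah",), store, EngineConfig())
    assert store.get("leah", "predict-obj") == pytest.approx(0.3)


def test_apply_outcome_moves_toward_failure_target():
    store = AssociationStore({("leah", "predict-subj"): 0.5})
    cfg = EngineConfig(alpha=0.2)
    apply_outcome(["predict-subj"], ("leah",), store, cfg, target=0.0)
    assert store.get("leah", "predict-subj") == pytest.approx(0.4)


def test_duplicate_context_symbols_update_once():
    store = AssociationStore()
    cfg = EngineConfig(alpha=0.2, reward=1.0)
    apply_reward(["predict-subj", "predict-subj"], ("leah", "leah"),
                 store, cfg)
    assert store.get("leah", "predict-subj") == pytest.approx(0.2)


@settings(max_examples=200, deadline=None)
@given(st.lists(st.tuples(st.booleans(), st.integers(0, 2)),
                min_size=1, max_size=60),
       st.floats(0.01, 1.0), st.floats(0.1, 3.0))
def test_strength_boundedness(steps, alpha, reward):
    """After any reward/failure update sequence, strengths stay in [0, R]."""
    cfg = EngineConfig(alpha=alpha, reward=reward, failure_target=0.0)
    store = AssociationStore()
    ops = ["op-a", "op-b", "op-c"]
    for rewarded, which in steps:
        if rewarded:
            apply_reward([ops[which]], ("ctx",), store, cfg)
        else:
            apply_outcome([ops[which]], ("ctx",), store, cfg,
                          cfg.failure_target)
        for _, value in store.items():
            assert 0.0 <= value <= reward + 1e-12


def test_engine_config_validation():
    with pytest.raises(ValueError):
        EngineConfig(alpha=0.0)
    with pytest.raises(ValueError):
        EngineConfig(reward=-1.0)
    with pytest.raises(ValueError):
        EngineConfig(noise_sd=-0.1)
    with pytest.raises(ValueError):
        EngineConfig(failure_target=2.0)  # above reward


def test_association_store_round_trip_and_copy():
    store = AssociationStore({("leah", "predict-subj"): 0.25,
                              ("fascinated", "predict-obj"): 0.5})
    again = AssociationStore.from_json(store.to_json())
    assert again == store
    clone = store.copy()
    clone.set("leah", "predict-subj", 0.9)
    assert store.get("leah", "predict-subj") == pytest.approx(0.25)
    assert not math.isnan(store.total_mass())
    assert store.total_mass() == pytest.approx(0.75)
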