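"""The reference-learning model.

A trial has four stages, all driven by the same generic operator-selection
loop over one fixed set of 14 operators:

1. *Comprehension* — the transitive sentence sits in the input buffer
   (V1=subject, V2=verb, V3=object); retrieve/store operator pairs move each
   word through declarative retrieval into working memory (WM1..WM3).
2. *Referent prediction* — predict-subj or predict-obj copies the subject or
   object into WM5.
3. *Form prediction* — predict-subj-name / predict-obj-name write the
   predicted name into WM4, or predict-pro (followed by retrieve-pro) writes
   the pronoun "she"; either path triggers the read-next action that presents
   the actual continuation.
4. *Observation* — the continuation arrives as V1=form token, V2=referent.
   If both WM4 and WM5 match, a reward strengthens the associations between
   the sentence context (WM1..WM3 values) and every operator fired this
   trial; otherwise revision operators re-align working memory with the
   actual continuation.

Which operator wins a selection is decided by noisy associative activation,
but an operator only fires if its condition prims hold — this condition
gating (e.g. predict-obj-name requires WM3 = WM5) is what produces the
model's asymmetric verb-type x form interaction.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .corpus import (NAME, OBJECT, PRONOUN, PRONOUN_TOKEN, SUBJECT, InputItem)
from .engine import (AmbiguousRetrieval, AssociationStore, BufferSet, Chunk,
                     EngineConfig, EngineError, Operator, Prim, RetrievalFailure,
                     apply_outcome, apply_reward, execute_actions,
                     select_operator, slot)

__all__ = [
    "Lexicon",
    "TrialRecord",
    "ModelError",
    "build_lexicon",
    "build_operators",
    "ReferenceModel",
    "comprehend_sentence",
    "predict_continuation",
    "observe_continuation",
    "run_trial",
]

_MAX_FIRINGS = 50  # hard safety bound on operator firings per trial


class ModelError(EngineError):
    """The trial loop reached a state no operator can leave."""


class Lexicon:
    """Declarative memory: one lexical-entry chunk per word form.

    Covers every verb, every name, and the single pronoun "she" (only female
    referents occur in the input).  Forms are unique, so retrieval by form is
    unambiguous.
    """

    def __init__(self, chunks: Sequence[Chunk]):
        self._by_form: dict[str, Chunk] = {}
        self._by_pos: dict[str, list[Chunk]] = {}
        for chunk in chunks:
            if chunk.form in self._by_form:
                raise ValueError(f"duplicate word form: {chunk.form!r}")
            self._by_form[chunk.form] = chunk
            self._by_pos.setdefault(chunk.pos, []).append(chunk)
        if len(self._by_pos.get("pronoun", [])) != 1:
            raise ValueError("lexicon must contain exactly one pronoun chunk")

    @property
    def chunks(self) -> tuple[Chunk, ...]:
        return tuple(self._by_form.values())

    def __len__(self) -> int:
        return len(self._by_form)

    def __contains__(self, form: str) -> bool:
        return form in self._by_form

    def __iter__(self):
        return iter(self._by_form.values())

    def retrieve(self, request: Mapping[str, str]) -> Chunk:
        """Exact-match retrieval (fast path used by the engine)."""
        form = request.get("form")
        if form is not None:
            chunk = self._by_form.get(form)
            candidates = [chunk] if chunk is not None else []
        elif "pos" in request:
            candidates = list(self._by_pos.get(request["pos"], []))
        else:
            candidates = list(self._by_form.values())
        matches = [c for c in candidates
                   if all(getattr(c, k) == v for k, v in request.items())]
        if not matches:
            raise RetrievalFailure(f"no chunk matches {dict(request)!r}")
        if len(matches) > 1:
            raise AmbiguousRetrieval(f"ambiguous request {dict(request)!r}")
        return matches[0]

    def extended(self, verbs: Sequence[str] = (),
                 names: Sequence[str] = ()) -> "Lexicon":
        """A new lexicon with additional (novel) verbs and names."""
        extra = ([Chunk.lexical_entry(v, "verb") for v in verbs]
                 + [Chunk.lexical_entry(n, "noun") for n in names])
        return Lexicon(tuple(self.chunks) + tuple(extra))


def build_lexicon(verbs: Sequence[str], names: Sequence[str]) -> Lexicon:
    """One chunk per verb and per name, plus the pronoun chunk for "she"."""
    if not verbs or not names:
        raise ValueError("verbs and names must be non-empty")
    if set(verbs) & set(names):
        raise ValueError("verbs and names must be disjoint")
    chunks = ([Chunk.lexical_entry(v, "verb") for v in verbs]
              + [Chunk.lexical_entry(n, "noun") for n in names]
              + [Chunk("she", "lexical-entry", PRONOUN_TOKEN, "pronoun",
                       "c-she")])
    return Lexicon(chunks)


# ---------------------------------------------------------------------------
# The fixed operator set

def _eq(a: str, b: str) -> Prim:
    return Prim("cmp_eq", slot(a), slot(b))


def _ne(a: str, b: str) -> Prim:
    return Prim("cmp_ne", slot(a), slot(b))


def _nil(a: str) -> Prim:
    return Prim("is_nil", slot(a))


def _filled(a: str) -> Prim:
    return Prim("not_nil", slot(a))


def _copy(src: str, dst: str) -> Prim:
    return Prim("copy", slot(src), slot(dst))


def _const(value: str, dst: str) -> Prim:
    return Prim("set_const", value, slot(dst))


def _signal(value: str) -> Prim:
    return Prim("ext_action", value, slot("AC1"))


def build_operators() -> tuple[Operator, ...]:
    """The model's 14 operators.

    Six comprehension operators (a retrieve/store pair per sentence word; the
    k>1 pairs additionally require the previous WM slot to be filled, which
    enforces left-to-right word order), two referent-prediction operators,
    four form-prediction operators, and two revision operators.
    """
    ops: list[Operator] = []
    for k in (1, 2, 3):
        r_conds = [_filled(f"V{k}"), _nil("RT1"), _nil(f"WM{k}")]
        s_conds = [_eq(f"V{k}", "RT2"), _nil(f"WM{k}")]
        if k > 1:
            r_conds.append(_filled(f"WM{k - 1}"))
            s_conds.append(_filled(f"WM{k - 1}"))
        ops.append(Operator(f"retrieve-V{k}", r_conds,
                            [_const("lexical-entry", "RT1"),
                             _copy(f"V{k}", "RT2")]))
        ops.append(Operator(f"store-V{k}", s_conds,
                            [_copy("RT2", f"WM{k}")]))

    predict_conds = [_filled("WM3"), _nil("WM4"), _nil("WM5")]
    ops.append(Operator("predict-subj", predict_conds, [_copy("WM1", "WM5")]))
    ops.append(Operator("predict-obj", predict_conds, [_copy("WM3", "WM5")]))

    ops.append(Operator("predict-subj-name",
                        [_nil("WM4"), _eq("WM1", "WM5"), _nil("RT1")],
                        [_copy("WM5", "WM4"), _signal("read-next")]))
    ops.append(Operator("predict-obj-name",
                        [_nil("WM4"), _eq("WM3", "WM5"), _nil("RT1")],
                        [_copy("WM5", "WM4"), _signal("read-next")]))
    ops.append(Operator("predict-pro",
                        [_nil("WM4"), _filled("WM5"), _nil("RT1")],
                        [_const("lexical-entry", "RT1"),
                         _const("pronoun", "RT3")]))
    ops.append(Operator("retrieve-pro",
                        [_nil("WM4"), _filled("WM5"), _filled("RT1")],
                        [_copy("RT2", "WM4"), _signal("read-next")]))

    ops.append(Operator("correct-re", [_ne("WM4", "V1"), _nil("V3")],
                        [_copy("V1", "WM4")]))
    ops.append(Operator("correct-ref", [_ne("WM5", "V2"), _nil("V3")],
                        [_copy("V2", "WM5")]))

    for i, op in enumerate(ops):
        op.index = i
    return tuple(ops)


REVISION_OPERATORS = frozenset({"correct-re", "correct-ref"})


@dataclass(frozen=True, slots=True)
class TrialRecord:
    """Everything recorded about one training trial."""

    item_id: int
    verb: str
    verb_category: str | None
    predicted_role: str
    predicted_form: str
    actual_role: str
    actual_form: str
    rewarded: bool
    fired_ops: tuple[str, ...]
    trial_index: int


class ReferenceModel:
    """A single simulated language learner.

    Holds the lexicon, the fixed operator set, the (initially empty)
    association store and a private random stream.  ``run_trial`` executes
    the full comprehend -> predict -> observe cycle on one input item and
    learns from the outcome; ``predict_item`` runs only comprehension and
    prediction (used for the frozen-learning novel-item evaluation).
    """

    def __init__(self, lexicon: Lexicon, cfg: EngineConfig,
                 operators: Sequence[Operator] | None = None,
                 store: AssociationStore | None = None,
                 verb_categories: Mapping[str, str] | None = None):
        self.lexicon = lexicon
        self.cfg = cfg
        self.operators = tuple(operators) if operators else build_operators()
        self.store = store if store is not None else AssociationStore()
        self.verb_categories = dict(verb_categories or {})
        self.rng = random.Random(cfg.rng_seed)
        self.buffers = BufferSet()
        self._fired: list[str] = []

    # -- generic selection-execution step ---------------------------------
    def _fire_next(self) -> tuple[Operator | None, tuple[str, ...]]:
        op = select_operator(self.operators, self.buffers, self.store,
                             self.cfg, self.rng)
        if op is None:
            return None, ()
        _, signals = execute_actions(op, self.buffers, self.lexicon)
        self._fired.append(op.name)
        if op.name.startswith("store-V"):
            # the store operator consumes the retrieved chunk; clearing RT
            # lets the next retrieve operator place a fresh request
            self.buffers.clear("RT")
        return op, signals

    # -- trial stages ------------------------------------------------------
    def start_trial(self) -> None:
        self.buffers.clear()
        self._fired = []

    def comprehend(self, subject: str, verb: str, obj: str) -> BufferSet:
        """Process the transitive sentence word-by-word into WM1..WM3."""
        b = self.buffers
        if b.WM[0] is not None or b.WM[1] is not None or b.WM[2] is not None:
            raise ModelError("working memory must be empty before comprehension")
        b.V[:] = [subject, verb, obj]
        steps = 0
        while b.WM[2] is None:
            op, _ = self._fire_next()
            if op is None:
                raise ModelError("no operator eligible during comprehension")
            steps += 1
            if steps > _MAX_FIRINGS:
                raise ModelError("comprehension did not converge")
        return b

    def predict(self) -> tuple[str, str]:
        """Predict the next referent (WM5) and its form (WM4).

        Returns ``(predicted_role, predicted_form)``; ends when a form
        operator emits the read-next action.
        """
        b = self.buffers
        if b.WM[2] is None or b.WM[3] is not None or b.WM[4] is not None:
            raise ModelError("prediction requires WM1..3 filled, WM4/WM5 empty")
        steps = 0
        while True:
            op, signals = self._fire_next()
            if op is None:
                raise ModelError("no operator eligible during prediction")
            if "read-next" in signals:
                self.buffers.AC[0] = None  # the signal does not persist
                break
            steps += 1
            if steps > _MAX_FIRINGS:
                raise ModelError("prediction did not converge")
        role = SUBJECT if b.WM[4] == b.WM[0] else OBJECT
        form = PRONOUN if b.WM[3] == PRONOUN_TOKEN else NAME
        return role, form

    def observe(self, item: InputItem) -> bool:
        """Present the actual continuation; learn on reward, revise otherwise.

        The continuation is presented as V1 = surface form token and
        V2 = referent.  Returns whether the trial was rewarded.  After this
        stage WM4 holds the actual form token and WM5 the actual referent,
        rewarded or not.
        """
        if not item.has_continuation:
            raise ModelError("observe() needs an item with a continuation")
        b = self.buffers
        prediction_ops = list(self._fired)
        b.V[:] = [item.continuation_token, item.continuation_referent, None]
        rewarded = (b.WM[3] == b.V[0]) and (b.WM[4] == b.V[1])
        if self.cfg.learning_enabled:
            context = b.context()
            if rewarded:
                apply_reward(prediction_ops, context, self.store, self.cfg)
            elif self.cfg.failure_target is not None:
                apply_outcome(prediction_ops, context, self.store, self.cfg,
                              self.cfg.failure_target)
        # revision: re-align working memory with the actual continuation
        steps = 0
        while True:
            op, _ = self._fire_next()
            if op is None:
                break
            steps += 1
            if steps > _MAX_FIRINGS:
                raise ModelError("revision did not converge")
        return rewarded

    def run_trial(self, item: InputItem, trial_index: int = 0) -> TrialRecord:
        """Full comprehend -> predict -> observe cycle on one training item."""
        self.start_trial()
        self.comprehend(item.subject_name, item.verb, item.object_name)
        role, form = self.predict()
        rewarded = self.observe(item)
        return TrialRecord(
            item_id=item.item_id,
            verb=item.verb,
            verb_category=self.verb_categories.get(item.verb),
            predicted_role=role,
            predicted_form=form,
            actual_role=item.continuation_role,  # type: ignore[arg-type]
            actual_form=item.continuation_form,  # type: ignore[arg-type]
            rewarded=rewarded,
            fired_ops=tuple(self._fired),
            trial_index=trial_index,
        )

    def predict_item(self, item: InputItem) -> tuple[str, str]:
        """Comprehension plus prediction only — no outcome, no learning."""
        self.start_trial()
        self.comprehend(item.subject_name, item.verb, item.object_name)
        return self.predict()

    # -- state management ---------------------------------------------------
    def frozen(self) -> "ReferenceModel":
        """A view of this model with learning disabled (shared store)."""
        cfg = replace(self.cfg, learning_enabled=False)
        return ReferenceModel(self.lexicon, cfg, self.operators, self.store,
                              self.verb_categories)

    def extend_lexicon(self, verbs: Sequence[str] = (),
                       names: Sequence[str] = ()) -> None:
        """Add novel tokens so comprehension retrieval can succeed; the new
        tokens carry zero associations by construction."""
        self.lexicon = self.lexicon.extended(verbs=verbs, names=names)

    def state_json(self) -> str:
        return json.dumps({
            "config": {
                "alpha": self.cfg.alpha,
                "reward": self.cfg.reward,
                "noise_sd": self.cfg.noise_sd,
                "learning_enabled": self.cfg.learning_enabled,
                "failure_target": self.cfg.failure_target,
                "rng_seed": self.cfg.rng_seed,
            },
            "store": json.loads(self.store.to_json()),
        }, sort_keys=True)

    @classmethod
    def from_state_json(cls, text: str, lexicon: Lexicon,
                        verb_categories: Mapping[str, str] | None = None
                        ) -> "ReferenceModel":
        state = json.loads(text)
        cfg = EngineConfig(**state["config"])
        store = AssociationStore.from_json(json.dumps(state["store"]))
        return cls(lexicon, cfg, store=store, verb_categories=verb_categories)


# ---------------------------------------------------------------------------
# Functional wrappers over the staged trial loop

def comprehend_sentence(item: InputItem, model: ReferenceModel) -> BufferSet:
    model.start_trial()
    return model.comprehend(item.subject_name, item.verb, item.object_name)


def predict_continuation(model: ReferenceModel,
                         buffers: BufferSet | None = None) -> tuple[str, str]:
    if buffers is not None and buffers is not model.buffers:
        model.buffers = buffers
    return model.predict()


def observe_continuation(buffers: BufferSet, item: InputItem,
                         model: ReferenceModel) -> bool:
    if buffers is not model.buffers:
        model.buffers = buffers
    return model.observe(item)


def run_trial(item: InputItem, model: ReferenceModel,
              trial_index: int = 0) -> TrialRecord:
    return model.run_trial(item, trial_index)
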