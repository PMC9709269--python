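"""Minimal operator-based production engine.

The engine provides the machinery that the reference-learning model is built
on: a small set of buffers whose ordered, unlabeled slots hold symbols; prims
(primitive condition/action elements) that compare or move slot contents;
operators (named bundles of condition and action prims) retrieved by noisy,
association-driven activation with condition gating; deterministic declarative
retrieval of lexical chunks; and reward-driven updating of context-operator
associative strengths.

Deliberately *not* modeled: bottom-up compilation of operators from prims,
base-level activation and decay, and any latency/timing quantities.  Operator
retrieval is purely associative (plus selection noise), which keeps the
learned association store the complete description of the model's state.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "NIL",
    "BUFFER_SIZES",
    "EngineError",
    "SlotError",
    "RetrievalFailure",
    "AmbiguousRetrieval",
    "Chunk",
    "BufferSet",
    "Prim",
    "Operator",
    "AssociationStore",
    "EngineConfig",
    "eval_conditions",
    "execute_actions",
    "retrieve_chunk",
    "activation",
    "select_operator",
    "apply_reward",
    "apply_outcome",
    "slot",
]

#: Marker for an empty slot ("nil").
NIL = None

BUFFER_SIZES = {"V": 3, "WM": 5, "RT": 4, "AC": 1}

CONDITION_KINDS = frozenset({"cmp_eq", "cmp_ne", "is_nil", "not_nil"})
ACTION_KINDS = frozenset({"copy", "set_const", "ext_action"})

#: Retrieval-buffer slot layout: RT1..RT4 hold these chunk fields.
RT_FIELDS = ("chunk_type", "form", "pos", "meaning")


class EngineError(Exception):
    """Base class for engine-level failures."""


class SlotError(EngineError):
    """Malformed slot address, or an action that misuses a slot."""


class RetrievalFailure(EngineError):
    """No declarative chunk matches a retrieval request."""


class AmbiguousRetrieval(EngineError):
    """More than one declarative chunk matches a retrieval request."""


def slot(address: str) -> tuple[str, int]:
    """Parse a slot address like ``"WM3"`` into ``("WM", 3)``.

    Raises :class:`SlotError` for unknown buffers or out-of-range indices.
    """
    for buf, size in BUFFER_SIZES.items():
        if address.startswith(buf):
            tail = address[len(buf):]
            if tail.isdigit() and 1 <= int(tail) <= size:
                return (buf, int(tail))
    raise SlotError(f"malformed slot address: {address!r}")


def _check_addr(addr: tuple[str, int]) -> tuple[str, int]:
    try:
        buf, idx = addr
    except (TypeError, ValueError):
        raise SlotError(f"malformed slot address: {addr!r}") from None
    if buf not in BUFFER_SIZES or not 1 <= idx <= BUFFER_SIZES[buf]:
        raise SlotError(f"malformed slot address: {addr!r}")
    return addr


@dataclass(frozen=True)
class Chunk:
    """A declarative-memory record for one lexical entry.

    ``meaning`` carries the word's concept token; by the one-concept-per-word
    convention of this model it is ``"c-" + form`` for names and verbs.
    """

    name: str
    chunk_type: str
    form: str
    pos: str
    meaning: str

    @classmethod
    def lexical_entry(cls, form: str, pos: str) -> "Chunk":
        if not form:
            raise ValueError("chunk form must be non-empty")
        return cls(name=form, chunk_type="lexical-entry", form=form, pos=pos,
                   meaning="c-" + form)

    def rt_values(self) -> tuple[str, str, str, str]:
        """The four values this chunk loads into the retrieval buffer."""
        return (self.chunk_type, self.form, self.pos, self.meaning)


class BufferSet:
    """Input (V), working-memory (WM), retrieval (RT) and action (AC) buffers.

    Slots are positional and unlabeled; an empty slot holds :data:`NIL`.
    During sentence processing the model uses WM1 for the subject, WM2 for the
    verb, WM3 for the object, WM4 for the predicted referent form, and WM5 for
    the predicted referent.
    """

    __slots__ = ("V", "WM", "RT", "AC")

    def __init__(self) -> None:
        self.V: list = [NIL] * 3
        self.WM: list = [NIL] * 5
        self.RT: list = [NIL] * 4
        self.AC: list = [NIL] * 1

    def get(self, addr: tuple[str, int]):
        buf, idx = _check_addr(addr)
        return getattr(self, buf)[idx - 1]

    def set(self, addr: tuple[str, int], value) -> None:
        buf, idx = _check_addr(addr)
        getattr(self, buf)[idx - 1] = value

    def clear(self, buffer: str | None = None) -> None:
        names = (buffer,) if buffer else ("V", "WM", "RT", "AC")
        for name in names:
            if name not in BUFFER_SIZES:
                raise SlotError(f"unknown buffer: {name!r}")
            lst = getattr(self, name)
            for i in range(len(lst)):
                lst[i] = NIL

    def context(self) -> tuple:
        """Learning context: the non-empty values of WM1..WM3 (the sentence).

        Context is keyed by value, not by slot position — this is what lets
        proper names accumulate credit across the whole corpus.
        """
        return tuple(v for v in self.WM[:3] if v is not NIL)

    def copy(self) -> "BufferSet":
        other = BufferSet.__new__(BufferSet)
        other.V = list(self.V)
        other.WM = list(self.WM)
        other.RT = list(self.RT)
        other.AC = list(self.AC)
        return other

    def as_dict(self) -> dict:
        return {b: list(getattr(self, b)) for b in BUFFER_SIZES}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BufferSet({self.as_dict()})"


@dataclass(frozen=True)
class Prim:
    """One primitive element: a slot comparison (condition) or transfer (action).

    Condition kinds: ``cmp_eq``/``cmp_ne`` compare two slots (both must be
    non-empty; a comparison against an empty slot never holds), ``is_nil`` /
    ``not_nil`` test a single slot.  Action kinds: ``copy`` moves one slot's
    value to another, ``set_const`` writes a constant symbol into a slot
    (writes into RT slots form a pending retrieval request), ``ext_action``
    emits an external signal such as ``read-next``.
    """

    kind: str
    src: tuple[str, int] | str
    dst: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if self.kind in CONDITION_KINDS:
            _check_addr(self.src)  # type: ignore[arg-type]
            if self.kind in ("cmp_eq", "cmp_ne"):
                if self.dst is None:
                    raise SlotError(f"{self.kind} needs two slot addresses")
                _check_addr(self.dst)
            elif self.dst is not None:
                raise SlotError(f"{self.kind} takes a single slot address")
        elif self.kind in ACTION_KINDS:
            if self.kind == "copy":
                _check_addr(self.src)  # type: ignore[arg-type]
            elif not isinstance(self.src, str) or not self.src:
                raise SlotError(f"{self.kind} needs a constant source symbol")
            if self.kind == "ext_action":
                if self.dst is not None:
                    _check_addr(self.dst)
            else:
                if self.dst is None:
                    raise SlotError(f"{self.kind} needs a destination slot")
                _check_addr(self.dst)
        else:
            raise SlotError(f"unknown prim kind: {self.kind!r}")


def _compile_condition(prim: Prim) -> Callable[[BufferSet], bool]:
    if prim.kind in ("cmp_eq", "cmp_ne"):
        b1, i1 = prim.src
        b2, i2 = prim.dst  # type: ignore[misc]
        i1 -= 1
        i2 -= 1
        if prim.kind == "cmp_eq":
            def test(bs, b1=b1, i1=i1, b2=b2, i2=i2):
                a = getattr(bs, b1)[i1]
                return a is not NIL and a == getattr(bs, b2)[i2]
        else:
            def test(bs, b1=b1, i1=i1, b2=b2, i2=i2):
                a = getattr(bs, b1)[i1]
                b = getattr(bs, b2)[i2]
                return a is not NIL and b is not NIL and a != b
        return test
    b1, i1 = prim.src  # type: ignore[misc]
    i1 -= 1
    if prim.kind == "is_nil":
        return lambda bs, b1=b1, i1=i1: getattr(bs, b1)[i1] is NIL
    return lambda bs, b1=b1, i1=i1: getattr(bs, b1)[i1] is not NIL


class Operator:
    """A named, retrievable production: condition prims gating action prims.

    An operator fires only if *all* conditions hold against the current
    buffers; firing applies all actions in order.
    """

    __slots__ = ("name", "conditions", "actions", "_tests", "index")

    def __init__(self, name: str, conditions: Sequence[Prim],
                 actions: Sequence[Prim]) -> None:
        self.name = name
        self.conditions = tuple(conditions)
        self.actions = tuple(actions)
        for p in self.conditions:
            if p.kind not in CONDITION_KINDS:
                raise SlotError(f"{name}: {p.kind} is not a condition prim")
        for p in self.actions:
            if p.kind not in ACTION_KINDS:
                raise SlotError(f"{name}: {p.kind} is not an action prim")
        self._tests = tuple(_compile_condition(p) for p in self.conditions)
        self.index = -1  # assigned when registered in an operator set

    def check(self, buffers: BufferSet) -> bool:
        for test in self._tests:
            if not test(buffers):
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Operator({self.name!r})"


def eval_conditions(op: Operator, buffers: BufferSet) -> bool:
    """True iff every condition prim of ``op`` holds; never mutates buffers."""
    return op.check(buffers)


def retrieve_chunk(request: Mapping[str, str], lexicon) -> Chunk:
    """Deterministically retrieve the unique chunk matching ``request``.

    ``request`` maps chunk fields (chunk_type, form, pos, meaning) to required
    values; at least one field must be constrained.  Base-level activation is
    disabled in this model, so retrieval is exact-match and deterministic:
    zero matches raise :class:`RetrievalFailure`, more than one raise
    :class:`AmbiguousRetrieval` (the lexicon must be unambiguous).

    ``lexicon`` may be any iterable of chunks, or an object exposing a
    ``retrieve(request)`` method (used as a fast path).
    """
    if not request:
        raise RetrievalFailure("empty retrieval request")
    finder = getattr(lexicon, "retrieve", None)
    if finder is not None:
        return finder(request)
    matches = [c for c in lexicon
               if all(getattr(c, k) == v for k, v in request.items())]
    if not matches:
        raise RetrievalFailure(f"no chunk matches {dict(request)!r}")
    if len(matches) > 1:
        raise AmbiguousRetrieval(f"{len(matches)} chunks match {dict(request)!r}")
    return matches[0]


def execute_actions(op: Operator, buffers: BufferSet, lexicon=None):
    """Apply all action prims of ``op`` in order; return ``(buffers, signals)``.

    The caller is responsible for having verified the conditions.  Writes into
    RT slots form a retrieval request; if a ``lexicon`` is supplied the
    request is resolved immediately and the retrieved chunk's four fields are
    loaded into RT1..RT4, otherwise a ``"retrieval-request"`` signal is
    emitted.  ``ext_action`` prims write their signal into AC1 and also return
    it as a signal (the trial loop clears AC after handling, so the write does
    not persist).  Copying from an empty slot raises :class:`SlotError` — it
    indicates an operator-design bug, not a run-time condition.
    """
    signals: list[str] = []
    rt_written = False
    for prim in op.actions:
        if prim.kind == "copy":
            value = buffers.get(prim.src)  # type: ignore[arg-type]
            if value is NIL:
                raise SlotError(
                    f"{op.name}: copy from empty slot {prim.src!r}")
            buffers.set(prim.dst, value)  # type: ignore[arg-type]
            if prim.dst[0] == "RT":  # type: ignore[index]
                rt_written = True
        elif prim.kind == "set_const":
            buffers.set(prim.dst, prim.src)  # type: ignore[arg-type]
            if prim.dst[0] == "RT":  # type: ignore[index]
                rt_written = True
        else:  # ext_action
            buffers.AC[0] = prim.src
            signals.append(prim.src)  # type: ignore[arg-type]
    if rt_written:
        if lexicon is None:
            signals.append("retrieval-request")
        else:
            request = {f: v for f, v in zip(RT_FIELDS, buffers.RT)
                       if v is not NIL}
            chunk = retrieve_chunk(request, lexicon)
            buffers.RT[:] = chunk.rt_values()
    return buffers, tuple(signals)


class AssociationStore:
    """Learned context-operator associative strengths.

    Maps ``(context symbol, operator name)`` to a strength in ``[0, R]``;
    missing pairs read as 0.  This mapping is the *entire* learned state of
    the model.
    """

    __slots__ = ("_rows",)

    def __init__(self, strengths: Mapping[tuple[str, str], float] | None = None):
        self._rows: dict[str, dict[str, float]] = {}
        if strengths:
            for (sym, op_name), value in strengths.items():
                self.set(sym, op_name, value)

    def get(self, context_symbol: str, operator_name: str) -> float:
        row = self._rows.get(context_symbol)
        return 0.0 if row is None else row.get(operator_name, 0.0)

    def set(self, context_symbol: str, operator_name: str, value: float) -> None:
        if value < 0.0:
            raise ValueError("associative strengths are non-negative")
        self._rows.setdefault(context_symbol, {})[operator_name] = value

    def row(self, context_symbol: str) -> Mapping[str, float]:
        return self._rows.get(context_symbol, {})

    def items(self) -> Iterable[tuple[tuple[str, str], float]]:
        for sym, row in self._rows.items():
            for op_name, value in row.items():
                yield (sym, op_name), value

    def total_mass(self) -> float:
        return sum(v for row in self._rows.values() for v in row.values())

    def copy(self) -> "AssociationStore":
        other = AssociationStore()
        other._rows = {sym: dict(row) for sym, row in self._rows.items()}
        return other

    def __eq__(self, other) -> bool:
        if not isinstance(other, AssociationStore):
            return NotImplemented
        return self._rows == other._rows

    def __len__(self) -> int:
        return sum(len(row) for row in self._rows.values())

    def to_json(self) -> str:
        return json.dumps(self._rows, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AssociationStore":
        store = cls()
        store._rows = {sym: {op: float(v) for op, v in row.items()}
                       for sym, row in json.loads(text).items()}
        return store


@dataclass(frozen=True)
class EngineConfig:
    """Learning and selection parameters.

    alpha
        Learning rate of the association update, in (0, 1].
    reward
        Reward magnitude R issued when both predictions match the input; the
        upper bound of every associative strength.
    noise_sd
        Scale parameter of the zero-mean logistic selection noise added
        independently to each candidate operator's activation at every
        selection.  0 makes selection deterministic up to ties (ties are
        broken uniformly at random).
    learning_enabled
        When false the association store is frozen: no trial changes it.
    failure_target
        Outcome value propagated to the fired operators on *unrewarded*
        trials: strengths move toward this value with the same learning rate,
        making each strength track the operator's reward rate in that
        context.  ``None`` disables any update on unrewarded trials (the
        success-only variant); there is no negative reward in either case.
    rng_seed
        Seed for the model's single random stream (selection noise,
        tie-breaks).
    """

    alpha: float = 0.25
    reward: float = 1.0
    noise_sd: float = 0.1
    learning_enabled: bool = True
    failure_target: float | None = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.reward <= 0.0:
            raise ValueError("reward must be positive")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")
        if self.failure_target is not None and not (
                0.0 <= self.failure_target <= self.reward):
            raise ValueError("failure_target must lie in [0, reward]")


def activation(op: Operator, context: Iterable[str],
               store: AssociationStore) -> float:
    """Associative activation of ``op``: sum of its strengths over ``context``.

    ``context`` is the multiset of non-empty WM1..WM3 values (the sentence).
    There is no base-level term.
    """
    total = 0.0
    for sym in context:
        total += store.get(sym, op.name)
    return total


def _logistic(rng: random.Random, scale: float) -> float:
    u = rng.random()
    while u <= 0.0:  # random() is [0, 1); guard the log
        u = rng.random()
    return scale * math.log(u / (1.0 - u))


def select_operator(candidates: Sequence[Operator], buffers: BufferSet,
                    store: AssociationStore, cfg: EngineConfig,
                    rng: random.Random) -> Operator | None:
    """Noisy activation-based retrieval with condition gating.

    Every candidate is scored ``activation + logistic noise`` (independent
    draws); candidates are visited in descending score with uniform random
    tie-breaking, and the first whose conditions all hold is returned (its
    actions are fired by the caller).  Returns ``None`` if no candidate's
    conditions hold — a valid outcome, not an error.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    context = buffers.context()
    rows = [row for row in (store._rows.get(sym) for sym in context)
            if row]
    sd = cfg.noise_sd
    scored = []
    for op in candidates:
        score = 0.0
        for row in rows:
            score += row.get(op.name, 0.0)
        if sd > 0.0:
            score += _logistic(rng, sd)
        scored.append((-score, rng.random(), op))
    scored.sort(key=lambda t: (t[0], t[1]))
    for _, _, op in scored:
        if op.check(buffers):
            return op
    return None


def apply_outcome(fired: Sequence[Operator | str], context: Iterable[str],
                  store: AssociationStore, cfg: EngineConfig,
                  target: float) -> AssociationStore:
    """Move strength(v, o) toward ``target`` for every context symbol ``v``
    and fired operator ``o``: ``s <- s + alpha * (target - s)``.

    Each (symbol, operator) pair is updated once per call; pairs involving
    operators that did not fire are untouched.
    """
    names = {op if isinstance(op, str) else op.name for op in fired}
    alpha = cfg.alpha
    for sym in set(context):
        row = store._rows.setdefault(sym, {})
        for name in names:
            s = row.get(name, 0.0)
            row[name] = s + alpha * (target - s)
    return store


def apply_reward(fired: Sequence[Operator | str], context: Iterable[str],
                 store: AssociationStore, cfg: EngineConfig) -> AssociationStore:
    """Reward update: strengthen associations between the current context and
    all operators that led to the reward (delta rule toward R).

    Called only on rewarded trials and only when learning is enabled; all
    other (context, operator) pairs remain unchanged.
    """
    return apply_outcome(fired, context, store, cfg, cfg.reward)
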