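"""Synthetic input-corpus generator.

Each training item is a transitive sentence ``Name1 VERB Name2`` followed by a
one-referent discourse continuation: the subject or the object of the sentence
is rementioned (with a verb-dependent probability reflecting the verb's
implicit-causality bias), realized either as a proper name or as the pronoun
"she" (with a grammatical-role-dependent probability: pronouns are favored for
rementioned subjects, names for rementioned objects).

The default configuration is the study's training regime: 10,000 items sampled
from 10 verbs (5 subject-biased, 3 object-biased, 2 neutral) and 40 synthetic
female names, with P(pronoun | subject continuation) = 0.75 and
P(name | object continuation) = 0.75.  "repulsed" carries the norming-derived
subject-continuation probability 0.76; the other nine verbs use configurable
category-respecting defaults.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "SUBJECT",
    "OBJECT",
    "NAME",
    "PRONOUN",
    "PRONOUN_TOKEN",
    "CATEGORIES",
    "VerbSpec",
    "CorpusConfig",
    "InputItem",
    "default_verb_table",
    "generate_names",
    "generate_novel_tokens",
    "sample_item",
    "generate_corpus",
    "generate_novel_items",
    "validate_corpus",
    "corpus_names",
    "write_jsonl",
    "read_jsonl",
    "write_csv",
    "read_csv",
]

SUBJECT = "subject"
OBJECT = "object"
NAME = "name"
PRONOUN = "pronoun"
PRONOUN_TOKEN = "she"

SUBJECT_BIASED = "subject_biased"
OBJECT_BIASED = "object_biased"
NEUTRAL = "neutral"
CATEGORIES = (SUBJECT_BIASED, OBJECT_BIASED, NEUTRAL)


@dataclass(frozen=True)
class VerbSpec:
    """One implicit-causality verb and its subject-continuation probability."""

    lemma: str
    category: str
    p_subject: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown verb category: {self.category!r}")
        if not 0.0 <= self.p_subject <= 1.0:
            raise ValueError("p_subject must lie in [0, 1]")
        if self.category == SUBJECT_BIASED and not self.p_subject > 0.5:
            raise ValueError(f"{self.lemma}: subject-biased needs p_subject > 0.5")
        if self.category == OBJECT_BIASED and not self.p_subject < 0.5:
            raise ValueError(f"{self.lemma}: object-biased needs p_subject < 0.5")


# Subject-continuation probabilities.  "repulsed" is the published norming
# value (76% subject continuations); the other nine are defaults chosen to
# respect each verb's category, approximating sentence-completion norms, and
# are overridable through CorpusConfig.verb_table.
_DEFAULT_TABLE: tuple[tuple[str, str, float], ...] = (
    ("repulsed", SUBJECT_BIASED, 0.76),
    ("angered", SUBJECT_BIASED, 0.80),
    ("fascinated", SUBJECT_BIASED, 0.75),
    ("disappointed", SUBJECT_BIASED, 0.78),
    ("apologized", SUBJECT_BIASED, 0.70),
    ("comforted", OBJECT_BIASED, 0.25),
    ("feared", OBJECT_BIASED, 0.30),
    ("congratulated", OBJECT_BIASED, 0.20),
    ("interrupted", NEUTRAL, 0.50),
    ("filmed", NEUTRAL, 0.52),
)


def default_verb_table() -> list[VerbSpec]:
    """The 10-verb training inventory (5 subject-biased / 3 object-biased / 2 neutral)."""
    return [VerbSpec(lemma, cat, p) for lemma, cat, p in _DEFAULT_TABLE]


@dataclass
class CorpusConfig:
    """Parameters of the synthetic training corpus."""

    n_items: int = 10_000
    verb_table: list[VerbSpec] = field(default_factory=default_verb_table)
    n_names: int = 40
    p_pronoun_given_subject: float = 0.75
    p_name_given_object: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        if self.n_names < 2:
            raise ValueError("need at least two names")
        for p in (self.p_pronoun_given_subject, self.p_name_given_object):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lemmas = [v.lemma for v in self.verb_table]
        if len(set(lemmas)) != len(lemmas):
            raise ValueError("duplicate verb lemmas in verb_table")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["verb_table"] = [dataclasses.asdict(v) for v in self.verb_table]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CorpusConfig":
        d = dict(d)
        if "verb_table" in d:
            d["verb_table"] = [VerbSpec(**v) for v in d["verb_table"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorpusConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class InputItem:
    """One transitive sentence plus (for training items) its continuation.

    ``continuation_token`` is the surface token presented in the continuation
    ("she" for pronouns, otherwise the rementioned name);
    ``continuation_referent`` is always the rementioned name itself.
    Novel-item evaluation sentences carry no continuation and a ``novelty``
    label instead.
    """

    item_id: int
    subject_name: str
    verb: str
    object_name: str
    continuation_role: str | None = None
    continuation_form: str | None = None
    continuation_token: str | None = None
    continuation_referent: str | None = None
    novelty: str | None = None

    def __post_init__(self) -> None:
        if self.subject_name == self.object_name:
            raise ValueError("subject and object names must differ")
        if self.continuation_role is not None:
            if self.continuation_role not in (SUBJECT, OBJECT):
                raise ValueError(f"bad continuation role: {self.continuation_role!r}")
            expected = (self.subject_name if self.continuation_role == SUBJECT
                        else self.object_name)
            if self.continuation_referent != expected:
                raise ValueError("continuation_referent must match its role")
            if self.continuation_form == PRONOUN:
                if self.continuation_token != PRONOUN_TOKEN:
                    raise ValueError("pronoun continuations use the token 'she'")
            elif self.continuation_form == NAME:
                if self.continuation_token != self.continuation_referent:
                    raise ValueError("name continuations repeat the referent name")
            else:
                raise ValueError(f"bad continuation form: {self.continuation_form!r}")

    @property
    def has_continuation(self) -> bool:
        return self.continuation_role is not None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InputItem":
        clean = {k: (None if (isinstance(v, float) and pd.isna(v)) else v)
                 for k, v in d.items()}
        return cls(**clean)


_ONSETS = "bdfghjklmnprstvz"
_VOWELS = "aeiou"


def _syllable(rng: random.Random) -> str:
    return rng.choice(_ONSETS) + rng.choice(_VOWELS)


def generate_names(n: int, rng: random.Random,
                   exclude: Iterable[str] = ()) -> list[str]:
    """Generate ``n`` distinct synthetic female name tokens.

    Names are pronounceable CV-syllable strings ending in "-a" (e.g.
    "melira"); only distinctness (and disjointness from ``exclude``) matters
    to the model.  Deterministic under the supplied ``rng``.
    """
    if n < 2:
        raise ValueError("need at least two names")
    taken = set(exclude) | {PRONOUN_TOKEN}
    names: list[str] = []
    while len(names) < n:
        body = "".join(_syllable(rng) for _ in range(rng.choice((2, 3))))
        name = body + "a" if not body.endswith("a") else body
        if name not in taken:
            taken.add(name)
            names.append(name)
    return names


def generate_novel_tokens(n: int, rng: random.Random, kind: str,
                          exclude: Iterable[str] = ()) -> list[str]:
    """Synthetic tokens guaranteed absent from ``exclude``: verb-like
    ("-ed") or name-like ("-a") strings."""
    taken = set(exclude) | {PRONOUN_TOKEN}
    out: list[str] = []
    while len(out) < n:
        body = "".join(_syllable(rng) for _ in range(rng.choice((2, 3))))
        token = body + ("ed" if kind == "verb" else "a")
        if token not in taken:
            taken.add(token)
            out.append(token)
    return out


def corpus_names(cfg: CorpusConfig) -> list[str]:
    """The deterministic name inventory implied by a corpus configuration."""
    rng = random.Random(cfg.seed)
    return generate_names(cfg.n_names, rng,
                          exclude=[v.lemma for v in cfg.verb_table])


def sample_item(cfg: CorpusConfig, rng: random.Random,
                names: Sequence[str] | None = None,
                item_id: int = 0) -> InputItem:
    """Sample one training item.

    The verb is uniform over the verb table; subject and object names are
    drawn uniformly without replacement (the two arguments must be distinct
    referents); the continuation role is Bernoulli in the verb's p_subject;
    the form is Bernoulli in the role-conditional pronoun probability.
    """
    if names is None:
        names = corpus_names(cfg)
    verb = rng.choice(cfg.verb_table)
    subject_name, object_name = rng.sample(list(names), 2)
    role = SUBJECT if rng.random() < verb.p_subject else OBJECT
    if role == SUBJECT:
        form = PRONOUN if rng.random() < cfg.p_pronoun_given_subject else NAME
        referent = subject_name
    else:
        form = NAME if rng.random() < cfg.p_name_given_object else PRONOUN
        referent = object_name
    token = PRONOUN_TOKEN if form == PRONOUN else referent
    return InputItem(item_id=item_id, subject_name=subject_name,
                     verb=verb.lemma, object_name=object_name,
                     continuation_role=role, continuation_form=form,
                     continuation_token=token, continuation_referent=referent)


def generate_corpus(cfg: CorpusConfig) -> list[InputItem]:
    """Generate the full training corpus: a pure function of the config.

    Items are sampled independently; uniqueness of the full item tuple is not
    enforced (collisions are possible but rare at the default inventory
    sizes).
    """
    rng = random.Random(cfg.seed)
    names = generate_names(cfg.n_names, rng,
                           exclude=[v.lemma for v in cfg.verb_table])
    return [sample_item(cfg, rng, names, item_id=i)
            for i in range(cfg.n_items)]


FULLY_NOVEL = "fully_novel"
NOVEL_VERB = "novel_verb"
NOVEL_NAME = "novel_name"
NOVELTY_CONDITIONS = (FULLY_NOVEL, NOVEL_VERB, NOVEL_NAME)


def generate_novel_items(cfg: CorpusConfig, trained_verbs: Sequence[VerbSpec],
                         trained_names: Sequence[str],
                         rng: random.Random) -> list[InputItem]:
    """The 25-sentence generalization set, prediction-only (no continuations).

    Five fully novel items (novel verb, novel subject and object names), five
    novel-verb items (novel verb, familiar names), and fifteen novel-name
    items (familiar verb — five per implicit-causality category — with novel
    names).
    """
    trained_lemmas = [v.lemma for v in trained_verbs]
    exclude = set(trained_lemmas) | set(trained_names)
    novel_verbs = generate_novel_tokens(10, rng, "verb", exclude)
    exclude |= set(novel_verbs)
    novel_names = generate_novel_tokens(10, rng, "name", exclude)

    items: list[InputItem] = []
    next_id = 0

    def add(verb: str, pool: Sequence[str], novelty: str) -> None:
        nonlocal next_id
        subj, obj = rng.sample(list(pool), 2)
        items.append(InputItem(item_id=next_id, subject_name=subj, verb=verb,
                               object_name=obj, novelty=novelty))
        next_id += 1

    for verb in novel_verbs[:5]:
        add(verb, novel_names, FULLY_NOVEL)
    for verb in novel_verbs[5:]:
        add(verb, trained_names, NOVEL_VERB)
    for category in CATEGORIES:
        lemmas = [v.lemma for v in trained_verbs if v.category == category]
        for i in range(5):
            add(lemmas[i % len(lemmas)], novel_names, NOVEL_NAME)
    return items


def validate_corpus(items: Sequence[InputItem]) -> pd.DataFrame:
    """Empirical rate table of a corpus, mirroring its configured probabilities.

    Returns a tidy frame with one row per cell: per-verb subject-continuation
    proportion (measure ``p_subject_continuation``) and per-(category x role)
    pronoun proportion (measure ``p_pronoun``), each with its trial count.
    """
    if not items:
        raise ValueError("empty corpus")
    rows = []
    df = pd.DataFrame([i.to_dict() for i in items if i.has_continuation])
    for verb, sub in df.groupby("verb", sort=True):
        rows.append({"measure": "p_subject_continuation", "verb": verb,
                     "category": None, "role": None,
                     "proportion": (sub.continuation_role == SUBJECT).mean(),
                     "n": len(sub)})
    # category is a property of the verb, recovered from the default table if
    # possible; callers with custom tables can merge on verb instead.
    cat_of = {lemma: cat for lemma, cat, _ in _DEFAULT_TABLE}
    df["category"] = df.verb.map(cat_of)
    for (cat, role), sub in df.dropna(subset=["category"]).groupby(
            ["category", "continuation_role"], sort=True):
        rows.append({"measure": "p_pronoun", "verb": None, "category": cat,
                     "role": role,
                     "proportion": (sub.continuation_form == PRONOUN).mean(),
                     "n": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File round-tripping

def write_jsonl(items: Sequence[InputItem], path: str | Path) -> None:
    with open(path, "w") as fh:
        for item in items:
            fh.write(json.dumps(item.to_dict()) + "\n")


def read_jsonl(path: str | Path) -> list[InputItem]:
    items = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                items.append(InputItem.from_dict(json.loads(line)))
    return items


def write_csv(items: Sequence[InputItem], path: str | Path) -> None:
    pd.DataFrame([i.to_dict() for i in items]).to_csv(path, index=False)


def read_csv(path: str | Path) -> list[InputItem]:
    df = pd.read_csv(path)
    df = df.astype(object).where(pd.notna(df), None)
    return [InputItem.from_dict(rec) for rec in df.to_dict("records")]
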