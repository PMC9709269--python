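"""Multi-run learning experiment and analysis.

A *run* trains one fresh model (all-zero association store) on the full
corpus in a run-specific random order, logging every trial, and then
evaluates the 25 novel generalization sentences with learning frozen.  A
*cohort* of such runs simulates a group of language learners; curves are
aggregated with simulated-participant semantics (proportion within each run,
then averaged across runs).
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import (CATEGORIES, NAME, NOVELTY_CONDITIONS, OBJECT, PRONOUN,
                     SUBJECT, CorpusConfig, InputItem, VerbSpec,
                     default_verb_table, generate_corpus, generate_novel_items)
from .engine import AssociationStore, EngineConfig
from .model import Lexicon, ReferenceModel, TrialRecord, build_lexicon

__all__ = [
    "MEASURES",
    "NovelPrediction",
    "RunResult",
    "CurvePoint",
    "run_simulation",
    "run_cohort",
    "evaluate_novel",
    "bin_proportions",
    "curves_frame",
    "trials_frame",
    "novel_frame",
    "novel_summary",
    "final_window_form_rates",
    "final_window_role_rates",
    "summarize",
    "report",
]

P_SUBJECT_PREDICTION = "p_subject_prediction"
P_PRONOUN_GIVEN_SUBJECT = "p_pronoun_given_predicted_subject"
P_PRONOUN_GIVEN_OBJECT = "p_pronoun_given_predicted_object"
MEASURES = (P_SUBJECT_PREDICTION, P_PRONOUN_GIVEN_SUBJECT,
            P_PRONOUN_GIVEN_OBJECT)

_SEED_BOUND = 2 ** 31


@dataclass(frozen=True, slots=True)
class NovelPrediction:
    """One frozen-learning prediction for a novel evaluation sentence."""

    novelty: str
    verb: str
    verb_category: str | None
    predicted_role: str
    predicted_form: str
    rep: int


@dataclass
class RunResult:
    """One simulated learner: its trial log, final state and novel-item eval."""

    run_id: int
    seed: int
    trials: list[TrialRecord]
    final_store: AssociationStore
    novel_eval: list[NovelPrediction]


@dataclass(frozen=True)
class CurvePoint:
    """One aggregated learning-curve cell (a bin x group proportion)."""

    bin_index: int
    group: str
    measure: str
    proportion: float
    n_trials: int


def _verb_categories(verb_table: Sequence[VerbSpec]) -> dict[str, str]:
    return {v.lemma: v.category for v in verb_table}


def _lexicon_for(corpus: Sequence[InputItem]) -> Lexicon:
    verbs = sorted({it.verb for it in corpus})
    names = sorted({it.subject_name for it in corpus}
                   | {it.object_name for it in corpus})
    return build_lexicon(verbs, names)


def evaluate_novel(model: ReferenceModel, novel_items: Sequence[InputItem],
                   n_reps: int = 1) -> list[NovelPrediction]:
    """Prediction-only evaluation of novel sentences with learning frozen.

    The model's lexicon is extended with any unseen tokens so comprehension
    retrieval succeeds; the new tokens carry zero associations, which is what
    makes the items genuinely novel to the learned state.  Requires
    ``learning_enabled=False`` so every item is equally novel and the
    association store is untouched.
    """
    if model.cfg.learning_enabled:
        raise ValueError("novel-item evaluation requires frozen learning")
    new_verbs = sorted({it.verb for it in novel_items
                        if it.verb not in model.lexicon})
    new_names = sorted({n for it in novel_items
                        for n in (it.subject_name, it.object_name)
                        if n not in model.lexicon})
    if new_verbs or new_names:
        model.extend_lexicon(verbs=new_verbs, names=new_names)
    out: list[NovelPrediction] = []
    for rep in range(n_reps):
        for item in novel_items:
            role, form = model.predict_item(item)
            out.append(NovelPrediction(
                novelty=item.novelty or "familiar",
                verb=item.verb,
                verb_category=model.verb_categories.get(item.verb),
                predicted_role=role,
                predicted_form=form,
                rep=rep,
            ))
    return out


def run_simulation(corpus: Sequence[InputItem], model_cfg: EngineConfig,
                   run_seed: int, *,
                   novel_items: Sequence[InputItem] = (),
                   lexicon: Lexicon | None = None,
                   verb_categories: dict[str, str] | None = None,
                   n_reps_novel: int = 1,
                   run_id: int = 0) -> RunResult:
    """Train one fresh model on a run-specific permutation of the corpus.

    The learner starts with an all-zero association store; every trial is
    logged.  If ``novel_items`` are given, the trained model is evaluated on
    them afterwards with learning frozen.
    """
    rng = random.Random(run_seed)
    if lexicon is None:
        lexicon = _lexicon_for(corpus)
    if verb_categories is None:
        verb_categories = _verb_categories(default_verb_table())
    order = list(range(len(corpus)))
    rng.shuffle(order)
    cfg = replace(model_cfg, rng_seed=rng.randrange(_SEED_BOUND),
                  learning_enabled=True)
    model = ReferenceModel(lexicon, cfg, verb_categories=verb_categories)
    trials = [model.run_trial(corpus[idx], trial_index=t)
              for t, idx in enumerate(order)]
    novel_eval: list[NovelPrediction] = []
    if novel_items:
        frozen_cfg = replace(cfg, learning_enabled=False,
                             rng_seed=rng.randrange(_SEED_BOUND))
        frozen = ReferenceModel(lexicon, frozen_cfg, model.operators,
                                model.store, verb_categories)
        novel_eval = evaluate_novel(frozen, novel_items, n_reps_novel)
    return RunResult(run_id=run_id, seed=run_seed, trials=trials,
                     final_store=model.store, novel_eval=novel_eval)


def run_cohort(n_runs: int, corpus_cfg: CorpusConfig, model_cfg: EngineConfig,
               master_seed: int, *,
               fresh_corpus_per_run: bool = False,
               n_reps_novel: int = 1,
               progress: bool = False) -> list[RunResult]:
    """Run ``n_runs`` independent learners and return their results.

    By default one corpus is generated from ``corpus_cfg`` and shared by all
    runs (each run sees it in a different random order); with
    ``fresh_corpus_per_run`` every learner gets its own resampled corpus.
    Run seeds are derived from ``master_seed`` and are pairwise distinct.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be positive")
    master = random.Random(master_seed)
    seeds: list[int] = []
    seen: set[int] = set()
    while len(seeds) < n_runs:
        s = master.randrange(_SEED_BOUND)
        if s not in seen:
            seen.add(s)
            seeds.append(s)

    categories = _verb_categories(corpus_cfg.verb_table)
    corpus = generate_corpus(corpus_cfg)
    lexicon = _lexicon_for(corpus)
    novel_rng = random.Random(master.randrange(_SEED_BOUND))
    trained_names = sorted({it.subject_name for it in corpus}
                           | {it.object_name for it in corpus})
    novel_items = generate_novel_items(corpus_cfg, corpus_cfg.verb_table,
                                       trained_names, novel_rng)

    iterator: Iterable[int] = range(n_runs)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="runs", unit="run")

    results = []
    for run_id in iterator:
        if fresh_corpus_per_run and run_id > 0:
            cfg_k = replace(corpus_cfg, seed=master.randrange(_SEED_BOUND))
            corpus = generate_corpus(cfg_k)
            lexicon = _lexicon_for(corpus)
            trained_names = sorted({it.subject_name for it in corpus}
                                   | {it.object_name for it in corpus})
            novel_items = generate_novel_items(
                cfg_k, cfg_k.verb_table, trained_names, novel_rng)
        results.append(run_simulation(
            corpus, model_cfg, seeds[run_id], novel_items=novel_items,
            lexicon=lexicon, verb_categories=categories,
            n_reps_novel=n_reps_novel, run_id=run_id))
    return results


# ---------------------------------------------------------------------------
# Aggregation

def trials_frame(cohort: Sequence[RunResult] | pd.DataFrame) -> pd.DataFrame:
    """All trial records of a cohort as one tidy frame (fired_ops omitted)."""
    if isinstance(cohort, pd.DataFrame):
        return cohort
    cols: dict[str, list] = {k: [] for k in (
        "run_id", "trial_index", "item_id", "verb", "verb_category",
        "predicted_role", "predicted_form", "actual_role", "actual_form",
        "rewarded")}
    for run in cohort:
        for t in run.trials:
            cols["run_id"].append(run.run_id)
            cols["trial_index"].append(t.trial_index)
            cols["item_id"].append(t.item_id)
            cols["verb"].append(t.verb)
            cols["verb_category"].append(t.verb_category)
            cols["predicted_role"].append(t.predicted_role)
            cols["predicted_form"].append(t.predicted_form)
            cols["actual_role"].append(t.actual_role)
            cols["actual_form"].append(t.actual_form)
            cols["rewarded"].append(t.rewarded)
    return pd.DataFrame(cols)


def _measure_subframe(df: pd.DataFrame, measure: str) -> pd.DataFrame:
    if measure == P_SUBJECT_PREDICTION:
        sub = df.copy()
        sub["value"] = sub.predicted_role == SUBJECT
    elif measure == P_PRONOUN_GIVEN_SUBJECT:
        sub = df[df.predicted_role == SUBJECT].copy()
        sub["value"] = sub.predicted_form == PRONOUN
    elif measure == P_PRONOUN_GIVEN_OBJECT:
        sub = df[df.predicted_role == OBJECT].copy()
        sub["value"] = sub.predicted_form == PRONOUN
    else:
        raise ValueError(f"unknown measure: {measure!r}")
    return sub


def bin_proportions(cohort: Sequence[RunResult] | pd.DataFrame,
                    group_by: str = "category",
                    measure: str = P_SUBJECT_PREDICTION,
                    bin_size: int = 100) -> list[CurvePoint]:
    """Grand-average learning curve: per bin and group, the proportion is
    computed within each run and then averaged over runs.

    ``group_by`` is ``"category"`` (implicit-causality verb type) or
    ``"verb"``.  Cells empty in every run are emitted with ``n_trials=0`` and
    NaN proportion.
    """
    df = trials_frame(cohort)
    group_col = {"category": "verb_category", "verb": "verb"}.get(group_by)
    if group_col is None:
        raise ValueError(f"unknown grouping: {group_by!r}")
    df = df.assign(bin_index=df.trial_index // bin_size + 1)
    sub = _measure_subframe(df, measure)
    per_run = sub.groupby(["run_id", "bin_index", group_col],
                          sort=True)["value"].mean()
    across = per_run.groupby(["bin_index", group_col]).mean()
    counts = sub.groupby(["bin_index", group_col]).size()
    grid = pd.MultiIndex.from_product(
        [sorted(df.bin_index.unique()), sorted(df[group_col].dropna().unique())],
        names=["bin_index", group_col])
    across = across.reindex(grid)
    counts = counts.reindex(grid, fill_value=0)
    return [CurvePoint(bin_index=int(b), group=str(g), measure=measure,
                       proportion=float(p), n_trials=int(n))
            for (b, g), p, n in zip(across.index, across.values, counts.values)]


def curves_frame(points: Sequence[CurvePoint]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in points])


def novel_frame(cohort: Sequence[RunResult]) -> pd.DataFrame:
    rows = []
    for run in cohort:
        for p in run.novel_eval:
            d = dataclasses.asdict(p)
            d["run_id"] = run.run_id
            rows.append(d)
    return pd.DataFrame(rows)


def _novel_condition(row) -> str:
    if row.novelty == "novel_name":
        return f"novel_name:{row.verb_category}"
    return row.novelty


def novel_summary(cohort: Sequence[RunResult]) -> pd.DataFrame:
    """Pooled novel-item rates per novelty condition.

    For each condition (fully novel; novel verb with familiar names; familiar
    verb of each category with novel names): the subject-prediction
    proportion, and the pronoun-prediction proportion split by predicted
    role, pooled over runs.
    """
    df = novel_frame(cohort)
    if df.empty:
        return pd.DataFrame(
            columns=["condition", "measure", "proportion", "n"])
    df = df.assign(condition=df.apply(_novel_condition, axis=1))
    rows = []
    for cond, sub in df.groupby("condition", sort=True):
        rows.append({"condition": cond, "measure": P_SUBJECT_PREDICTION,
                     "proportion": (sub.predicted_role == SUBJECT).mean(),
                     "n": len(sub)})
        for role, measure in ((SUBJECT, P_PRONOUN_GIVEN_SUBJECT),
                              (OBJECT, P_PRONOUN_GIVEN_OBJECT)):
            cell = sub[sub.predicted_role == role]
            rows.append({"condition": cond, "measure": measure,
                         "proportion": (cell.predicted_form == PRONOUN).mean()
                         if len(cell) else float("nan"),
                         "n": len(cell)})
    return pd.DataFrame(rows)


def _final_window(df: pd.DataFrame, window: int) -> pd.DataFrame:
    n_trials = int(df.trial_index.max()) + 1
    return df[df.trial_index >= n_trials - window]


def final_window_form_rates(cohort: Sequence[RunResult] | pd.DataFrame,
                            window: int = 2000,
                            predicted_role: str = OBJECT) -> pd.DataFrame:
    """Grand-average pronoun-prediction rate over each run's final ``window``
    presentations, among trials where the model predicted ``predicted_role``,
    by verb category.

    This is the asymptotic form-interaction quantity: on predicted-object
    trials it levels off near 40% pronouns for subject-biased verbs versus
    near 10% for object-biased verbs, despite identical form distributions in
    the input.
    """
    df = trials_frame(cohort)
    tail = _final_window(df, window)
    cell = tail[tail.predicted_role == predicted_role]
    per_run = cell.groupby(["run_id", "verb_category"])[
        "predicted_form"].apply(lambda s: (s == PRONOUN).mean())
    across = per_run.groupby("verb_category").mean()
    counts = cell.groupby("verb_category").size()
    out = pd.DataFrame({"proportion": across, "n": counts}).reindex(
        list(CATEGORIES))
    out.index.name = "verb_category"
    return out.reset_index()


def final_window_role_rates(cohort: Sequence[RunResult] | pd.DataFrame,
                            window: int = 2000) -> pd.DataFrame:
    """Grand-average subject-prediction rate over the final ``window``
    presentations, by verb category."""
    df = trials_frame(cohort)
    tail = _final_window(df, window)
    per_run = tail.groupby(["run_id", "verb_category"])[
        "predicted_role"].apply(lambda s: (s == SUBJECT).mean())
    across = per_run.groupby("verb_category").mean()
    counts = tail.groupby("verb_category").size()
    out = pd.DataFrame({"proportion": across, "n": counts}).reindex(
        list(CATEGORIES))
    out.index.name = "verb_category"
    return out.reset_index()


def summarize(cohort: Sequence[RunResult], bin_size: int = 100) -> dict:
    """Cohort summary: first/final-bin proportions per category, asymptotic
    form rates, novel-item rates, and named qualitative checks."""
    df = trials_frame(cohort)
    curves = {m: curves_frame(bin_proportions(df, "category", m, bin_size))
              for m in MEASURES}

    def bin_values(measure: str, bin_index: int) -> dict:
        c = curves[measure]
        sel = c[c.bin_index == bin_index]
        return {row.group: (None if pd.isna(row.proportion)
                            else round(float(row.proportion), 4))
                for row in sel.itertuples()}

    last_bin = int(curves[P_SUBJECT_PREDICTION].bin_index.max())
    form_obj = final_window_form_rates(df, predicted_role=OBJECT)
    form_subj = final_window_form_rates(df, predicted_role=SUBJECT)
    role_final = final_window_role_rates(df)
    novel = novel_summary(cohort)

    def tidy(frame: pd.DataFrame) -> dict:
        return {row.verb_category: {"proportion": round(float(row.proportion), 4),
                                    "n": int(row.n)}
                for row in frame.itertuples() if not pd.isna(row.proportion)}

    obj_rates = tidy(form_obj)
    summary = {
        "n_runs": len(cohort),
        "n_trials_per_run": len(cohort[0].trials),
        "bin_size": bin_size,
        "first_bin": {m: bin_values(m, 1) for m in MEASURES},
        "final_bin": {m: bin_values(m, last_bin) for m in MEASURES},
        "final_2000_pronoun_given_predicted_object": obj_rates,
        "final_2000_pronoun_given_predicted_subject": tidy(form_subj),
        "final_2000_subject_prediction": tidy(role_final),
        "novel_items": [
            {k: (None if pd.isna(v) else (round(float(v), 4)
                                          if isinstance(v, float) else v))
             for k, v in row.items()}
            for row in novel.to_dict("records")],
    }
    checks = {}
    fb = summary["first_bin"][P_SUBJECT_PREDICTION]
    checks["first_bin_at_chance"] = all(
        v is not None and abs(v - 0.5) <= 0.05 for v in fb.values())
    if all(c in obj_rates for c in CATEGORIES):
        checks["form_interaction_ordering"] = (
            obj_rates["subject_biased"]["proportion"]
            > obj_rates["neutral"]["proportion"]
            > obj_rates["object_biased"]["proportion"])
    summary["checks"] = checks
    return summary


# ---------------------------------------------------------------------------
# Reporting

_CATEGORY_COLORS = {"subject_biased": "tab:green", "neutral": "tab:orange",
                    "object_biased": "tab:blue"}


def _plot_curves(points_by_group: pd.DataFrame, ax, title: str,
                 ylabel: str) -> None:
    for group, sub in points_by_group.groupby("group"):
        color = _CATEGORY_COLORS.get(group)
        ax.plot(sub.bin_index * 100, sub.proportion, label=group, color=color)
    ax.set_ylim(0, 1)
    ax.axhline(0.5, color="gray", lw=0.5, ls=":")
    ax.set_xlabel("input items presented")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(fontsize=7)


def report(cohort: Sequence[RunResult], out_dir: str | Path,
           bin_size: int = 100) -> dict[str, Path]:
    """Write curves.csv, novel_eval.csv, summary.json and figures to ``out_dir``.

    Returns a mapping of artifact names to paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    figs = out / "figs"
    figs.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    df = trials_frame(cohort)
    all_points = []
    for measure in MEASURES:
        all_points.extend(bin_proportions(df, "category", measure, bin_size))
    all_points.extend(bin_proportions(df, "verb", P_SUBJECT_PREDICTION,
                                      bin_size))
    curves = curves_frame(all_points)
    paths["curves"] = out / "curves.csv"
    curves.to_csv(paths["curves"], index=False)

    nov = novel_frame(cohort)
    paths["novel_eval"] = out / "novel_eval.csv"
    nov.to_csv(paths["novel_eval"], index=False)

    summary = summarize(cohort, bin_size)
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")

    # learning curves, by category and by verb
    cat = curves[curves.measure == P_SUBJECT_PREDICTION]
    by_cat = cat[cat.group.isin(CATEGORIES)]
    by_verb = cat[~cat.group.isin(CATEGORIES)]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), constrained_layout=True)
    _plot_curves(by_cat, axes[0], "next-referent prediction by verb type",
                 "P(predict subject)")
    _plot_curves(by_verb, axes[1], "next-referent prediction by verb",
                 "P(predict subject)")
    paths["fig_role"] = figs / "next_referent_curves.png"
    fig.savefig(paths["fig_role"], dpi=150)
    plt.close(fig)

    # form curves by predicted role
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), constrained_layout=True)
    for ax, measure, title in (
            (axes[0], P_PRONOUN_GIVEN_SUBJECT, "predicted subject referents"),
            (axes[1], P_PRONOUN_GIVEN_OBJECT, "predicted object referents")):
        sel = curves[(curves.measure == measure)
                     & curves.group.isin(CATEGORIES)]
        _plot_curves(sel, ax, title, "P(predict pronoun)")
    paths["fig_form"] = figs / "referent_form_curves.png"
    fig.savefig(paths["fig_form"], dpi=150)
    plt.close(fig)

    # novel-item bars
    ns = novel_summary(cohort)
    if not ns.empty:
        fig, axes = plt.subplots(1, 3, figsize=(11, 3.2),
                                 constrained_layout=True)
        for ax, measure in zip(axes, MEASURES):
            sel = ns[ns.measure == measure]
            ax.bar(range(len(sel)), sel.proportion.fillna(0.0),
                   color=[_CATEGORY_COLORS.get(c.split(":")[-1], "gray")
                          for c in sel.condition])
            ax.set_xticks(range(len(sel)))
            ax.set_xticklabels(sel.condition, rotation=45, ha="right",
                               fontsize=6)
            ax.set_ylim(0, 1)
            ax.axhline(0.5, color="gray", lw=0.5, ls=":")
            ax.set_title(measure, fontsize=8)
        paths["fig_novel"] = figs / "novel_items.png"
        fig.savefig(paths["fig_novel"], dpi=150)
        plt.close(fig)
    return paths
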