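"""Anatomy of a single trial.

A fresh learner reads "leah fascinated kathy", predicts who will be mentioned
next and in which form, then observes the actual continuation ("she", i.e.
the subject leah as a pronoun).  The printout shows the operator firing
sequence and how working memory evolves through the three stages.
"""

from refbias import EngineConfig, InputItem, ReferenceModel, build_lexicon

lexicon = build_lexicon(verbs=["fascinated"], names=["leah", "kathy"])
model = ReferenceModel(lexicon, EngineConfig(rng_seed=6),
                       verb_categories={"fascinated": "subject_biased"})

item = InputItem(item_id=0, subject_name="leah", verb="fascinated",
                 object_name="kathy", continuation_role="subject",
                 continuation_form="pronoun", continuation_token="she",
                 continuation_referent="leah")

model.start_trial()
model.comprehend(item.subject_name, item.verb, item.object_name)
print("after comprehension  WM =", model.buffers.WM)

role, form = model.predict()
print(f"after prediction     WM = {model.buffers.WM}")
print(f"  -> predicted next referent: {role}, realized as a {form}")

rewarded = model.observe(item)
print(f"after observation    WM = {model.buffers.WM}")
print(f"  -> continuation was '{item.continuation_token}' "
      f"(= {item.continuation_referent}); rewarded: {rewarded}")

print("\noperator firing sequence:")
for i, name in enumerate(model._fired, 1):
    print(f"  {i:2d}. {name}")

print("\nlearned associations (context symbol -> operator):")
for (symbol, op), strength in sorted(model.store.items()):
    if strength:
        print(f"  {symbol:12s} -> {op:18s} {strength:.3f}")
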