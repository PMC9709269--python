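"""Learning curves of a small cohort.

Trains five simulated learners on the default 10,000-item corpus and prints
how the next-referent bias (subject-prediction rate) and the referent-form
bias (pronoun rate given a predicted subject / object) develop by verb type.
A full report with figures is written to ./curves_report/.

Runtime: about half a minute.  For the paper-scale experiment use
``refbias cohort --n-runs 100`` or scripts/acceptance.py.
"""

from refbias import CorpusConfig, EngineConfig, run_cohort
from refbias.experiment import (MEASURES, bin_proportions, curves_frame,
                                report, trials_frame)

cohort = run_cohort(n_runs=5, corpus_cfg=CorpusConfig(seed=0),
                    model_cfg=EngineConfig(), master_seed=0, progress=True)
trials = trials_frame(cohort)

for measure in MEASURES:
    curve = curves_frame(bin_proportions(trials, "category", measure))
    print(f"\n{measure}  (bins of 100 presentations)")
    print(f"  {'bin':>5s}  {'subject_biased':>14s}  {'neutral':>8s}  "
          f"{'object_biased':>13s}")
    for b in (1, 5, 10, 20, 40, 100):
        row = curve[curve.bin_index == b].set_index("group").proportion
        print(f"  {b:5d}  {row['subject_biased']:14.3f}  "
              f"{row['neutral']:8.3f}  {row['object_biased']:13.3f}")

paths = report(cohort, "curves_report")
print("\nfull report written to:")
for name, path in paths.items():
    print(f"  {name}: {path}")
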