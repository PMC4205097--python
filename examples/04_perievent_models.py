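"""Peri-event tensors, the pointwise mixed-model scan and windowed models.

Run with ``python examples/04_perievent_models.py``.
"""

import numpy as np

from oscimp import SimConfig, perievent_stats as pes, pipeline, synthetic

# Three rats, short sessions; gamma60 power aligned to wait start.
cfg = SimConfig(n_rats=3, session_duration=420.0, seed=5)
sessions = synthetic.simulate_cohort(cfg)
tensors = pipeline.cohort_tensors(sessions, measures=("gamma60",))
ws = tensors[("wait_start", "gamma60")]
n_trials = sum(t.n_trials for t in ws)
print(f"wait-start gamma60 tensors: {n_trials} trials, "
      f"{ws[0].values.shape[2]} time points from -1 to +2 s")

# Grand-average trace: the generator injects a gamma bump at wait start.
curve = np.mean([t.values.mean(axis=(0, 1)) for t in ws], axis=0)
offsets = np.asarray(ws[0].offsets)
print(f"grand-average peak at {offsets[np.argmax(curve)]:+.2f} s "
      f"(z = {curve.max():.2f})")

# Pointwise scan: a mixed model at every grid point, epochs from runs of
# p < 0.01/75 lasting more than 0.2 s.
scan = pes.pointwise_scan(ws)
print(f"pointwise threshold = {scan.threshold:.5f}")
for factor, epochs in sorted(scan.epochs.items()):
    span = ", ".join(f"[{a:+.2f}, {b:+.2f}] s" for a, b in epochs) or "none"
    print(f"  {factor:>14}: {span}")

# Windowed model: full factorial with Bonferroni over the nine windows.
win = pes.DEFAULT_WINDOWS[0]  # wait-start gamma60, [-0.25, 0.25] s
table = pes.window_average(ws, win)
res = pes.windowed_model(table, win)
print(f"\nwindow '{win.name}' fitted with fallback '{res.fallback}':")
print(res.terms[["term", "statistic", "df", "p_corrected"]].to_string(index=False))
if "outcome" in res.posthoc:
    print("\npost-hoc outcome contrasts (Bonferroni):")
    print(res.posthoc["outcome"][["contrast", "estimate", "p_adjusted"]]
          .to_string(index=False))
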