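"""The full group-comparison protocol, scaled down for a quick demo.

Three groups (ND, VO, SS) each run pretest, training and posttest sessions;
per-trial SDLP/SWV feed the mixed repeated-measures ANOVA with
Greenhouse-Geisser correction, simple main effects and Shaffer-adjusted
pairwise comparisons.  This demo uses 5 agents per group and 12 training
trials (~30 s); the study-scale run is simply ``SimConfig()`` — 15 per
group, 5 + 40 + 5 one-minute trials — and takes a couple of minutes.
"""

from lanecue import SimConfig, run_experiment, summarize_report

config = SimConfig(n_per_group=5, n_pretest=2, n_training=12, n_posttest=2,
                   master_seed=1)
metrics, report = run_experiment(config)

print(f"{len(metrics)} trial-level rows "
      f"({config.n_per_group} agents/group x "
      f"{config.n_pretest + config.n_training + config.n_posttest} trials)\n")
tr = metrics[metrics.session == "training"]
first = tr[tr.trial == 1].groupby("group")["sdlp"].mean()
last = tr[tr.trial == config.n_training].groupby("group")["sdlp"].mean()
print("mean SDLP (m), first vs last training trial:")
for g in ("ND", "VO", "SS"):
    print(f"  {g}: {first[g]:.3f} -> {last[g]:.3f}")
print()
print(summarize_report(report))
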