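"""One closed-loop trial per sensory condition.

A synthetic driver steers a constant-speed (80 km/h) vehicle along a random
course for one minute under each condition: ND sees the near road, VO has
it occluded, SS has it occluded but hears the binaural cue (before any
training, so its decoding is still noisy).  SDLP summarises lane-keeping
accuracy, SWV steering stability; lower is better for both.
"""

from lanecue import (
    Condition,
    DriverAgent,
    generate_course,
    sample_participant,
    simulate_trial,
    trial_metrics,
)

params = sample_participant(group_seed=1, participant_index=0)
print(f"sampled driver: k_comp={params.k_comp:.3f} rad/m, "
      f"k_head={params.k_head:.2f} rad/rad, reaction={params.reaction_delay * 1e3:.0f} ms")

print(f"\n{'condition':>10} {'SDLP (m)':>9} {'SWV (deg/s)':>12} {'curves':>7}")
for cond in (Condition.ND, Condition.VO, Condition.SS):
    course = generate_course(seed=11)
    agent = DriverAgent(params, cond, trial_index=0)
    log = simulate_trial(course, agent, duration=60.0, seed=4)
    m = trial_metrics(log, course)
    print(f"{cond.value:>10} {m.sdlp:9.3f} {m.swv:12.1f} {m.n_curves:7d}")

print("\nOcclusion (VO) inflates SDLP because nothing corrects lateral drift;")
print("the untrained SS driver does little better.  SWV barely moves: it is")
print("set by the anticipatory response to previewed curvature, which all")
print("conditions retain.")
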