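"""Learning to use the auditory channel.

Simulates a small sensory-substitution cohort at several points of the
40-trial training session.  The audio-decoding noise SD decays
exponentially with training, so SDLP falls from its occluded level toward
the normal-driving baseline.
"""

import numpy as np

from lanecue import Condition, DriverAgent, generate_course, sample_participant, sdlp, simulate_trial

N_AGENTS = 5

print(f"{'trial':>6} {'sigma_audio (m)':>16} {'mean SDLP (m)':>14}")
for trial in (0, 4, 9, 19, 39):
    vals = []
    for i in range(N_AGENTS):
        params = sample_participant(group_seed=3, participant_index=i)
        course = generate_course(seed=500 + 13 * i + trial)
        agent = DriverAgent(params, Condition.SS, trial_index=trial)
        log = simulate_trial(course, agent, seed=100 + i)
        vals.append(sdlp(log))
    sigma = sample_participant(3, 0).sigma_audio(trial)
    print(f"{trial + 1:6d} {sigma:16.3f} {np.mean(vals):14.3f}")

print("\nEach row is a later training trial: as the agents learn to decode")
print("the binaural cue (falling sigma_audio), lane keeping recovers.")
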