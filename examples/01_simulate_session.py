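"""Simulate one flicker-SART session and inspect its structure.

Generates a scaled-down session (2 blocks of 45 trials on a reduced
montage), prints the trial/probe layout and the behavioural summary. In a
full-size session (the defaults) there are 8 blocks of 90 trials with six
thought probes each.
"""

import flickersart as fs
from flickersart.stats import behavior_summary
from flickersart.synthgen import SimConfig

config = SimConfig(
    n_blocks=2,
    trials_per_block=45,
    probes_per_block=5,
    channels=["Fz", "Cz", "Pz", "Oz", "P7", "P8", "O1", "O2"],
    seed=1,
)
session = fs.simulate_session(config)

events = session.events
print(f"trials: {len(events)}  "
      f"nogo: {(events.trial_type == 'nogo').sum()} "
      f"({(events.trial_type == 'nogo').mean():.1%})  "
      f"probes: {len(session.probes)}")
print(f"recording: {session.recording.shape[0]} channels x "
      f"{session.recording.shape[1]} samples at {session.fs:.0f} Hz")

summary = behavior_summary(
    session.events.merge(session.behavior, on="trial_index")
)["overall"]
print(f"Go accuracy {summary.go_accuracy:.2%}, "
      f"Nogo accuracy {summary.nogo_accuracy:.2%}, "
      f"mean RT {summary.rt_mean * 1000:.0f} ms, cvRT {summary.rt_cv:.2f}")
# Nogo accuracy sits well below Go accuracy: withholding to rare uppercase
# targets is the hard part of the task, and the latent state modulates it.

first = session.probes[0]
print(f"first probe after trial {first.after_trial}: "
      f"content option {first.content_option}, "
      f"stickiness rating {first.stickiness}")
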