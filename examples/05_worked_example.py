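"""The canonical single-participant demonstration.

A standard-length session whose positions are out of the 11-year-old
non-outlier interval [-2.4, 2.6] exactly on observations
[20,617, 31,008) is pushed through mask -> sustained runs -> profile.
Equivalent to `lanelapse worked-example` on the command line."""

from lanelapse.experiments import worked_example

r = worked_example()
print(f"non-outlier interval: {r['fences']}")
print(f"sustained errors start at observation {r['first_loss_index']}, "
      f"i.e. after {r['first_loss_minutes']:.2f} min")
print(f"attention recovered from observation {r['recovery_index']} "
      f"({r['recovery_minutes']:.2f} min) after "
      f"{r['inattention_minutes']:.2f} min of inattention")
print(f"maintained until the end of the task: {r['attentive_to_end']}")
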