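"""Build the block paradigm and inspect the three acquisition presets.

Prints the event table head and per-protocol timing. The paradigm has 18
active blocks (3 per body part x side) of 16 s, each preceded by a 3 s cued
preparation period and a 16 s rest block; every preset retains a 90 mm
head-foot slab.
"""

import somatoseg as ss

presets = ss.default_protocol_presets()
for p in presets:
    print(f"{p.name:>6}: voxel {p.voxel_size_mm} mm, TR {p.tr_s:.3f} s, "
          f"{p.n_volumes} volumes ({p.encoding}), coverage {p.coverage_mm:.0f} mm, "
          f"scan {p.scan_duration_s:.0f} s")

events = ss.make_paradigm(ss.ParadigmSpec(), seed=0)
print("\nFirst blocks of the session:")
print(events.head(9).to_string(index=False))
active = events[events.event_class == "active"]
print(f"\n{len(active)} active blocks, "
      f"{active.trial_type.value_counts().iloc[0]} per condition, "
      f"session ends at {float((events.onset + events.duration).max()):.0f} s")
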