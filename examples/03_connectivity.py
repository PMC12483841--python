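"""Circuit-theory connectivity surfaces.

Cover-based omnidirectional current treats every cell with >= 15% cover as
a source and solves a resistor network in a moving window around each one;
lek-based current injects at lek points instead.  The loss layer is the
gain-clamped difference between current and historic lek connectivity.
"""

import numpy as np

from sageplan import connectivity as conn
from sageplan.synth import generate_bundle

bundle = generate_bundle(seed=1)
cfg = conn.WindowConfig(radius=600.0, stride=4)

sources = bundle.current_cover.values >= cfg.source_threshold
sage = conn.omnidirectional_current(bundle.current_cover, cfg, sources)
v = sage.values.values
print(f"sagebrush connectivity: mean {v.mean():.3f}, max {v.max():.2f} "
      f"({(v > 0).mean():.0%} of cells carry current)")

lek_cfg = conn.WindowConfig(radius=600.0, source_mode="point_based")
now = conn.mask_lek_buffers(
    conn.lek_connectivity(bundle.current_cover, bundle.leks, lek_cfg),
    bundle.leks, radius=1000.0)
then = conn.mask_lek_buffers(
    conn.lek_connectivity(bundle.historic_cover, bundle.leks, lek_cfg),
    bundle.leks, radius=1000.0)
loss = conn.connectivity_change(now, then)
print(f"lek connectivity (2020-analogue): max {now.values.values.max():.3f}")
print(f"connectivity loss: min {loss.values.min():.4f} "
      f"({(loss.values < 0).mean():.0%} of cells lost connectivity)")
# High current marks corridors and pinch points; the loss layer is <= 0 by
# construction (gains from current redirection are clamped to zero).
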