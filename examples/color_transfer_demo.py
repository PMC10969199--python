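"""Impose a capsule-endoscopy color style on a wired-endoscopy frame.

Generates one synthetic wired-style frame and three capsule-style
reference frames, pools the references' l-alpha-beta channel statistics,
and transfers them onto the wired frame.  The printout shows the channel
means/SDs before and after: after transfer they match the pooled target
statistics, which is the defining property of moment-matching transfer.
"""

import numpy as np

from wcesim import (
    SynthConfig,
    channel_stats,
    generate_image,
    generate_references,
    rgb_to_lab,
    stats_from_references,
    transfer,
)

cfg = SynthConfig(image_size=128)
wired = generate_image("Angulus", "wired", cfg, seed=0)
refs = generate_references(["G"], n_per_style=3, config=cfg, seed=0)["G"]

target = stats_from_references(refs)
result = transfer(wired, target)

before = channel_stats(rgb_to_lab(wired))
after = channel_stats(rgb_to_lab(result))

np.set_printoptions(precision=3)
print("target (pooled capsule refs)  mean:", target.means, " sd:", target.sds)
print("wired frame before transfer   mean:", before.means, " sd:", before.sds)
print("wired frame after transfer    mean:", after.means, " sd:", after.sds)
print()
print("After transfer the frame's lab statistics sit on the capsule target")
print("(small residuals come only from the final clip back to 8-bit RGB).")
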