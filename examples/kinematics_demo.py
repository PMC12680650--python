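"""CASA kinematics on simulated sperm tracks, fresh versus frozen.

Simulates a fresh-like population (85% motile) and a post-thaw-like
population (more immotile cells, slower swimmers), summarises both with the
standard thresholds (immotile below VAP 10 µm/s; progressive above VAP
30 µm/s and STR 80%), and reports the motility freezability index — the
post/pre motility ratio as a percentage.
"""

from cryoht import TrackMixture, motility_freezability, simulate_tracks, summarize
from cryoht.kinematics import TrackClassParams

fresh_mix = TrackMixture()  # defaults: 25% progressive / 60% motile / 15% immotile
frozen_mix = TrackMixture(
    weights={"progressive": 0.10, "motile": 0.25, "immotile": 0.65},
    classes={
        "progressive": TrackClassParams(35.0, 6.0, 0.15, 0.05),
        "motile": TrackClassParams(22.0, 4.0, 0.9, 0.05),
        "immotile": TrackClassParams(0.0, 0.0, 0.0, 0.08),
    },
)

fresh = summarize(simulate_tracks(fresh_mix, n=1000, seed=1).tracks)
frozen = summarize(simulate_tracks(frozen_mix, n=1000, seed=2).tracks)

for name, s in (("fresh", fresh), ("frozen", frozen)):
    print(f"{name:<7} TM {s.tm:5.1f}%  PM {s.pm:5.1f}%  "
          f"VCL {s.mean_vcl:5.1f}  VSL {s.mean_vsl:5.1f}  VAP {s.mean_vap:5.1f} µm/s")

fi_tm = motility_freezability(frozen.tm, fresh.tm)
fi_pm = motility_freezability(frozen.pm, fresh.pm)
print(f"motility freezability: TM {fi_tm:.1f}%, PM {fi_pm:.1f}%")

# A freezability index near 40% for TM mirrors the typical post-thaw
# collapse of motility; velocities drop less than the motile fraction does.
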