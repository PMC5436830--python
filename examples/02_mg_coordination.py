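"""Classify the Mg2+ coordination state along a trajectory.

Generates trajectories planted in each binding mode, reports the minimal
Mg-phosphate-oxygen distances, the per-state occupancy, and a distance
histogram such as the ones used to visualize binding-mode stability."""

from mgatp.coordination import CoordinationState, mg_phosphate_distances, occupancy
from mgatp.hbonds import histogram, min_distance_series
from mgatp.synthetic import SiteConfig, build_site_trajectory

for state in (CoordinationState.FIRST_SPHERE_ALPHA_BETA,
              CoordinationState.SECOND_SPHERE):
    cfg = SiteConfig(n_frames=100, mg_state=state, jitter_sigma=0.05, seed=4)
    trajectory, truth = build_site_trajectory(cfg)
    d_alpha, d_beta, d_gamma = mg_phosphate_distances(trajectory.frames[0])
    report = occupancy(trajectory)
    fraction = report.fractions[state]
    print(f"planted {state.value}:")
    print(f"  d(Mg-Oalpha)={d_alpha:.2f}  d(Mg-Obeta)={d_beta:.2f} "
          f" d(Mg-Ogamma)={d_gamma:.2f} A (frame 0)")
    print(f"  occupancy of the planted state over 100 frames: {fraction:.2f}")

    series = min_distance_series(trajectory, "ATP:Oβ", "MG")
    edges, freq = histogram(series, bin_width=0.1)
    peak = freq.argmax()
    print(f"  Mg-Obeta minimal-distance mode: "
          f"{edges[peak]:.1f}-{edges[peak + 1]:.1f} A (freq {freq[peak]:.2f})")
print("First-sphere states put the ion ~2 A from two oxygen groups; the")
print("second-sphere state sits ~4 A away, bridged by water in real systems.")
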