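"""Surface repeatability between two speckled ultrasound scans.

Renders the same bone geometry twice with independent speckle (SNR 4),
detects the bone surface in each, restricts both to the common bone-bearing
range, and reports the symmetric mean absolute distance between the two
surface reconstructions plus Bland-Altman agreement of the normalized
markers.
"""

import math

from osteoquant import phantom, pipeline

config = phantom.PhantomConfig(
    shell_radius_mm=10.0,
    shell_length_mm=10.0,
    voxel_mm=0.2,
    grid_shape=(160, 144, 60),
    deposit_spans=((-math.pi / 4, math.pi / 4, 0.5, 9.5, 2.0),),
    speckle_snr=4.0,
    ct_noise_sd=30.0,
    skin_depth_mm=1.0,
    seed=7,
)
result = pipeline.run_phantom_study(config, seed=42)

mad = result["mad_us_us"]
print(f"mean absolute surface distance, scan 1 vs scan 2: "
      f"{mad.mean_abs_distance_mm:.3f} mm over {mad.n_points} surface points")
print(f"(one voxel is {config.voxel_mm} mm; sub-voxel distance means the two")
print(" speckle realizations reconstruct essentially the same surface)")
print()
print("Bland-Altman of per-slice normalized markers (scan1 - scan2):")
for marker, r in result["bland_altman_us_us"].items():
    print(
        f"  {marker:13s}: mean diff {r.mean_diff:+.4f}, "
        f"95% limits ({r.loa_low:+.3f}, {r.loa_high:+.3f}), n={r.n}"
    )
print()
print("Limits spanning zero with small half-widths indicate the repeated")
print("scans agree within speckle-induced slice-to-slice variation.")
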