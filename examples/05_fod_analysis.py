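"""Fiber orientation distributions over a noisy phantom map.

Simulates a noisy uniform phantom, estimates the per-pixel 3D orientation,
then summarizes the in-plane and through-plane maps with windowed FODs
(peak + FWHM) and an ROI average.
"""

from octaxis import (PhantomSpec, estimate_map, fods_over_windows,
                     simulate_pair_map, summarize_roi)

spec = PhantomSpec(shape=(50, 50), theta=20.0, alpha=30.0, dn=5e-4,
                   omega_deg=15.0, noise_theta_deg=3.0, noise_dn_rel=0.05,
                   seed=8)
pair_map, truth = simulate_pair_map(spec)
result = estimate_map(pair_map)

for channel, values, wrap in [("in-plane", result.theta, True),
                              ("through-plane", result.alpha, False)]:
    # 0.25 mm windows at 10 um pixels -> 25x25-pixel FODs, 4 per map
    fods, excluded = fods_over_windows(values, result.mask, pixel_um=10.0,
                                       window_mm=0.25, bin_deg=5.0, wrap=wrap)
    roi = summarize_roi(fods, wrap=wrap, excluded_fraction=excluded)
    print(f"{channel}: {roi.n_windows} windows, "
          f"mean peak = {roi.mean_peak_deg:+.2f} deg, "
          f"mean FWHM = {roi.mean_fwhm_deg:.2f} deg")

# With 3 deg orientation noise and 5% birefringence noise the FOD peaks sit
# at the ground truth (20 deg in-plane, 30 deg through-plane) and the FWHM
# reflects the propagated measurement noise.
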