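"""Compare the full method against its ablations on a small synthetic suite.

Runs four pipeline variants over 12 mixed-difficulty eyes: the full
method (spatial prior + adaptive filter), prior-only, filter-only, and
the classical-FCM baseline (neither), and prints mean AC/SE/SP, the mean
pupil-center error and the mean iteration count per variant.
"""

from pupilfcm import compare_methods, generate_suite

eyes = generate_suite(12, "mixed", seed=7)
table = compare_methods(eyes)

header = f"{'method':>14} {'AC':>7} {'SE':>7} {'SP':>7} {'err px':>7} {'iters':>6}"
print(header)
for method, row in table.items():
    print(f"{method:>14} {row['ac']:7.4f} {row['se']:7.4f} {row['sp']:7.4f} "
          f"{row['center_error_px']:7.3f} {row['mean_iterations']:6.1f}")
print("\nThe mixed suite cycles clean / glint / low-contrast / eyelash images. "
      "Differences concentrate in AC and SP: eyelash pixels at pupil-like "
      "intensity are the main confounder.")
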