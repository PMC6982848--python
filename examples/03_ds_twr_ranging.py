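"""Why the UWB modules use double-sided two-way ranging.

A single request-reply round ("single-sided") measures the round trip on
one clock and the reply delay on the other; any clock-rate difference
multiplies the (long) reply delay and corrupts the (tiny) flight time.
Adding a second round in the opposite direction cancels that first-order
error.  This script simulates both estimators on the same exchange.
"""

from stemsurvey import ds_twr_distance, simulate_twr_exchange, ss_twr_distance

TRUE_CM = 1000.0  # 10 m between the nodes

print(f"true distance: {TRUE_CM:.0f} cm; replies 1 ms; drifts +20 / -20 ppm\n")
x = simulate_twr_exchange(TRUE_CM, reply1_s=1e-3, reply2_s=1e-3,
                          drift_ppm_A=20.0, drift_ppm_B=-20.0)

ds = ds_twr_distance(x).dis
ss = ss_twr_distance(x).dis
print(f"double-sided estimate: {ds:10.3f} cm   (error {abs(ds - TRUE_CM):9.5f} cm)")
print(f"single-sided estimate: {ss:10.3f} cm   (error {abs(ss - TRUE_CM):9.5f} cm)")
print("\nThe single-sided error is dominated by drift x reply delay "
      "(40 ppm x 0.5 ms ~ 600 cm); the double-sided residual is second-order "
      "in the drift and far below the radio's 1 cm resolution.")
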