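"""Evaluate the exponential learning curves for attack rate and handling time.

Builds a predator that starts naive (a0 = 0.2, h0 = 1) and improves with each
consumed prey toward am = 1 and hm = 0.1, then prints both curves at a few
experience levels.
"""

from funcresp import PredatorParams, attack_rate, handling_time, learning_amplitudes

p = PredatorParams.from_values(a0=0.2, am=1.0, la=0.5, h0=1.0, hm=0.1, lh=0.3)

da, dh = learning_amplitudes(p)
print(f"learning amplitudes: delta_a = {da:.2f}, delta_h = {dh:.2f}")
print(f"{'consumed prey':>14} {'attack rate':>12} {'handling time':>14}")
for n in [0, 1, 2, 5, 10, 50]:
    a = attack_rate(p.attack, n)
    h = handling_time(p.handling, n)
    print(f"{n:>14} {a:>12.4f} {h:>14.4f}")

print(
    "\nAttack rate climbs from a0 toward am and handling time falls toward hm,"
    "\neach exponentially at its own per-prey learning rate (la, lh)."
)
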