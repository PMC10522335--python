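"""How large can the exchanged signaling molecule be?

Brownian motion in 3-d covers L^2 = 6*D*t; with Stokes-Einstein
D = kB*T/(6*pi*eta*r) the largest particle able to cross a gap L within a
time t has radius r = kB*T/(pi*eta) * t/L^2.
"""

from hyphal_dialogue import (prefactor, radius_upper_bound, stokes_einstein_D,
                             traversal_time)

print(f"prefactor kB*T/(pi*eta) at 25 C in water: {prefactor():.3g} m^2/s")

r = 1.5e-9  # a small protein
D = stokes_einstein_D(r)
print(f"a r = 1.5 nm particle diffuses at D = {D:.3g} m^2/s and crosses")
print(f"a 10 um gap in ~{traversal_time(10e-6, D):.2g} s -- fast enough for")
print("a ~100 s signaling cycle.")

rb = radius_upper_bound(10e-6, 10.0)
print(f"\nformula bound at L = 10 um, t = 10 s: r <= {rb:.3g} m")
print("(note: the often-quoted nanometre-scale bound for this argument")
print(" corresponds to L ~ 100 um or t ~ 0.1 s; the formula result is")
print(" reported unmodified)")
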