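"""Calibrate a biosynthesis-pathway expression degree from a titer.

Generates a synthetic mono-culture measurement at a known expression
degree d (the fractional growth loss caused by forcing the pathway to
express), then inverts it: scan d, impose the growth floor
(1−d)·v_nfeg, maximize production, and keep the d that reproduces the
measured titer.
"""

from coyield import calibrate_degree
from coyield.fixtures import ToySpec, synth_monoculture, toy_model

TRUE_D = 0.25

spec = ToySpec(true_d=TRUE_D, noise_cv=0.0)
model = toy_model(spec)
data = synth_monoculture(model, spec)

print(f"measured production: {data.measured_production:.3f} mM over "
      f"{data.culture_duration:.0f} h")

degree = calibrate_degree(model, data)
print(f"calibrated d = {degree.d:.4f}  (generating value {TRUE_D})")
print(f"wild growth v_nfeg = {degree.v_nfeg:.3f} /h, "
      f"forced-expression growth v_feg = {degree.v_feg:.3f} /h")
print(f"residual |simulated - measured| = {degree.residual:.2e}")

# On noise-free data the grid search recovers the generating degree
# exactly (to the 1e-4 grid): the toy's production response is linear
# in d, so the inversion is unambiguous.
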