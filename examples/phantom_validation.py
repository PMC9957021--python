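"""Validate the two-compartment model on the simulated K2HPO4 phantom.

Renders the 10-solution phantom at 100 and 120 kVp with realistic voxel
noise, self-calibrates the marrow/cortical references, and compares the
measured vBMD of every compartment with its known concentration.  The
HU of each solution changes with tube voltage, but the TCM vBMD does
not — the property that makes the method usable across scanners.
"""

from tcmbmd import PhantomSpec, make_spectrum, render_phantom, validate_phantom

spec = PhantomSpec()
print(f"{'conc':>6} | {'HU@100':>9} {'HU@120':>9} | {'vBMD@100':>9} {'vBMD@120':>9}")
results = {}
for kvp in (100.0, 120.0):
    vol, labels = render_phantom(spec, make_spectrum(kvp), noise_sd_hu=10.0, seed=7)
    results[kvp] = validate_phantom(vol, labels, spec)

for r100, r120 in zip(results[100.0][0], results[120.0][0]):
    print(
        f"{r100.concentration:6.2f} | {r100.mean_hu:9.1f} {r120.mean_hu:9.1f} | "
        f"{r100.vbmd:9.4f} {r120.vbmd:9.4f}"
    )
for kvp in (100.0, 120.0):
    fit = results[kvp][1]
    print(
        f"{kvp:g} kVp fit: slope {fit['slope']:.5f}, intercept {fit['intercept']:+.5f}, "
        f"R^2 {fit['r_squared']:.6f}"
    )
print(
    "\nHU columns differ between tube voltages (energy-dependent CT numbers); "
    "the vBMD columns agree with each other and with the concentration "
    "column — the calibration cancels the spectral dependence."
)
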