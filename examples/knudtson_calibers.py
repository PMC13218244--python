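"""Summary calibers from individual vessel widths.

The six largest arteriolar and venular widths near the optic disc are
combined pairwise (largest with smallest, k = 0.88 for arterioles, 0.95
for venules) into the central retinal arteriolar/venular equivalents
CRAE and CRVE; their ratio AVR indexes relative arteriolar narrowing.
"""

from oculovasc.fundus import avr, knudtson_equivalent

arteriole_widths = [21.4, 19.8, 18.9, 17.2, 15.0, 14.1]  # px, zone B
venule_widths = [28.6, 27.1, 25.3, 24.0, 22.8, 20.5]

crae = knudtson_equivalent(arteriole_widths, "artery")
crve = knudtson_equivalent(venule_widths, "vein")

print(f"CRAE = {crae:.3f} px   (summary caliber of the big-6 arterioles)")
print(f"CRVE = {crve:.3f} px   (summary caliber of the big-6 venules)")
print(f"AVR  = {avr(crae, crve):.4f}     (< 1: arterioles narrower than venules)")
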