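"""Compute the CIEDE2000 color difference for one sitting/supine pair.

The sitting measurement is the reference, so the signed components read
supine minus sitting: a negative dL' means the tongue looks darker supine.
"""

from tonguecolor import LabColor, ciede2000

sitting = LabColor(36.0, 23.9, 2.4)   # edge-region color, sitting
supine = LabColor(43.5, 25.1, 5.3)    # same patient, supine

res = ciede2000(sitting, supine)
print(f"dE00      = {res.dE00:.2f}")
print(f"dL' (lightness)  = {res.dL_prime:+.2f}")
print(f"dC' (chroma)     = {res.dC_prime:+.2f}")
print(f"dH' (hue)        = {res.dH_prime:+.2f}")
print(f"weights S_L/S_C/S_H = {res.S_L:.3f}/{res.S_C:.3f}/{res.S_H:.3f}")
print()
print("A dE00 above 4.1 (the 50:50% acceptability threshold) means half of")
print("observers would find the sitting-vs-supine color change objectionable;")
print("here the supine tongue is markedly lighter (dL' dominates).")
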