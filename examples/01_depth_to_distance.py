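"""Convert 8-bit depth codes to real distances.

The sensor reports depth as an 8-bit code (0 = near, 255 = far). A
fitted degree-6 regression polynomial maps a code to centimeters. The
mapping is strongly non-linear — equal code steps correspond to very
different real-distance steps along the range — so the layered depth
features average codes first and convert the mean to cm, rather than
treating codes as distances.
"""

from layerfusion import depth_to_cm

for code in (0, 1, 64, 128, 192, 255):
    print(f"depth code {code:3d} -> {depth_to_cm(code):8.2f} cm")

step_a = depth_to_cm(5) - depth_to_cm(4)
step_b = depth_to_cm(251) - depth_to_cm(250)
print(f"\none code step at codes 4->5 spans {abs(step_a):6.2f} cm,")
print(f"one code step at 250->251 spans    {abs(step_b):6.2f} cm:")
print("the regression is applied exactly as fitted (it is not monotone")
print("over the full code range), and all layer comparisons happen on")
print("the cm scale it produces.")
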