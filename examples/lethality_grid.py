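"""Feed length-derived masses to a plug-in strike-lethality model.

The demonstration grid crosses six vessel types with four lengths (10, 20,
50, 100 m) and two transit speeds (10 and 20 kn), holding the flared-bow
impact area constant at 1.15 m x 1.15 m.  Mass comes from the published
power laws; the probability comes from whatever callable you plug in —
here the built-in TOY logistic model, which exercises the plumbing but is
not a biophysical collision model.
"""

import vesselmass as vm

grid = vm.run_scenario()  # default scenario, toy model

table = grid.pivot_table(
    index=["vessel_type", "loa_m"], columns="speed_kn", values="probability"
)
print("toy-model lethality probability by type, LOA and speed (kn):\n")
print(table.round(3).to_string())

ten_kn_10m = grid[(grid.loa_m == 10.0) & (grid.speed_kn == 10.0)]
print(
    f"\nAt LOA 10 m and 10 kn the toy probability spans "
    f"{ten_kn_10m.probability.min():.2f}-{ten_kn_10m.probability.max():.2f} "
    "across types: same length, different masses, different risk."
)
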