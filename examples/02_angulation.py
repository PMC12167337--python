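"""Measure fracture angulation against the growth-plate perpendicular.

Builds a phantom with a 12-degree dorsally angulated distal fragment and
reads the angle back with the standard clinical protocol: the angle
between the diaphysis axis and the perpendicular to the growth plate.
"""

from pocusalign import AngulationInput, measure_angulation
from pocusalign.phantom import PhantomConfig, generate_pair

for alpha in (0.0, 12.0, 25.0):
    pair = generate_pair(PhantomConfig(seed=4, angulation_deg=alpha))
    inp = AngulationInput(
        growth_plate=pair.growth_plate,
        distal_axis=(pair.fixed_landmarks.L_d0, pair.fixed_landmarks.L_d1),
    )
    print(f"configured angulation {alpha:5.1f} deg -> measured {measure_angulation(inp):6.3f} deg")

print("0 deg is intact anatomy (shaft perpendicular to the physis);")
print("a nonzero reading is the dislocation angle of the distal fragment.")
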