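"""Chroma and hue derivation from CIELab colorimeter readings.

Builds a small flower-color table (L*, a*, b* per organ region) and adds
the polar color coordinates: chroma C* (color intensity, distance from
grey) and hue angle H° (shade: 0° red, 90° yellow, 180° green, 270°
blue). The wide feature matrix at the end is the input clustering uses.
"""

import pandas as pd

from germdiv import ColorTable, color_feature_matrix, derive_color_features

rows = [
    # a dark-red flower eye, a pale slip, a greenish sepal
    {"genotype": "cv_A", "organ": "eye", "L": 30.2, "a": 45.1, "b": -8.0},
    {"genotype": "cv_A", "organ": "slip", "L": 88.0, "a": 12.3, "b": 4.1},
    {"genotype": "cv_A", "organ": "sepal", "L": 55.0, "a": -18.6, "b": 22.8},
    {"genotype": "cv_B", "organ": "eye", "L": 25.7, "a": 52.9, "b": -14.2},
    {"genotype": "cv_B", "organ": "slip", "L": 93.5, "a": 4.0, "b": 2.2},
    {"genotype": "cv_B", "organ": "sepal", "L": 60.1, "a": -22.0, "b": 30.5},
]
table = ColorTable(pd.DataFrame(rows))

derived = derive_color_features(table)
print("Per-measurement chroma and hue:")
print(derived.data.round(2).to_string(index=False))

print("\nWide genotype x (organ.channel) feature matrix:")
print(color_feature_matrix(table).round(2).to_string())
print("\nNegative a* = green, positive a* = red; hue near 340° is purple-red.")
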