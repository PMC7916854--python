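"""Generate a small synthetic 4-channel dataset and inspect its structure.

Each sample is four grayscale PNGs (green = protein of interest, blue =
nucleus, red = microtubules, yellow = ER) plus a row in labels.csv with
one to four organelle class codes.
"""

from collections import Counter
from pathlib import Path

from protloc.simdata import SimConfig, generate_dataset

out = Path("scratch_example_data")
table = generate_dataset(60, SimConfig(image_side=64), seed=1, out_dir=out)

print(f"wrote {len(table)} samples to {out}/")
print(table.head(5).to_string(index=False))

counts = Counter(" ".join(table.classes).split())
print("\nclass counts:", dict(sorted(counts.items())))

k = table.classes.str.split().str.len()
print("localization-count fractions:", k.value_counts(normalize=True).round(3).to_dict())
print("cell lines:", table.cell_line.value_counts().to_dict())
# Expect ~60% single-label samples and lineC as the rare (~10%) morphology.
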