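"""Simulate flipon-style datasets: Z-DNA, G-quadruplex, H-DNA, diffuse.

Each positive sequence carries a planted non-B-DNA signature at strength
0.9; negatives are GC-matched background.  Files go to scratch/ in the
Genomic-Benchmarks CSV dialect plus FASTA and BED.
"""

import os

from gkan import SyntheticDatasetSpec, make_dataset
from gkan.synthetic_data import write_bed, write_csv, write_fasta

os.makedirs("scratch", exist_ok=True)
for cls in ("zdna", "g4", "hdna", "diffuse"):
    spec = SyntheticDatasetSpec(motif_class=cls, n_sequences=200,
                                seq_length=120, motif_length=30,
                                motif_strength=0.9, seed=7)
    data = make_dataset(spec)
    out = f"scratch/{cls}"
    os.makedirs(out, exist_ok=True)
    write_csv(data, f"{out}/dataset.csv")
    write_fasta(data, f"{out}/dataset.fasta")
    write_bed(data, f"{out}/motifs.bed")
    pos = data.sequences[int(data.labels.argmax())]
    span = data.motif_spans[int(data.labels.argmax())]
    print(f"{cls:8s} n={len(data)} balanced, folds 0-4; "
          f"example planted window: {pos[span[0]:span[1]][:40]}")
# the printed windows show each class's signature: R/Y alternation (zdna),
# G-runs with loops (g4), a purine mirror repeat (hdna)
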