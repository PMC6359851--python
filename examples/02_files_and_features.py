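"""The file-based path: FASTA/BED in, feature matrix and labels out.

Writes a small simulated experiment to disk, then reconstructs everything
from the standard files exactly as one would with real genome, TSS/peak
and motif-library downloads.
"""

import tempfile
from pathlib import Path

from tfcoop import (build_feature_matrix, intersect_labels, make_windows,
                    parse_jaspar_pfm, read_bed, read_fasta, write_jaspar_pfm)
from tfcoop.synthetic import default_cooperation_spec, simulate_experiment

spec = default_cooperation_spec(n_decoys=10, n_sequences=200,
                                window_width=400, seed=3)
sim = simulate_experiment(spec, seed=4)

out = Path(tempfile.mkdtemp())
sim.write(out)
write_jaspar_pfm(spec.motifs, out / "motifs.jaspar")
print("wrote", sorted(p.name for p in out.iterdir()))

genome = read_fasta(out / "genome.fa")
window_ivs = read_bed(out / "windows.bed")
peaks = read_bed(out / "peaks.bed")
motifs = parse_jaspar_pfm(out / "motifs.jaspar")

# windows are mid-point anchored, so re-derive them from the intervals
windows = make_windows(window_ivs, genome, flank=len(window_ivs[0]) // 2)
labels = intersect_labels(windows, peaks)
X = build_feature_matrix(windows, motifs, scorer="best_hit")

print(f"genome: {len(genome['chrSim'])} bp on one synthetic chromosome")
print(f"windows: {len(windows)}, of which {int(labels.sum())} overlap a peak")
print(f"feature matrix: {X.shape[0]} sequences x {X.shape[1]} predictors "
      f"({len(motifs)} motif scores + 12 composition rates)")
print("first row, first 3 motif scores:",
      [round(v, 2) for v in X.iloc[0, :3]])
# Each motif score is the best log-odds hit over both strands; the last 12
# columns are the reverse-complement-collapsed (di)nucleotide rates.
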