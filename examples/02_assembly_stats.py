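"""Summary statistics of an assembled transcriptome FASTA.

Writes a small synthetic contig set with a log-normal length distribution
(resembling a de novo transcriptome assembly) and reports contig count,
total bases, N50, mean and median length.  N50 here is the largest contig
length such that contigs of equal or greater length hold at least half the
assembly's bases.
"""

import json
import tempfile
from pathlib import Path

from siphonatlas import generate_atlas, length_summary, read_lengths
from siphonatlas.synthetic_data import generate_go_and_lengths, write_fasta

cm, truth = generate_atlas(seed=0, n_transcripts=500)
_, lengths, _ = generate_go_and_lengths(truth, seed=1)

with tempfile.TemporaryDirectory() as d:
    fasta = Path(d) / "contigs.fasta"
    write_fasta(lengths, fasta, seed=2)
    stats = length_summary(read_lengths(fasta))

print(json.dumps(stats, indent=1))
print("N50 ≥ median, as always for right-skewed assemblies:",
      stats["n50"] >= stats["median"])
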