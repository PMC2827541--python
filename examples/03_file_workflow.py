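"""File-based workflow: edge list + annotation TSV in, prediction table out.

Writes a small edge list with confidence scores and a two-column annotation
file, reads them back with a confidence threshold, builds the trilean label
vector for one term, runs the two-step baseline, and writes the ranked
prediction table.
"""

import tempfile
from pathlib import Path

from bmrf import (
    McmcConfig,
    build_label_vector,
    mrf_deng,
    read_annotations,
    read_edge_list,
    write_predictions,
)

workdir = Path(tempfile.mkdtemp())

(workdir / "edges.tsv").write_text(
    "# proteinA proteinB PE-score\n"
    "p1 p2 4.1\np2 p3 3.9\np3 p4 0.8\np1 p3 5.0\np4 p5 4.4\np2 p5 3.5\n"
)
(workdir / "annotations.tsv").write_text(
    "p1 GO:0001\np2 GO:0001\np3 GO:0002\n"  # p4, p5 unannotated
)

net = read_edge_list(workdir / "edges.tsv", weight_column=2, threshold=3.19)
print(f"after PE > 3.19 filtering: {net.n_nodes} proteins, {net.n_edges} edges")

table = read_annotations(workdir / "annotations.tsv")
labels = build_label_vector(net, table, "GO:0001")
print("labels (1=positive, 0=negative, -1=unknown):",
      dict(zip(net.nodes, labels.tolist())))

out = mrf_deng(net, labels, McmcConfig(n_iter=2000, burn_in=500, seed=0))
rows = [(n, "GO:0001", p) for n, p in out.as_dict().items()]
write_predictions(workdir / "predictions.tsv", rows)
print("\nprediction table:")
print((workdir / "predictions.tsv").read_text())
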