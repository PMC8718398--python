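"""Ingest an association table, project it, and export Cytoscape files.

Writes SIF (bare topology) and GraphML (with every score attached as typed
node/edge attributes) plus the TSV score tables and a JSON report — the
same artifacts the `aonproj build` / `aonproj score` commands produce.
"""

import tempfile
from pathlib import Path

from aonproj import analyze
from aonproj.readwrite import read_association_table, write_score_tables

TABLE = """\
drug_id\tevent_id\tevent_type\tsource
tamoxifen\tMIE:1181\tMIE\tcomptox
tamoxifen\tKE:1115\tKE\tcomptox
bisphenol_a\tMIE:1181\tMIE\taopwiki
bisphenol_a\tKE:1115\tKE\taopwiki
bisphenol_a\tAO:405\tAO\taopwiki
ketoconazole\tMIE:1181\tMIE\tliterature
"""

workdir = Path(tempfile.mkdtemp(prefix="aonproj_"))
table = workdir / "associations.tsv"
table.write_text(TABLE, encoding="utf-8")

records, errors = read_association_table(table)
analysis = analyze(records)
bundle = write_score_tables(analysis, workdir / "out")

print(f"read {len(records)} associations ({len(errors)} rejected rows)")
print(f"monopartite network: {analysis.monopartite.n_events} events, "
      f"{analysis.monopartite.n_edges} edges, "
      f"dH = {analysis.uncertainty.delta_h_network:.2f} nats")
print("\nexported files:")
for name, path in vars(bundle).items():
    print(f"  {name:20s} {path}")
print("\nSIF content (load into Cytoscape via File > Import > Network):")
print(bundle.sif.read_text())
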