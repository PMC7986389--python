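# External benchmark inputs (not bundled)

Drop the distributed inputs of the interactome benchmark here to enable the
replication tests in `tests/test_acceptance.py` and the
`fvsnet.replication.run_benchmark` entry point. Expected files (plain TSV /
one-id-per-line text; see `fvsnet.graph_core` for the formats):

| file | content |
|---|---|
| `mfvs_edges.tsv`   | edge list compressed with the plain bypass (C3 `ignore`) |
| `mfvs_deltam.txt`  | forced vertices (ΔM) matching `mfvs_edges.tsv` |
| `wmfvs_edges.tsv`  | edge list compressed with the weighted bypass (`ignore_w`) |
| `wmfvs_deltam.txt` | forced vertices matching `wmfvs_edges.tsv` |
| `wfvs_edges.tsv`   | edge list compressed with the always-safe rules only |
| `gene_weights.tsv` | gene id → fold-change weight for the whole network |

Nothing in this directory is required for the regular test suite, the
examples or `scripts/acceptance.py`.
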