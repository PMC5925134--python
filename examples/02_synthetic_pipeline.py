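"""Run the full pipeline on a synthetic study with planted signal terms.

Generates a 2,000-gene interaction network, 300 terms and 25 positive genes
with five planted terms (half of every positive's edges rewired into them),
encodes every gene, ranks all terms by mutual information with the label,
and checks that the planted terms surface at the top.
"""

import tempfile
from pathlib import Path

import termrank as tr

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    ds = tr.generate(tr.GeneratorConfig(seed=1), data)
    print(f"generated {ds.network.n_nodes} genes, {ds.network.n_edges} edges, "
          f"{len(ds.catalogue)} terms, {ds.labels.n_positives} positives")
    print(f"planted terms: {', '.join(ds.truth.planted_term_ids)}")

    res = tr.run(tr.RunConfig(
        network=ds.network_path,
        annotations=ds.annotations_path,
        universe=ds.universe_path,
        positives=ds.positives_path,
        out_dir=Path(tmp) / "out",
        cutoff=0.003,
    ))

    print(f"\nfeature matrix: {res.matrix.shape[0]} genes x "
          f"{res.matrix.shape[1]} terms ({res.matrix.values.nnz} nonzeros)")
    print(f"selected {res.counts['n_selected']} terms at MI cutoff 0.003\n")
    print("rank  term      MI (bits)  planted?")
    for e in res.ranking.entries[:10]:
        mark = "yes" if e.term_id in ds.truth.planted_term_ids else ""
        print(f"{e.rank:>4}  {e.term_id:<9} {e.mi:.4f}     {mark}")

print("\nEvery planted term should appear in the top ranks: the ranking")
print("recovers exactly the terms whose members were wired into the")
print("positives' neighbourhoods.")
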