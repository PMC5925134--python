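"""Choose an MI cutoff by inspecting the features-vs-cutoff curve.

The number of selected features as a function of the MI cutoff typically
shows a sharp drop once the handful of label-associated terms is exhausted;
the cutoff is chosen by eye at that elbow, then applied with select().
"""

import tempfile
from pathlib import Path

import termrank as tr

with tempfile.TemporaryDirectory() as tmp:
    ds = tr.generate(tr.GeneratorConfig(seed=1), Path(tmp) / "data")
    labels, _ = tr.restrict_to_analyzable(ds.network, ds.catalogue, ds.labels)
    cat, _ = ds.catalogue.restricted_to(labels.universe)
    matrix = tr.build_matrix(labels, cat, ds.network)
    ranking = tr.maxrel_rank(matrix, labels, cat)

    cutoffs = [0.0, 0.001, 0.002, 0.003, 0.005, 0.01, 0.02]
    curve = tr.cutoff_curve(ranking, cutoffs)
    print("cutoff   n_selected")
    for c, n in curve:
        print(f"{c:<8} {n}")

    selected = tr.select(ranking, 0.003)
    print(f"\nat cutoff 0.003 the selection keeps {len(selected)} terms;")
    print(f"planted terms among them: "
          f"{sum(t in selected.term_ids for t in ds.truth.planted_term_ids)} of "
          f"{len(ds.truth.planted_term_ids)}")
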