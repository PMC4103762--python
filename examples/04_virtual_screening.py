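"""Screen a library against a consensus pharmacophore with fit values.

The library holds 20 'pseudo-ligands' whose feature points sit exactly on
the model centroids (randomly re-posed, so the matcher must re-align them)
and 80 geometry-scrambled decoys. A hit needs ≥3 of 5 features matched and
fit ≥ 3.
"""

from polopharm import fixtures as fx
from polopharm import build_consensus, screen_library

family = fx.make_feature_sets(seed=17)
hypo1 = build_consensus(family.models)
library, truth = fx.make_library(hypo1, n_match=20, n_decoy=80, seed=17)

table, report = screen_library(hypo1, library, max_omitted=2, min_fit=3.0)
print(f"hits: {report['n_hits']} / {report['n_molecules']} molecules")
print(table.head(5).to_string(index=False))
false_hits = set(table.molecule_id) - set(truth["match_ids"])
print(f"decoys slipping through: {len(false_hits)}")
# fit = Σ max(0, 1 − (d/tol)²) over matched features: 5.0 means every
# feature matched with zero displacement; decoys cannot satisfy any pairwise
# distance constraint and never reach the fit-≥3 gate.
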