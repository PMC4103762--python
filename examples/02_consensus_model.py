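"""Build a consensus pharmacophore across nine per-complex hypotheses.

Nine models share a designed five-feature core (3 H-bond acceptors, 1 donor,
1 hydrophobic, jittered ≤0.3 Å) plus random decoy features; keeping only the
features supported by all nine recovers exactly the core.
"""

from polopharm import fixtures as fx
from polopharm import build_consensus, geometry_report

family = fx.make_feature_sets(n_models=9, jitter=0.3, n_extra_range=(0, 4), seed=17)
sizes = [m.n_features for m in family.models]
print(f"model sizes (core 5 + decoys): {sizes}")

hypo1 = build_consensus(family.models, min_support=9, cluster_radius=2.0)
print(f"consensus features: {hypo1.kind_counts()}")
print("\npairwise feature distances (Å):")
print(geometry_report(hypo1).to_string())
# The distance table is the model's geometric constraint set: a matching
# ligand must present these feature kinds at these separations.
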