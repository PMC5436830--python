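"""Full wild-type vs mutant comparison on synthetic replica sets.

Three replicas per variant are generated, analysed for hydrogen-bond
counts, repulsive contacts and network energies, and summarized as a
results table with replica mean ± SD; the binding-energy penalty is the
difference of the two E_HB totals."""

from mgatp.pipeline import RunConfig, VariantSpec, run_compare, tables_to_frame
from mgatp.synthetic import build_site_trajectory, default_site_config


def replicas(variant):
    runs = []
    for seed in range(3):
        cfg = default_site_config(variant, n_frames=20, jitter_sigma=0.03, seed=seed)
        runs.append(build_site_trajectory(cfg)[0])
    return runs


config = RunConfig(
    variants={
        "wild_type": VariantSpec(replicas("wild_type")),
        "mutant": VariantSpec(replicas("mutant")),
    },
    skip_ps=50.0,  # drop the first 5 of 20 frames as equilibration
)
tables, penalty = run_compare(config)
print(tables_to_frame(tables).to_string())
print(f"\nDelta E_HB (mutant - wild type): {penalty:.1f} kcal/mol")
print("A positive penalty means the mutant's hydrogen-bond network binds")
print("ATP more strongly than the wild type's, at the same Mg2+ state.")
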