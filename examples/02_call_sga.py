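"""Calling somatic genomic alteration (SGA) events.

Generates a small synthetic cohort, applies the functional-mutation filter
and the CNV-expression concordance test, and compares the called event
matrix against the planted truth.
"""

from oncothemes import (
    MutationRecord,
    SyntheticConfig,
    build_sga_matrix,
    call_functional_mutations,
    cnv_concordance_test,
    evaluate_recovery,
    generate,
)
from oncothemes.pipeline import cnv_calls_from_matrix

cfg = SyntheticConfig(n_tumors=200, seed=1)
ds = generate(cfg)

records = [
    MutationRecord(r.sample_id, r.gene_id, r.variant_class, r.impact_label)
    for r in ds.mutations.itertuples()
]
mut_pairs = call_functional_mutations(records)
cnv_pairs = cnv_concordance_test(
    cnv_calls_from_matrix(ds.cnv), ds.expression, p_threshold=0.01
)
matrix = build_sga_matrix(mut_pairs, cnv_pairs, min_recurrence=2)

print(f"functional mutation events: {len(mut_pairs)}")
print(f"expression-concordant CNV events: {len(cnv_pairs)}")
print(f"SGA matrix: {len(matrix.tumors)} tumors x {len(matrix.genes)} genes")

metrics = evaluate_recovery(ds.truth, sga=matrix)
print(f"driver sensitivity: {metrics['driver_sensitivity']:.3f}")
print(f"spurious gene fraction: {metrics['spurious_gene_fraction']:.3f}")
# Sensitivity is the fraction of planted driver genes surviving the calls
# and the recurrence filter; spurious genes are called genes that were
# never planted as drivers (passengers that recur by chance).
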