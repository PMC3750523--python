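"""Genome-wide protein statistics summarized by multimerization order.

Generates a synthetic per-gene table (mean copy number, squared CV,
essentiality, homogeneous-subunit count) with the qualitative structure
reported for E. coli — essential genes are more highly expressed, more
often multimeric, and sit on a noise floor — then groups it by
(essentiality, subunit count) and prints percentages and medians.
"""

import multinoise as mn

records = mn.generate_fixture(n_genes=1000, seed=7)
summary = mn.summarize(records)

print(summary.wide().round(2).to_string())
print("\nEssential genes multimerize more often and have higher median means;")
print("median eta flattens toward the configured noise floor (0.12) for the")
print("highly expressed essential groups.")
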