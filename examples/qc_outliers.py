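"""RNA-seq sample QC: mapped-read floor and Tukey-fence outlier removal.

The synthetic knowledgebase plants one sample with too few mapped reads
(< 6M) and one sample whose expression profile comes from the wrong tissue;
the two QC passes should remove exactly those.
"""

import tempfile

from geneprio import pipeline, qc, synthetic

with tempfile.TemporaryDirectory() as tmp:
    _, truth = synthetic.simulate_knowledgebase(synthetic.SMALL, tmp)
    kb = pipeline.load_knowledgebase(tmp)

print(f"samples before QC: {kb.expression.n_samples}")
print(f"planted low-read sample: {truth.low_read_samples}")
print(f"planted mislabeled sample: {truth.mislabeled_samples}")

cleaned, report = qc.run_qc(kb.expression, min_reads=6_000_000, k=3)
print(f"\nsamples after QC: {cleaned.n_samples}")
for tissue, rep in report.per_tissue.items():
    if rep.removed:
        b = rep.bounds
        for s in rep.removed:
            print(f"  removed {s} from {tissue}: mean peer distance "
                  f"{rep.distances[s]:.1f} outside fences "
                  f"[{b.lower:.1f}, {b.upper:.1f}] (k=3)")
print("\nA sample whose mean Euclidean distance to its tissue peers (on "
      "\nlog2(TPM+1)) falls outside Q1/Q3 +- 3*IQR is flagged as mislabeled.")
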