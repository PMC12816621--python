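"""ROI sequencing QC and hypoxia-signature construction.

Filters simulated spatial-profiling regions of interest on the seven
sequencing thresholds, then builds a hypoxia signature by intersecting a
tumor-upregulated gene list with HIF-1a transcriptional targets and scores
it (per-sample median expression).
"""

import numpy as np
import pandas as pd

import glycostrat as g

records = g.gen_roi_records(40, violation_rate=0.4, seed=3)
passed, report = g.roi_qc_filter(records)
print(f"{len(passed)}/{len(records)} ROIs passed QC")
for rule, fails in report.items():
    if fails:
        print(f"  failed {rule}: {fails}")

upregulated = g.GeneSet("pdac_up", ["VEGFA", "SLC2A1", "CA9", "LDHA", "KRT19"])
hif_targets = g.GeneSet("hif1a_targets", ["VEGFA", "SLC2A1", "CA9", "EPO", "PGK1"])
hypoxia_sig = g.build_hypoxia_signature(upregulated, hif_targets)
print(f"hypoxia signature {hypoxia_sig.name}: {list(hypoxia_sig.genes)}")

rng = np.random.default_rng(0)
genes = sorted(set(upregulated.genes) | set(hif_targets.genes))
expr = g.ExpressionMatrix(pd.DataFrame(
    rng.normal(2.0, 1.0, (len(genes), 4)), index=genes,
    columns=[f"s{i}" for i in range(4)],
))
scores = g.hypoxia_score(expr, hypoxia_sig)
print("per-sample hypoxia scores:", np.round(scores.scores, 3).tolist())

# The QC report counts every rule a record violates; the hypoxia score is
# the median expression of the genes both tumor-upregulated and HIF-1a
# regulated, summarizing how hypoxic each sample's program looks.
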