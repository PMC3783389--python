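"""Relative miRNA expression by 2^-ddCt from simulated triplicate Ct values.

Simulates two targets with true test/calibrator ratios 4 and 0.5 against a
5.8S rRNA reference, then summarizes replicates into ratios with SDs.
"""

from mircleave.qpcr import QpcrDesign, summarize_replicates
from mircleave.synthetic import sim_qpcr

table = sim_qpcr({"miR-up": 4.0, "miR-down": 0.5}, noise_sd=0.05, replicates=3, seed=9)
design = QpcrDesign(test_sample="test", calibrator_sample="calibrator", reference_assay="5.8S")

for r in summarize_replicates(table, design):
    print(f"{r.target}: ddCt {r.ddct:+.3f}  ratio {r.ratio:.3f} +/- {r.ratio_sd:.3f}")
print("# ratio = 2^-ddCt; 4 means the target is 4-fold higher in the test sample")
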