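"""Small published datasets bundled for worked examples and checks.

``PINELLIA_SIGNAL_TABLE`` holds the published comparison of miRNA microarray
signals between *Pinellia ternata* (channel A) and *Pinellia pedatisecta*
(channel B) leaves: 21 differentially expressed miRNAs with their mean
channel signals and the printed log2(B/A) ratio.  The signals are
post-normalization summary values — no replicate detail is published — so
fold-only differential calls apply to them.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # family, mirna, sequence, signal_a, signal_b, printed_log2_ratio
    ("miR156", "ghr-miR156c", "UGUCAGAAGAGAGUGAGCAC", 101, 1192, 3.56),
    ("miR156", "osa-miR156l", "CGACAGAAGAGAGUGAGCAUA", 202, 1594, 2.98),
    ("miR156", "vvi-miR156e", "UGACAGAGGAGAGUGAGCAC", 89, 632, 2.83),
    ("miR156", "sbi-miR156e", "UGACAGAAGAGAGCGAGCAC", 298, 2105, 2.82),
    ("miR156", "bna-miR156a", "UGACAGAAGAGAGUGAGCACA", 468, 3200, 2.77),
    ("miR156", "aly-miR156g", "CGACAGAAGAGAGUGAGCAC", 538, 3295, 2.61),
    ("miR156", "aly-miR156a", "UGACAGAAGAGAGUGAGCAC", 557, 3401, 2.61),
    ("miR159", "ptc-miR159f", "AUUGGAGUGAAGGGAGCUCGA", 7570, 3150, -1.27),
    ("miR159", "pta-miR159b", "UUGGAUUGAAGAGAGCUCCC", 3465, 1265, -1.45),
    ("miR159", "zma-miR159e", "AUUGGUUUGAAGGGAGCUCCA", 3250, 1166, -1.48),
    ("miR165", "aly-miR165a", "UCGGACCAGGCUUCAUCCCC", 714, 327, -1.13),
    ("miR166", "aly-miR166a-5p", "GGAAUGUUGUCUGGCUCGAGG", 64, 722, 3.49),
    ("miR168", "aly-miR168a-3p", "CCCGCCUUGCAUCAACUGAAU", 94, 974, 3.38),
    ("miR168", "hvu-miR168-5p", "UCGCUUGGUGCAGAUCGGGAC", 427, 1027, 1.27),
    ("miR396", "gma-miR396e", "UUCCACAGCUUUCUUGAACUGU", 2078, 731, -1.51),
    ("miR397", "ptc-miR397b", "CCAUUGAGUGCAGCGUUGAUG", 87, 2301, 4.72),
    ("miR528", "osa-miR528", "UGGAAGGGGCAUGCAGAGGAG", 1099, 7565, 2.78),
    ("miR535", "aqc-miR535", "UGACAACGAGAGAGAGCACGCG", 9629, 19234, 1.00),
    ("miR894", "ppt-miR894", "CGUUUCACGUCGGGUUCACC", 4403, 2105, -1.06),
    ("miR1450", "ptc-miR1450", "UUCAAUGGCUCGGUCAGGUUAC", 421, 8285, 4.30),
    ("miR2919", "osa-miR2919", "AAGGGGGGGGGGGGAAAGA", 1924, 369, -2.38),
]


def pinellia_signal_table() -> pd.DataFrame:
    """The published 21-row two-channel signal comparison as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["family", "mirna", "sequence", "signal_a", "signal_b", "printed_log2_ratio"],
    )
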