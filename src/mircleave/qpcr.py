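"""Relative quantification of miRNA expression by the 2^-ddCt method.

Threshold cycles (Ct) are normalized to a reference assay (here typically
the 5.8S rRNA) within each sample (dCt = Ct_target - Ct_reference), then to
a calibrator sample (ddCt = dCt_test - dCt_calibrator); the expression ratio
is 2^-ddCt, assuming a doubling per cycle.  Replicate aggregation follows
the independent-experiment convention: mean Ct per (sample, assay) gives the
point estimate, while per-experiment ratios give the reported SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QpcrDesign:
    """Names the test sample, calibrator sample and reference assay."""

    test_sample: str
    calibrator_sample: str
    reference_assay: str = "5.8S"


@dataclass(frozen=True)
class RelativeExpression:
    target: str
    test_sample: str
    calibrator_sample: str
    delta_ct_test: float
    delta_ct_calibrator: float
    ddct: float
    ratio: float
    ratio_sd: float


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """dCt = Ct_target - Ct_reference (within one sample)."""
    return target_ct - reference_ct


def ddct_ratio(dct_test: float, dct_calibrator: float) -> float:
    """Expression ratio 2^-(dCt_test - dCt_calibrator)."""
    return 2.0 ** -(dct_test - dct_calibrator)


def summarize_replicates(ct_table: pd.DataFrame, design: QpcrDesign) -> list[RelativeExpression]:
    """Per-target relative expression with across-experiment SD.

    ``ct_table`` columns: sample, assay, experiment, ct (technical replicates
    within one experiment are averaged first).  The point estimate uses mean
    Ct across experiments; the SD is that of the per-experiment ratios
    (ddof=1; 0 for a single experiment).  Output rows are sorted by target.
    """
    required = {"sample", "assay", "experiment", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    means = ct_table.groupby(["sample", "assay", "experiment"])["ct"].mean()

    def ct_of(sample: str, assay: str, experiment: int | None = None) -> float:
        try:
            if experiment is None:
                return float(means.loc[(sample, assay)].mean())
            return float(means.loc[(sample, assay, experiment)])
        except KeyError as exc:
            raise ValueError(f"no Ct values for sample {sample!r}, assay {assay!r}") from exc

    for sample in (design.test_sample, design.calibrator_sample):
        if (sample, design.reference_assay) not in means.droplevel("experiment").index:
            raise ValueError(
                f"missing reference assay {design.reference_assay!r} for sample {sample!r}"
            )

    targets = sorted(set(ct_table["assay"]) - {design.reference_assay})
    out = []
    for target in targets:
        dct_test = delta_ct(
            ct_of(design.test_sample, target), ct_of(design.test_sample, design.reference_assay)
        )
        dct_cal = delta_ct(
            ct_of(design.calibrator_sample, target),
            ct_of(design.calibrator_sample, design.reference_assay),
        )
        # per-experiment ratios for the SD (experiments present in all four cells)
        exps = None
        for sample, assay in (
            (design.test_sample, target),
            (design.test_sample, design.reference_assay),
            (design.calibrator_sample, target),
            (design.calibrator_sample, design.reference_assay),
        ):
            have = set(means.loc[(sample, assay)].index)
            exps = have if exps is None else exps & have
        ratios = [
            ddct_ratio(
                delta_ct(
                    ct_of(design.test_sample, target, e),
                    ct_of(design.test_sample, design.reference_assay, e),
                ),
                delta_ct(
                    ct_of(design.calibrator_sample, target, e),
                    ct_of(design.calibrator_sample, design.reference_assay, e),
                ),
            )
            for e in sorted(exps or ())
        ]
        sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
        out.append(
            RelativeExpression(
                target=target,
                test_sample=design.test_sample,
                calibrator_sample=design.calibrator_sample,
                delta_ct_test=dct_test,
                delta_ct_calibrator=dct_cal,
                ddct=dct_test - dct_cal,
                ratio=ddct_ratio(dct_test, dct_cal),
                ratio_sd=sd,
            )
        )
    return out


def write_ratio_table(results: list[RelativeExpression], path) -> None:
    """Write relative-expression results as TSV."""
    with open(path, "w", newline="\n") as fh:
        fh.write("target\ttest_sample\tcalibrator_sample\tddct\tratio\tratio_sd\n")
        for r in results:
            fh.write(
                f"{r.target}\t{r.test_sample}\t{r.calibrator_sample}\t"
                f"{r.ddct:.6g}\t{r.ratio:.6g}\t{r.ratio_sd:.6g}\n"
            )
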