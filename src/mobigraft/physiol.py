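"""Validation-assay arithmetic: relative electrical conductance and qPCR ratios.

Two small, exactly specified calculations accompany the sequencing pipeline:

* **REC** (relative electrical conductance), ``(R1/R2) x 100%`` — a membrane
  damage proxy for chilling stress, where R1 is the conductivity of the leaf
  extraction solution before boiling and R2 after;
* **2^-ddCt** relative expression — the standard qPCR normalisation of a
  target gene against a reference gene and a calibrator sample, used to
  verify predicted mobile transcripts against homograft negative controls.

No-amplification wells are encoded as an explicit marker, never as a
sentinel cycle number, so a truly absent transcript propagates as an
infinite (or below-detection) ratio rather than silently entering the
arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: explicit marker for a well in which no amplification occurred
NO_AMPLIFICATION = "no-amplification"

SUPPORTED = "supported"
REFUTED = "refuted"
INDETERMINATE = "indeterminate"


@dataclass
class ConductanceMeasurement:
    sample_id: str
    r1: float  # initial conductivity (instrument units)
    r2: float  # final conductivity after boiling (same units)
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.r1 <= self.r2):
            logger.warning(
                "sample %s: expected 0 <= R1 <= R2, got R1=%s R2=%s",
                self.sample_id, self.r1, self.r2,
            )


@dataclass
class QpcrMeasurement:
    sample_id: str
    gene_id: str
    ct_target: float | str  # cycles, or NO_AMPLIFICATION
    ct_reference: float
    group: str = "heterograft"  # heterograft | positive-control | negative-control
    replicate: int = 1

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target),
                        ("ct_reference", self.ct_reference)):
            if v == NO_AMPLIFICATION:
                continue
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(
                    f"{self.sample_id}/{self.gene_id}: {name} must be a positive "
                    f"finite cycle count or the no-amplification marker, got {v!r}"
                )

    @property
    def amplified(self) -> bool:
        return self.ct_target != NO_AMPLIFICATION


def rec_percent(m: ConductanceMeasurement) -> float:
    """Relative electrical conductance as a percentage: (R1/R2) x 100."""
    if m.r2 == 0:
        raise ValueError(f"sample {m.sample_id!r}: R2 must be positive")
    return m.r1 / m.r2 * 100.0


def ddct_expression(target: QpcrMeasurement,
                    calibrator: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method.

    ``2^-((Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator)``.
    A calibrator that never amplified yields ``math.inf`` (the ratio against
    an absent transcript is infinite); a sample that never amplified while
    the calibrator did yields 0.0 (below detection).
    """
    if not target.amplified and not calibrator.amplified:
        raise ValueError(
            f"{target.gene_id}: neither sample nor calibrator amplified; "
            "the ratio is undefined"
        )
    if not calibrator.amplified:
        return math.inf
    if not target.amplified:
        logger.info("%s: no amplification in sample %s (below detection)",
                    target.gene_id, target.sample_id)
        return 0.0
    dct_sample = target.ct_target - target.ct_reference
    dct_calibrator = calibrator.ct_target - calibrator.ct_reference
    return 2.0 ** -(dct_sample - dct_calibrator)


def mobility_ratio(hetero_expr: float, negctrl_expr: float,
                   min_fold: float = 2.0) -> str:
    """Verdict on a predicted mobile transcript from qPCR expression levels.

    *Supported*: the heterograft tissue expresses the transcript at more than
    ``min_fold`` the negative-control (homograft) level, or the control is
    below detection while the heterograft amplifies.  *Refuted*: no
    expression in the heterograft, or the control matches/exceeds it within
    the fold threshold.  Both below detection → *indeterminate* (the assay
    says nothing either way).
    """
    if hetero_expr < 0 or negctrl_expr < 0:
        raise ValueError("expression ratios must be non-negative")
    hetero_detected = hetero_expr > 0
    negctrl_detected = negctrl_expr > 0
    if not hetero_detected and not negctrl_detected:
        return INDETERMINATE
    if not hetero_detected:
        return REFUTED
    if not negctrl_detected:
        return SUPPORTED
    if math.isinf(hetero_expr):
        return SUPPORTED if not math.isinf(negctrl_expr) else INDETERMINATE
    if math.isinf(negctrl_expr):
        return REFUTED
    return SUPPORTED if hetero_expr / negctrl_expr > min_fold else REFUTED


def read_conductance_tsv(path) -> list[ConductanceMeasurement]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        ConductanceMeasurement(sample_id=str(r.sample_id), r1=float(r.r1),
                               r2=float(r.r2),
                               replicate=int(getattr(r, "replicate", 1)))
        for r in df.itertuples()
    ]


def read_qpcr_tsv(path) -> list[QpcrMeasurement]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        ct = r.ct_target
        if isinstance(ct, str) and ct.strip() == NO_AMPLIFICATION:
            ct_val: float | str = NO_AMPLIFICATION
        else:
            ct_val = float(ct)
        out.append(QpcrMeasurement(
            sample_id=str(r.sample_id), gene_id=str(r.gene_id),
            ct_target=ct_val, ct_reference=float(r.ct_reference),
            group=str(getattr(r, "group", "heterograft")),
            replicate=int(getattr(r, "replicate", 1)),
        ))
    return out
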