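"""Validation-assay arithmetic: REC percentages and qPCR mobility verdicts.

Relative electrical conductance (REC) quantifies chilling damage to leaves;
the 2^-ddCt ratio against the homograft negative control verifies whether a
predicted mobile transcript is really present in the recipient tissue.
"""

from mobigraft import (
    ConductanceMeasurement,
    NO_AMPLIFICATION,
    QpcrMeasurement,
    ddct_expression,
    mobility_ratio,
    rec_percent,
)

print("REC = (R1/R2) x 100%:")
for sample, r1, r2 in [("chilled-leaf", 62.0, 80.0),
                       ("control-leaf", 9.5, 78.0)]:
    rec = rec_percent(ConductanceMeasurement(sample, r1, r2))
    print(f"  {sample}: R1={r1}, R2={r2} -> REC {rec:.1f}%")

print("\nqPCR verification of a predicted mobile transcript:")
hetero = QpcrMeasurement("heterograft-scion", "geneA",
                         ct_target=27.0, ct_reference=21.0)
negctrl = QpcrMeasurement("homograft-scion", "geneA",
                          ct_target=NO_AMPLIFICATION, ct_reference=21.0)
ratio = ddct_expression(hetero, negctrl)
verdict = mobility_ratio(ratio, 0.0)
print(f"  heterograft/negative-control expression ratio: {ratio}")
print(f"  verdict: {verdict}")
# An infinite ratio means the homograft control never amplified: the
# transcript can only have arrived through the graft junction.

print("\na refuted prediction (control expresses the gene just as much):")
neg2 = QpcrMeasurement("homograft-scion", "geneB",
                       ct_target=27.0, ct_reference=21.0)
het2 = QpcrMeasurement("heterograft-scion", "geneB",
                       ct_target=27.0, ct_reference=21.0)
h = ddct_expression(het2, neg2)
print(f"  ratio {h} -> verdict: {mobility_ratio(h, 1.0)}")
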