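"""Independent straight-line transcription of the published SRK/T equations.

Deliberately written as one flat function per quantity, with no shared code
with the package implementation; the two must agree to 0.01 D.
"""

import math


def srkt_refraction_oracle(al: float, mean_k: float, iol_power: float, a_constant: float) -> float:
    r = 337.5 / mean_k
    if al > 24.2:
        lcor = -3.446 + 1.715 * al - 0.0237 * al * al
    else:
        lcor = al
    cw = -5.41 + 0.58412 * lcor + 0.098 * mean_k
    operand = r * r - (cw * cw) / 4.0
    if operand < 0.0:
        operand = 0.0
    h = r - math.sqrt(operand)
    acd_const = 0.62467 * a_constant - 68.747
    acd_est = h + acd_const - 3.336
    rethick = 0.65696 - 0.02029 * al
    lopt = al + rethick
    na = 1.336
    ncm1 = 0.333
    v = 12.0
    p = iol_power
    numerator = 1000.0 * na * (na * r - ncm1 * lopt) - p * (lopt - acd_est) * (
        na * r - ncm1 * acd_est
    )
    denominator = na * (v * (na * r - ncm1 * lopt) + lopt * r) - 0.001 * p * (
        lopt - acd_est
    ) * (v * (na * r - ncm1 * acd_est) + acd_est * r)
    return numerator / denominator


def srkt_emmetropia_power_oracle(al: float, mean_k: float, a_constant: float) -> float:
    r = 337.5 / mean_k
    if al > 24.2:
        lcor = -3.446 + 1.715 * al - 0.0237 * al * al
    else:
        lcor = al
    cw = -5.41 + 0.58412 * lcor + 0.098 * mean_k
    operand = r * r - (cw * cw) / 4.0
    if operand < 0.0:
        operand = 0.0
    h = r - math.sqrt(operand)
    acd_const = 0.62467 * a_constant - 68.747
    acd_est = h + acd_const - 3.336
    rethick = 0.65696 - 0.02029 * al
    lopt = al + rethick
    na = 1.336
    ncm1 = 0.333
    return (1000.0 * na * (na * r - ncm1 * lopt)) / (
        (lopt - acd_est) * (na * r - ncm1 * acd_est)
    )
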