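"""Independent numeric oracles shared by the test modules."""

import numpy as np
from scipy import optimize


def table_correlation(freqs):
    """Allelic correlation computed from a 2x2 haplotype-frequency table."""
    f_mm, f_mM, f_Mm, _ = freqs
    p_t = f_mm + f_mM
    p_c = f_mm + f_Mm
    return (f_mm - p_t * p_c) / np.sqrt(p_t * (1 - p_t) * p_c * (1 - p_c))


def max_corr_numeric(p_t, p_c):
    """Maximize the allelic correlation over all valid haplotype tables
    with margins (p_t, p_c), by bounded scalar optimization over the
    both-minor haplotype frequency."""
    lo, hi = max(0.0, p_t + p_c - 1.0), min(p_t, p_c)

    def neg_corr(f_mm):
        return -table_correlation(
            (f_mm, p_t - f_mm, p_c - f_mm, 1 - p_t - p_c + f_mm)
        )

    res = optimize.minimize_scalar(
        neg_corr, bounds=(lo, hi), method="bounded", options={"xatol": 1e-13}
    )
    return max(-res.fun, -neg_corr(hi))
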