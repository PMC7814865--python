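"""Independent closed-form oracles shared across test modules."""

import numpy as np

from mvdry.synthetic import AbsorptionStudySpec


def gradient_se_oracle(spec: AbsorptionStudySpec) -> float:
    """Closed-form standard error of the recovered efficiency gradient.

    Per-run absorbed-power noise is sd_g * dHs / (duration * 3600); background
    subtraction doubles the variance.  That propagates through the per-
    concentration OLS slope (SE = sd / sqrt(Sxx_power)) and then through the
    efficiency-vs-concentration OLS (SE = slope_se / sqrt(Sxx_conc)),
    treating the per-concentration slopes as independent.
    """
    sd_w = spec.noise_sd_g * spec.dhs_J_per_g / (spec.duration_h * 3600.0)
    sd_corrected = sd_w * np.sqrt(2.0)
    powers = np.array([p for p in spec.applied_powers_w if p > 0])
    sxx_power = np.sum((powers - powers.mean()) ** 2)
    slope_se = sd_corrected / np.sqrt(sxx_power)
    conc = np.array(spec.concentrations_pct_wv)
    sxx_conc = np.sum((conc - conc.mean()) ** 2)
    return slope_se / np.sqrt(sxx_conc)
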