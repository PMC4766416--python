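"""Atomic masses and triclosan molar-mass arithmetic shared across modules."""

from __future__ import annotations

# atomic masses (g/mol)
MASS_12C = 12.000
MASS_13C = 13.00335
MASS_H = 1.008
MASS_CL = 35.453
MASS_O = 15.999

# triclosan: C12 H7 Cl3 O2
TCS_N_C = 12
TCS_N_H = 7
TCS_N_CL = 3
TCS_N_O = 2


def tcs_molar_mass(n_labeled_c: int = 0) -> float:
    """Molar mass of triclosan with `n_labeled_c` carbons replaced by 13C."""
    if not 0 <= n_labeled_c <= TCS_N_C:
        raise ValueError(
            f"triclosan has {TCS_N_C} carbons; got n_labeled_c={n_labeled_c}"
        )
    return (
        (TCS_N_C - n_labeled_c) * MASS_12C
        + n_labeled_c * MASS_13C
        + TCS_N_H * MASS_H
        + TCS_N_CL * MASS_CL
        + TCS_N_O * MASS_O
    )
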