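"""Hemoglobin extinction coefficients and the two-wavelength solve table.

Default values are the compiled molar hemoglobin absorption spectra widely
used in tissue optics, converted to 1/(mM cm). Any table can be supplied as
``{wavelength_nm: {"HbO2": eps, "HHb": eps}}``; the only structural
requirement is that the wavelength x chromophore matrix is non-singular,
otherwise the two concentrations cannot be separated.
"""

from __future__ import annotations

import numpy as np

CHROMOPHORES = ("HbO2", "HHb")

# 1/(mM cm); compiled in-vitro hemoglobin spectra (molar values / 1000)
DEFAULT_EXTINCTION = {
    690.0: {"HbO2": 0.2760, "HHb": 2.0520},
    830.0: {"HbO2": 0.9740, "HHb": 0.6930},
}

LN10 = float(np.log(10.0))


class ExtinctionTable:
    """Extinction coefficients epsilon(wavelength, chromophore) in 1/(mM cm)."""

    def __init__(self, table: dict[float, dict[str, float]] | None = None):
        table = table if table is not None else DEFAULT_EXTINCTION
        self.wavelengths_nm = tuple(sorted(float(w) for w in table))
        rows = []
        for w in self.wavelengths_nm:
            entry = {str(k): float(v) for k, v in table[w].items()}
            missing = [c for c in CHROMOPHORES if c not in entry]
            if missing:
                raise ValueError(f"extinction table at {w} nm missing {missing}")
            rows.append([entry[c] for c in CHROMOPHORES])
        self.matrix = np.asarray(rows, dtype=float)  # (n_wavelengths, 2)
        if len(self.wavelengths_nm) == 2:
            if abs(np.linalg.det(self.matrix)) < 1e-12:
                raise ValueError("extinction matrix is singular; wavelengths are degenerate")
            self.condition_number = float(np.linalg.cond(self.matrix))
        else:
            self.condition_number = float(np.linalg.cond(self.matrix))

    def epsilon(self, wavelength_nm: float, chromophore: str) -> float:
        i = self.wavelengths_nm.index(float(wavelength_nm))
        return float(self.matrix[i, CHROMOPHORES.index(chromophore)])

    def row(self, wavelength_nm: float) -> np.ndarray:
        return self.matrix[self.wavelengths_nm.index(float(wavelength_nm))]

    def submatrix(self, wavelengths_nm) -> np.ndarray:
        """Rows of the table for the given wavelengths, in the given order."""
        return np.stack([self.row(w) for w in wavelengths_nm])

    def to_dict(self) -> dict:
        return {
            str(w): {c: float(self.epsilon(w, c)) for c in CHROMOPHORES}
            for w in self.wavelengths_nm
        }

    def mua_from_concentrations(self, wavelengths_nm, c_hbo2_uM, c_hhb_uM) -> np.ndarray:
        """Absorption coefficient mu_a (1/cm) from concentrations in uM.

        mu_a(lambda) = ln(10) * sum_c eps_c(lambda) * C_c, with C in mM.
        Broadcasts over arbitrary concentration array shapes; output gains a
        trailing wavelength axis.
        """
        e = self.submatrix(wavelengths_nm)  # (nw, 2)
        c = np.stack(
            [np.asarray(c_hbo2_uM, dtype=float), np.asarray(c_hhb_uM, dtype=float)],
            axis=-1,
        ) / 1000.0  # mM
        return LN10 * (c @ e.T)
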