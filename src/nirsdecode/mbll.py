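"""Modified Beer-Lambert law (MBLL) forward and inverse transforms.

The MBLL relates optical-density change at wavelength lambda to chromophore
concentration changes:

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * d * DPF(lambda)

with eps the decadic molar extinction coefficients (1/(M*cm)), d the
source-detector distance (cm) and DPF the dimensionless differential
pathlength factor. With two wavelengths this is an invertible 2x2 linear
system per time point; concentrations are in molar units.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

#: Wavelength-dependent differential pathlength factor defaults (adult head).
DEFAULT_DPF = {760.0: 6.4, 850.0: 5.75}


def load_extinction_table() -> dict[float, tuple[float, float]]:
    """Packaged extinction-coefficient table: wavelength -> (eps_HbO, eps_HbR)."""
    table = {}
    ref = resources.files("nirsdecode.data").joinpath("extinction_coefficients.csv")
    with ref.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("wavelength"):
                continue
            wl, e_hbo, e_hbr = line.split(",")
            table[float(wl)] = (float(e_hbo), float(e_hbr))
    return table


@dataclass(frozen=True)
class MBLLParams:
    """Constants of the two-wavelength MBLL system.

    ``extinction[i] = (eps_HbO, eps_HbR)`` for ``wavelengths[i]``, in
    1/(M*cm); ``dpf[i]`` dimensionless; ``distance`` in cm.
    """

    wavelengths: tuple[float, float] = (760.0, 850.0)
    extinction: tuple[tuple[float, float], tuple[float, float]] | None = None
    dpf: tuple[float, float] | None = None
    distance: float = 3.0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("source-detector distance must be > 0")
        if self.extinction is None:
            table = load_extinction_table()
            try:
                ext = tuple(table[w] for w in self.wavelengths)
            except KeyError as err:
                raise ValueError(
                    f"no packaged extinction coefficients for {err.args[0]} nm; "
                    "pass `extinction` explicitly"
                ) from None
            object.__setattr__(self, "extinction", ext)
        if self.dpf is None:
            dpf = tuple(DEFAULT_DPF.get(w, 6.0) for w in self.wavelengths)
            object.__setattr__(self, "dpf", dpf)
        if any(v <= 0 for v in self.dpf):
            raise ValueError("DPF values must be > 0")
        if not np.isfinite(np.linalg.cond(self.system_matrix())):
            raise ValueError("extinction matrix is singular")

    def system_matrix(self) -> np.ndarray:
        """2x2 matrix mapping (dHbO, dHbR) -> (dOD(l1), dOD(l2))."""
        rows = []
        for (e_hbo, e_hbr), dpf in zip(self.extinction, self.dpf):
            rows.append([e_hbo * self.distance * dpf, e_hbr * self.distance * dpf])
        return np.asarray(rows, dtype=float)


def hemoglobin_to_od(hbo: np.ndarray, hbr: np.ndarray, params: MBLLParams) -> np.ndarray:
    """Forward MBLL: concentration changes (M) -> OD changes, shape (2, ...)."""
    A = params.system_matrix()
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    conc = np.stack([hbo, hbr])
    return np.tensordot(A, conc, axes=(1, 0))


def od_to_hemoglobin(od: np.ndarray, params: MBLLParams) -> tuple[np.ndarray, np.ndarray]:
    """Inverse MBLL: OD changes at both wavelengths -> (dHbO, dHbR) in M.

    ``od`` has shape (2, ...) with the leading axis ordered like
    ``params.wavelengths``. The 2x2 system is solved exactly; the solution is
    invariant to a consistent permutation of the two wavelength rows.
    """
    od = np.asarray(od, dtype=float)
    if od.shape[0] != 2:
        raise ValueError("od must have both wavelengths on the leading axis")
    A = params.system_matrix()
    flat = od.reshape(2, -1)
    conc = np.linalg.solve(A, flat).reshape(od.shape)
    return conc[0], conc[1]
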