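"""Temperature standardisation of g_m and Fick's-law derived quantities.

Mesophyll conductance is temperature dependent; measurements taken between
15 and 35 degC are brought to a common reference of 25 degC (g_m,25) by
dividing by a dimensionless scaling factor f(T) with f(25) = 1.  Two response
shapes are shipped (see ``data/tresponse.yaml``): a peaked Arrhenius curve
measured on tobacco (default) and a weaker simple Arrhenius curve measured on
Arabidopsis, used to bracket the uncertainty in the response.  Values at the
original measurement temperature are retained alongside g_m,25.

Fick's first law, g_m = A_n/(C_i - C_c), gives the chloroplastic CO2
concentration C_c = C_i - A_n/g_m and the drawdown C_i - C_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "R_GAS",
    "T_REF_C",
    "TemperatureResponse",
    "load_response",
    "available_responses",
    "temperature_scaling_factor",
    "standardize_gm_to_25",
    "compute_Cc",
    "derive_gas_exchange",
]

R_GAS = 8.314  # J mol-1 K-1
T_REF_C = 25.0

_FAMILIES = ("peaked_arrhenius", "arrhenius", "polynomial")


@dataclass(frozen=True)
class TemperatureResponse:
    """A named g_m temperature response, normalised to f(T_ref) = 1.

    ``params`` keys by family: peaked_arrhenius -> c, Ha, Hd, dS
    (J mol-1 / J mol-1 K-1); arrhenius -> Ea (J mol-1); polynomial ->
    coeffs (ascending powers of T in degC).
    """

    name: str
    family: str
    params: dict = field(default_factory=dict)
    T_ref: float = T_REF_C

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown response family: {self.family!r}")
        required = {
            "peaked_arrhenius": {"c", "Ha", "Hd", "dS"},
            "arrhenius": {"Ea"},
            "polynomial": {"coeffs"},
        }[self.family]
        missing = required - set(self.params)
        if missing:
            raise ValueError(
                f"{self.family} response {self.name!r} missing params: {sorted(missing)}"
            )

    def _raw(self, T_c):
        Tk = np.asarray(T_c, dtype=float) + 273.15
        p = self.params
        if self.family == "peaked_arrhenius":
            num = np.exp(p["c"] - p["Ha"] / (R_GAS * Tk))
            den = 1.0 + np.exp((p["dS"] * Tk - p["Hd"]) / (R_GAS * Tk))
            return num / den
        if self.family == "arrhenius":
            Tr = self.T_ref + 273.15
            return np.exp(p["Ea"] * (Tk - Tr) / (Tr * R_GAS * Tk))
        return np.polynomial.polynomial.polyval(np.asarray(T_c, dtype=float), p["coeffs"])

    def factor(self, T_c):
        """Scaling factor f(T); f(T_ref) = 1 exactly by construction."""
        T = np.asarray(T_c, dtype=float)
        if np.any((T <= 0) | (T >= 50)):
            raise ValueError("temperature outside the supported range (0, 50) degC")
        f = self._raw(T) / self._raw(self.T_ref)
        return float(f) if np.isscalar(T_c) else f


def _param_file() -> Path:
    return Path(str(resources.files("mesolim").joinpath("data/tresponse.yaml")))


def available_responses(path: str | Path | None = None) -> list[str]:
    doc = yaml.safe_load(Path(path or _param_file()).read_text())
    return sorted(doc["responses"])


def load_response(name: str = "tobacco", path: str | Path | None = None) -> TemperatureResponse:
    """Load a named response from the packaged (or a user) YAML file."""
    doc = yaml.safe_load(Path(path or _param_file()).read_text())
    try:
        entry = doc["responses"][name]
    except KeyError:
        raise KeyError(
            f"no temperature response named {name!r}; available: {sorted(doc['responses'])}"
        ) from None
    return TemperatureResponse(
        name=name,
        family=entry["family"],
        params=dict(entry["params"]),
        T_ref=float(entry.get("T_ref", T_REF_C)),
    )


def temperature_scaling_factor(T_c, params: TemperatureResponse):
    """f(T) such that g_m(T) = g_m,25 * f(T); f(25) = 1 exactly."""
    return params.factor(T_c)


def standardize_gm_to_25(
    gm, T_c, params: TemperatureResponse, already_standardised=False
):
    """g_m,25 = g_m / f(T); pass-through where the source already reports
    25 degC-standardised values (``already_standardised``)."""
    gm = np.asarray(gm, dtype=float)
    if np.any(gm[np.isfinite(gm)] <= 0):
        raise ValueError("gm must be positive")
    f = params.factor(T_c)
    out = np.where(np.asarray(already_standardised, dtype=bool), gm, gm / f)
    return float(out) if out.ndim == 0 else out


def compute_Cc(An, Ci, gm):
    """C_c and the CO2 drawdown from Fick's first law.

    drawdown = A_n/g_m (umol mol-1); C_c = C_i - drawdown.  For A_n <= 0 the
    drawdown is non-positive and C_c >= C_i, which is physically admissible
    (respiration) and left to callers to flag.
    """
    An = np.asarray(An, dtype=float)
    gm = np.asarray(gm, dtype=float)
    if np.any(gm[np.isfinite(gm)] <= 0):
        raise ValueError("gm must be positive (drawdown undefined at gm = 0)")
    drawdown = An / gm
    Cc = np.asarray(Ci, dtype=float) - drawdown
    if Cc.ndim == 0:
        return float(Cc), float(drawdown)
    return Cc, drawdown


def derive_gas_exchange(df: pd.DataFrame, params: TemperatureResponse) -> pd.DataFrame:
    """Add derived columns to a unit-standardised frame.

    Requires a ``gm`` column (mol m-2 s-1 at 100 kPa).  Adds ``f_T``,
    ``gm_25``, and, where A_n/C_i/C_a are present, ``Cc``, ``drawdown``,
    ``Cc_over_Ca`` and ``Ci_over_Ca``.  Rows without a usable measurement
    temperature keep a missing ``gm_25`` unless flagged already-standardised.
    """
    out = df.copy()
    T = pd.to_numeric(out.get("T_meas"), errors="coerce").to_numpy(dtype=float)
    gm = pd.to_numeric(out["gm"], errors="coerce").to_numpy(dtype=float)
    ok_T = np.isfinite(T) & (T > 0) & (T < 50)
    f = np.full(len(out), np.nan)
    if ok_T.any():
        f[ok_T] = params.factor(T[ok_T])
    already = out.get("already_standardised")
    already = (
        np.asarray(already, dtype=bool) if already is not None
        else np.zeros(len(out), dtype=bool)
    )
    gm25 = np.where(already, gm, gm / f)
    out["f_T"] = f
    out["gm_25"] = gm25

    An = pd.to_numeric(out.get("An"), errors="coerce").to_numpy(dtype=float)
    Ci = pd.to_numeric(out.get("Ci"), errors="coerce").to_numpy(dtype=float)
    Ca = pd.to_numeric(out.get("Ca"), errors="coerce").to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        drawdown = np.where(gm > 0, An / gm, np.nan)
        Cc = Ci - drawdown
        out["drawdown"] = drawdown
        out["Cc"] = Cc
        out["Cc_over_Ca"] = Cc / Ca
        out["Ci_over_Ca"] = Ci / Ca
    return out
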