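"""Record schema, CSV ingest, unit/pressure standardisation and PFT labels.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per gas-exchange measurement (one aggregated g_m value per set of plants).
:class:`GasExchangeRecord` and :class:`LeafTraits` document the row schema and
back the row-wise accessors; all pipeline stages operate on the frame.

Mesophyll conductance (g_m) is reported in the literature either as a
gas-phase conductance (mol m-2 s-1) or in liquid-phase-equivalent,
pressure-normalised units (mol m-2 s-1 bar-1 or umol m-2 s-1 Pa-1).  All
values are standardised here to mol m-2 s-1 at an atmospheric pressure of
100 kPa (= 1 bar); if neither pressure nor elevation is recorded, 100 kPa
is assumed.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PFT",
    "GmUnits",
    "Method",
    "GasExchangeRecord",
    "LeafTraits",
    "ParseLog",
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "standardize_units",
    "standardize_units_frame",
    "elevation_to_pressure",
    "gsw_to_gsc",
    "assign_pft",
    "load_schema",
    "MANDATORY_COLUMNS",
    "NUMERIC_COLUMNS",
    "TRAIT_COLUMNS",
]

STANDARD_PRESSURE_KPA = 100.0


class PFT(str, enum.Enum):
    """Plant functional types carried through the analysis.

    CAM, C4, semideciduous, deciduous gymnosperms, fern allies and mosses are
    pooled into ``other``: their labels are carried but they are excluded from
    PFT-level statistics.
    """

    fern = "fern"
    evergreen_gymnosperm = "evergreen_gymnosperm"
    evergreen_angiosperm = "evergreen_angiosperm"
    deciduous_angiosperm = "deciduous_angiosperm"
    C3_perennial_herb = "C3_perennial_herb"
    C3_annual_herb = "C3_annual_herb"
    other = "other"


#: PFTs entering PFT-level statistics (everything but ``other``).
ANALYSIS_PFTS = [p for p in PFT if p is not PFT.other]

#: Growth-form used by the extreme-value outlier thresholds.
HERBACEOUS_PFTS = {PFT.C3_perennial_herb, PFT.C3_annual_herb}


class GmUnits(str, enum.Enum):
    mol_m2_s = "mol_m2_s"
    mol_m2_s_bar = "mol_m2_s_bar"
    umol_m2_s_Pa = "umol_m2_s_Pa"


class Method(str, enum.Enum):
    isotope = "isotope"
    fluorescence = "fluorescence"
    curve_fitting = "curve_fitting"
    other = "other"


@dataclass
class GasExchangeRecord:
    """One leaf gas-exchange measurement row.

    Units: g_m per ``gm_units``; A_n umol m-2 s-1; g_s,c mol m-2 s-1 (CO2
    basis); C_i, C_a umol mol-1; T_meas degC; PPFD umol m-2 s-1; pressure kPa;
    elevation m.  ``Anp`` is net photosynthesis assuming C_c = C_i (infinite
    g_m, stomata as measured).
    """

    study_id: str
    species: str | None = None
    pft: PFT = PFT.other
    gm_value: float | None = None
    gm_units: GmUnits = GmUnits.mol_m2_s
    method: Method = Method.other
    T_meas: float | None = None
    PPFD: float | None = None
    CO2_meas: float | None = None
    pressure: float | None = None
    elevation: float | None = None
    An: float | None = None
    gs_c: float | None = None
    Ci: float | None = None
    Ca: float | None = None
    Anp: float | None = None
    already_standardised: bool = False
    flags: tuple[str, ...] = ()


@dataclass
class LeafTraits:
    """Optional anatomical/biochemical covariates for one record.

    Sc/Sm: chloroplast/mesophyll surface area exposed to intercellular
    airspaces per leaf area (m2 m-2); Tcw: cell-wall thickness (um);
    LMA g m-2; N_area, K_area, rubisco g m-2; Vcmax_Cc umol m-2 s-1.
    """

    Sc: float | None = None
    Sm: float | None = None
    Tcw: float | None = None
    LMA: float | None = None
    leaf_thickness: float | None = None
    density: float | None = None
    porosity: float | None = None
    N_area: float | None = None
    K_area: float | None = None
    rubisco: float | None = None
    Vcmax_Cc: float | None = None
    stomatal_density: float | None = None
    stomatal_length: float | None = None


MANDATORY_COLUMNS = ("gm_value", "gm_units", "pft", "study_id")

NUMERIC_COLUMNS = (
    "gm_value", "T_meas", "PPFD", "CO2_meas", "pressure", "elevation",
    "An", "gs_c", "Ci", "Ca", "Anp",
)

TRAIT_COLUMNS = tuple(f.name for f in dataclasses.fields(LeafTraits))

_RECORD_COLUMNS = tuple(f.name for f in dataclasses.fields(GasExchangeRecord) if f.name != "flags")


class SchemaError(ValueError):
    """A mandatory column is missing or a schema mapping is invalid."""


@dataclass
class ParseLog:
    """Per-run ingest log: coerced cells and row-level validation flags."""

    coerced: list[dict] = dataclasses.field(default_factory=list)
    flagged: list[dict] = dataclasses.field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"coerced": self.coerced, "flagged": self.flagged}, indent=2)
        )


def load_schema(path: str | Path) -> dict[str, str]:
    """Read a {source column -> canonical column} mapping from YAML."""
    mapping = yaml.safe_load(Path(path).read_text())
    if not isinstance(mapping, Mapping):
        raise SchemaError("schema file must contain a mapping of column names")
    return {str(k): str(v) for k, v in mapping.items()}


def read_dataset(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, ParseLog]:
    """Read a gas-exchange CSV into the canonical frame.

    ``schema`` maps source column names to canonical ones.  Unparseable cells
    in optional numeric columns become missing (logged), never errors; the row
    count is preserved.  Rows with non-positive g_m are retained but flagged.

    Raises :class:`SchemaError` naming the first missing mandatory column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True, encoding="utf-8")
    if schema:
        df = df.rename(columns=dict(schema))
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column missing: {col!r}")

    log = ParseLog()
    for col in NUMERIC_COLUMNS + TRAIT_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.str.strip() != "")
        for idx in df.index[bad]:
            log.coerced.append({"row": int(idx), "column": col, "value": raw.loc[idx]})
        df[col] = num

    if "already_standardised" in df.columns:
        df["already_standardised"] = (
            df["already_standardised"].str.strip().str.lower().isin(("true", "1", "yes"))
        )
    else:
        df["already_standardised"] = False

    df["row_flags"] = ""
    nonpos = df["gm_value"].notna() & (df["gm_value"] <= 0)
    for idx in df.index[nonpos]:
        log.flagged.append({"row": int(idx), "flag": "non_positive_gm"})
    df.loc[nonpos, "row_flags"] = "non_positive_gm"
    return df, log


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical frame back to CSV (UTF-8, comma, '.' decimal)."""
    df.to_csv(path, index=False, encoding="utf-8")


def iter_records(df: pd.DataFrame) -> Iterator[GasExchangeRecord]:
    """Yield typed records from a canonical frame (missing -> None)."""
    for _, row in df.iterrows():
        kwargs = {}
        for name in _RECORD_COLUMNS:
            if name not in row.index:
                continue
            val = row[name]
            if isinstance(val, float) and np.isnan(val):
                val = None
            if name == "pft" and val is not None:
                val = PFT(val)
            elif name == "gm_units" and val is not None:
                val = GmUnits(val)
            elif name == "method" and val is not None:
                val = Method(val)
            kwargs[name] = val
        flags = tuple(str(row.get("row_flags", "") or "").split(";")) if row.get("row_flags") else ()
        yield GasExchangeRecord(flags=flags, **kwargs)


# --- unit and pressure standardisation -------------------------------------

def elevation_to_pressure(elevation_m: float) -> float:
    """Mean atmospheric pressure (kPa) from elevation via the international
    barometric formula P = 101.325 (1 - 2.25577e-5 z)^5.25588."""
    return 101.325 * (1.0 - 2.25577e-5 * elevation_m) ** 5.25588


def gsw_to_gsc(gs_w: float) -> float:
    """Stomatal conductance to water vapour -> CO2 basis (divide by 1.6,
    the ratio of the molecular diffusivities of H2O and CO2 in air)."""
    return gs_w / 1.6


def standardize_units(
    gm_value: float,
    gm_units: GmUnits | str,
    pressure_kPa: float | None = None,
    elevation_m: float | None = None,
) -> float:
    """Convert one g_m value to mol m-2 s-1 at 100 kPa.

    Pressure-normalised units: umol m-2 s-1 Pa-1 = 0.1 mol m-2 s-1 bar-1;
    mol m-2 s-1 bar-1 times P (bar) gives mol m-2 s-1.  The pressure is taken
    from ``pressure_kPa`` if given, else derived from ``elevation_m``, else
    assumed 100 kPa.
    """
    units = GmUnits(gm_units)
    if not np.isfinite(gm_value) or gm_value <= 0:
        raise ValueError(f"gm_value must be positive, got {gm_value!r}")
    if pressure_kPa is not None and pressure_kPa <= 0:
        raise ValueError(f"pressure must be positive, got {pressure_kPa!r}")

    if units is GmUnits.mol_m2_s:
        return float(gm_value)

    if pressure_kPa is None:
        pressure_kPa = (
            elevation_to_pressure(elevation_m) if elevation_m is not None
            else STANDARD_PRESSURE_KPA
        )
    per_bar = gm_value * 0.1 if units is GmUnits.umol_m2_s_Pa else gm_value
    return float(per_bar * pressure_kPa / 100.0)  # 100 kPa = 1 bar


def standardize_units_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`standardize_units` over the canonical frame.

    Adds ``gm`` (mol m-2 s-1 at 100 kPa); rows with missing or non-positive
    g_m get a missing ``gm``.
    """
    out = df.copy()
    gm = pd.to_numeric(out["gm_value"], errors="coerce").astype(float).to_numpy()
    gm = np.where(gm > 0, gm, np.nan)
    units = out["gm_units"].astype(str).to_numpy()

    pressure = np.full(len(out), STANDARD_PRESSURE_KPA)
    if "pressure" in out.columns:
        p = pd.to_numeric(out["pressure"], errors="coerce").to_numpy(dtype=float)
        has_p = np.isfinite(p) & (p > 0)
        pressure[has_p] = p[has_p]
    else:
        has_p = np.zeros(len(out), dtype=bool)
    if "elevation" in out.columns:
        z = pd.to_numeric(out["elevation"], errors="coerce").to_numpy(dtype=float)
        use_z = ~has_p & np.isfinite(z)
        pressure[use_z] = elevation_to_pressure(z[use_z])

    std = gm.copy()
    is_pa = units == GmUnits.umol_m2_s_Pa.value
    is_bar = units == GmUnits.mol_m2_s_bar.value
    std[is_pa] = gm[is_pa] * 0.1 * pressure[is_pa] / 100.0
    std[is_bar] = gm[is_bar] * pressure[is_bar] / 100.0
    known = is_pa | is_bar | (units == GmUnits.mol_m2_s.value)
    if not known.all():
        bad = sorted(set(units[~known]))
        raise ValueError(f"unknown gm_units value(s): {bad}")
    out["gm"] = std
    return out


# --- PFT assignment ---------------------------------------------------------

#: Default lineage/growth-habit/leaf-longevity -> PFT mapping.  Exposed so
#: deployments can override classifications the metadata leaves ambiguous.
DEFAULT_PFT_RULES: dict[str, object] = {
    "other_lineages": ["moss", "fern_ally"],
    "herb_habits": ["herbaceous_forb", "herbaceous_grass"],
    "annual_longevities": ["annual", "biennial"],
}


def assign_pft(
    lineage: str,
    growth_habit: str,
    leaf_longevity: str,
    pathway: str = "C3",
    rules: Mapping[str, object] | None = None,
) -> PFT:
    """Deterministically map lineage/habit/longevity (+ photosynthetic
    pathway) to a PFT label.

    Herbaceous covers both forbs and grasses; biennial herbs are pooled with
    annuals.  CAM/C4 plants, mosses, fern allies, semideciduous angiosperms
    and deciduous gymnosperms map to ``other`` (carried, not analysed).

    Raises ``ValueError`` on contradictory attribute combinations.
    """
    rules = dict(DEFAULT_PFT_RULES, **(rules or {}))
    lineage, growth_habit = lineage.lower(), growth_habit.lower()
    leaf_longevity = (leaf_longevity or "").lower()
    pathway = pathway.upper()

    if pathway in ("C4", "CAM"):
        return PFT.other
    if pathway != "C3":
        raise ValueError(f"unknown photosynthetic pathway: {pathway!r}")

    herb_habits = set(rules["herb_habits"])
    annual_like = set(rules["annual_longevities"])

    if lineage in set(rules["other_lineages"]):
        return PFT.other
    if lineage == "fern":
        if leaf_longevity in annual_like or growth_habit == "woody":
            raise ValueError(
                f"contradictory attributes: fern with habit={growth_habit!r}, "
                f"longevity={leaf_longevity!r}"
            )
        return PFT.fern
    if lineage == "gymnosperm":
        if growth_habit in herb_habits:
            raise ValueError("contradictory attributes: herbaceous gymnosperm")
        return PFT.evergreen_gymnosperm if leaf_longevity == "evergreen" else PFT.other
    if lineage == "angiosperm":
        if growth_habit == "woody":
            if leaf_longevity in annual_like:
                raise ValueError(
                    "contradictory attributes: woody plant with annual/biennial leaves"
                )
            if leaf_longevity == "evergreen":
                return PFT.evergreen_angiosperm
            if leaf_longevity == "deciduous":
                return PFT.deciduous_angiosperm
            return PFT.other  # semideciduous and unclassified woody habits
        if growth_habit in herb_habits:
            if leaf_longevity in annual_like:
                return PFT.C3_annual_herb
            return PFT.C3_perennial_herb
        raise ValueError(f"unknown growth habit: {growth_habit!r}")
    raise ValueError(f"unknown lineage: {lineage!r}")
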