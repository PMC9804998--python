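"""Synthetic leaf gas-exchange data with the statistical structure the
analysis assumes.

Two layers:

* a minimal steady-state leaf simulator coupling the Rubisco-limited demand
  curve A = Vcmax (Cc - gamma*)/(Cc + Km) - Rd with the CO2 supply chain
  Cc = Ca - A (1/gs + 1/gm).  Solving the pair with measured gs and gm gives
  A_n; solving with 1/gm = 0 (chloroplasts at C_i) gives A_np, the quantity
  needed for the limitation statistic L_m.  Only the Rubisco-limited demand
  is modelled: the compilation this emulates represents light-saturated
  leaves.

* a cohort generator emulating a multi-study trait compilation: PFT-
  stratified records whose expected g_m,25 follows the log-linear anatomical
  model E[g_m,25] = exp(b0 + b1 Sc + b2 Tcw) with multiplicative gamma noise
  (g_m,25 is right-skewed), back-transformed to the measurement temperature,
  pushed through the leaf simulator for A_n/C_i/A_np, and annotated with
  study ids and measurement methods.  ``inject_violations`` plants labelled
  filter violations for quality-control recall tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .limitation import compute_Lm
from .records import GmUnits, Method, PFT
from .temperature import TemperatureResponse, load_response

__all__ = [
    "LeafSimConfig",
    "LeafState",
    "SimulationError",
    "simulate_leaf",
    "simulate_glm_dataset",
    "PFTCohort",
    "CohortConfig",
    "default_cohort_config",
    "generate_cohort",
    "inject_violations",
]

#: Reference 25 degC photosynthesis constants (umol mol-1): CO2 compensation
#: point without day respiration and effective Michaelis constant for CO2.
GAMMA_STAR_25 = 42.75
KM_25 = 717.0


class SimulationError(RuntimeError):
    """The supply-demand system has no physical solution for this config."""


@dataclass(frozen=True)
class LeafSimConfig:
    """One steady-state leaf.

    Vcmax, Rd in umol m-2 s-1; gamma_star, Km, Ca in umol mol-1; gs_c and gm
    in mol m-2 s-1 (``gm=inf`` allowed, giving C_c = C_i).
    """

    Vcmax: float = 80.0
    Rd: float = 1.0
    gamma_star: float = GAMMA_STAR_25
    Km: float = KM_25
    gs_c: float = 0.3
    gm: float = 0.2
    Ca: float = 400.0

    def __post_init__(self):
        for name in ("Vcmax", "Rd", "gamma_star", "Km", "gs_c", "gm", "Ca"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.Ca <= self.gamma_star:
            raise ValueError("Ca must exceed gamma_star")


@dataclass(frozen=True)
class LeafState:
    An: float
    Ci: float
    Cc: float
    Anp: float
    Lm: float


def _solve_supply_demand(cfg: LeafSimConfig, resistance: float) -> tuple[float, float]:
    """Root of the coupled system for total resistance r (m2 s mol-1).

    Substituting Cc = Ca - A r into the demand curve gives
    r A^2 - (Ca + Km + r (Vcmax - Rd)) A + Vcmax (Ca - gamma*) - Rd (Ca + Km) = 0;
    the physical root is the smaller one, with Cc in (0, Ca].
    """
    a = resistance
    b = cfg.Ca + cfg.Km + a * (cfg.Vcmax - cfg.Rd)
    c = cfg.Vcmax * (cfg.Ca - cfg.gamma_star) - cfg.Rd * (cfg.Ca + cfg.Km)
    if a == 0:
        An = c / b
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise SimulationError(f"no real root (supply cannot meet demand): {cfg}")
        An = (b - np.sqrt(disc)) / (2.0 * a)
    Cc = cfg.Ca - An * a
    if not (0.0 < Cc <= cfg.Ca):
        raise SimulationError(f"unphysical chloroplast CO2 ({Cc:.3g}): {cfg}")
    return float(An), float(Cc)


def simulate_leaf(config: LeafSimConfig) -> LeafState:
    """Steady-state A_n, C_i, C_c, A_np and L_m for one leaf.

    A_n uses the full resistance chain 1/gs + 1/gm; A_np repeats the solve
    with 1/gm = 0 (infinite mesophyll conductance, stomata as measured).
    """
    r_m = 0.0 if np.isinf(config.gm) else 1.0 / config.gm
    An, Cc = _solve_supply_demand(config, 1.0 / config.gs_c + r_m)
    Anp, _ = _solve_supply_demand(config, 1.0 / config.gs_c)
    Ci = config.Ca - An / config.gs_c
    return LeafState(An=An, Ci=float(Ci), Cc=Cc, Anp=Anp, Lm=compute_Lm(An, Anp))


# --- trait-linked g_m cohorts ----------------------------------------------

#: Table-style all-PFT anatomical coefficients on the exp scale:
#: (exp(b0) in mol m-2 s-1, exp(b1) per unit Sc, exp(b2) per um Tcw).
DEFAULT_EXP_BETAS = (0.128, 1.050, 0.096)


def simulate_glm_dataset(
    n: int,
    exp_betas: tuple[float, float, float] = DEFAULT_EXP_BETAS,
    gamma_shape: float = 5.0,
    sc_range: tuple[float, float] = (5.0, 40.0),
    tcw_range: tuple[float, float] = (0.05, 0.6),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw (g_m,25, Sc, Tcw) from the log-linear anatomical model.

    Sc ~ U(sc_range) (m2 m-2), Tcw ~ U(tcw_range) (um);
    g_m,25 ~ Gamma(shape, scale = E[g_m,25]/shape) so that the mean equals
    exp(b0) exp(b1)^Sc exp(b2)^Tcw exactly.
    """
    rng = np.random.default_rng(rng)
    b0, b1, b2 = np.log(exp_betas)
    Sc = rng.uniform(*sc_range, n)
    Tcw = rng.uniform(*tcw_range, n)
    mean = np.exp(b0 + b1 * Sc + b2 * Tcw)
    gm25 = rng.gamma(gamma_shape, mean / gamma_shape)
    return pd.DataFrame({"gm_25": gm25, "Sc": Sc, "Tcw": Tcw})


@dataclass(frozen=True)
class PFTCohort:
    """Sampling ranges for one PFT stratum (uniform draws)."""

    pft: PFT
    n: int
    sc_range: tuple[float, float]
    tcw_range: tuple[float, float]
    vcmax_range: tuple[float, float] = (40.0, 100.0)
    T_range: tuple[float, float] = (20.0, 30.0)


@dataclass
class CohortConfig:
    """Configuration of a synthetic multi-study compilation."""

    pfts: list[PFTCohort]
    exp_betas: tuple[float, float, float] = DEFAULT_EXP_BETAS
    gamma_shape: float = 5.0
    Ca: float = 400.0
    PPFD: float = 1500.0
    rows_per_study: int = 6
    method_probs: dict[str, float] = field(
        default_factory=lambda: {
            "isotope": 0.4, "fluorescence": 0.4, "curve_fitting": 0.15, "other": 0.05,
        }
    )
    violation_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    tresponse: str = "tobacco"

    def __post_init__(self):
        for crit, rate in self.violation_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"violation rate for {crit!r} outside [0, 1]")
        if any(spec.n < 1 for spec in self.pfts):
            raise ValueError("each PFT stratum needs n >= 1")


def default_cohort_config(seed: int = 0, n_per_pft: int = 60) -> CohortConfig:
    """A six-PFT cohort whose trait ranges produce the observed ordering of
    g_m,25 medians (annual herbs highest ... ferns lowest)."""
    ranges = {
        PFT.fern: ((5, 15), (0.30, 0.60), (30, 70)),
        PFT.evergreen_gymnosperm: ((8, 20), (0.25, 0.50), (30, 80)),
        PFT.evergreen_angiosperm: ((10, 25), (0.20, 0.45), (35, 90)),
        PFT.deciduous_angiosperm: ((12, 28), (0.15, 0.35), (40, 100)),
        PFT.C3_perennial_herb: ((15, 32), (0.10, 0.25), (50, 110)),
        PFT.C3_annual_herb: ((18, 40), (0.05, 0.20), (60, 130)),
    }
    pfts = [
        PFTCohort(pft=p, n=n_per_pft, sc_range=sc, tcw_range=tcw, vcmax_range=vc)
        for p, (sc, tcw, vc) in ranges.items()
    ]
    return CohortConfig(pfts=pfts, seed=seed)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a synthetic compilation in the canonical CSV schema.

    Per stratum: draw anatomy (Sc, Tcw), set E[g_m,25] from the log-linear
    model with gamma multiplicative noise, back-transform to the drawn
    measurement temperature via the inverse temperature response, then run
    the leaf simulator for A_n, C_i, C_c, A_np and L_m.  Reproducible:
    identical seeds give identical frames.  Ground-truth columns are prefixed
    ``true_``.
    """
    rng = np.random.default_rng(config.seed)
    resp = load_response(config.tresponse)
    methods = sorted(config.method_probs)
    probs = np.array([config.method_probs[m] for m in methods], dtype=float)
    probs = probs / probs.sum()

    frames = []
    study_counter = 0
    for spec in config.pfts:
        base = simulate_glm_dataset(
            spec.n, config.exp_betas, config.gamma_shape,
            spec.sc_range, spec.tcw_range, rng,
        )
        T = rng.uniform(*spec.T_range, spec.n)
        f_T = resp.factor(T)
        gm = base["gm_25"].to_numpy() * f_T  # value at measurement temperature
        vcmax = rng.uniform(*spec.vcmax_range, spec.n)
        gs = np.clip(gm * rng.uniform(1.2, 2.5, spec.n), 0.05, 1.5)

        An = np.empty(spec.n)
        Ci = np.empty(spec.n)
        Cc = np.empty(spec.n)
        Anp = np.empty(spec.n)
        Lm = np.empty(spec.n)
        for i in range(spec.n):
            leaf = simulate_leaf(
                LeafSimConfig(
                    Vcmax=vcmax[i], gs_c=gs[i], gm=gm[i], Ca=config.Ca,
                )
            )
            An[i], Ci[i], Cc[i], Anp[i], Lm[i] = (
                leaf.An, leaf.Ci, leaf.Cc, leaf.Anp, leaf.Lm,
            )

        n_studies = max(1, round(spec.n / config.rows_per_study))
        study_ids = rng.integers(0, n_studies, spec.n) + study_counter
        study_counter += n_studies

        sm_ratio = rng.uniform(0.6, 0.9, spec.n)  # Sc/Sm, so Sc <= Sm
        n_area = np.clip(1.0 + 3.0 * base["gm_25"] + rng.normal(0, 0.3, spec.n), 0.3, None)
        k_area = np.clip(0.5 + 2.0 * base["gm_25"] + rng.normal(0, 0.3, spec.n), 0.1, None)

        frames.append(
            pd.DataFrame(
                {
                    "study_id": [f"study_{s:03d}" for s in study_ids],
                    "species": [f"sp_{spec.pft.value}_{i:03d}" for i in range(spec.n)],
                    "pft": spec.pft.value,
                    "gm_value": gm,
                    "gm_units": GmUnits.mol_m2_s.value,
                    "method": rng.choice(methods, spec.n, p=probs),
                    "T_meas": T,
                    "PPFD": config.PPFD,
                    "CO2_meas": config.Ca,
                    "pressure": 100.0,
                    "An": An,
                    "gs_c": gs,
                    "Ci": Ci,
                    "Ca": config.Ca,
                    "Anp": Anp,
                    "already_standardised": False,
                    "Sc": base["Sc"],
                    "Sm": base["Sc"] / sm_ratio,
                    "Tcw": base["Tcw"],
                    "N_area": n_area,
                    "K_area": k_area,
                    "true_gm_25": base["gm_25"],
                    "true_Lm": Lm,
                    "true_Cc": Cc,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if config.violation_rates:
        out = inject_violations(out, config.violation_rates, seed=config.seed + 1)
    return out


_VIOLATION_CRITERIA = ("temperature", "irradiance", "co2", "drawdown", "outlier_extreme")


def inject_violations(
    df: pd.DataFrame,
    rates: dict[str, float],
    seed: int,
    herbaceous_extreme: float = 2.0,
    woody_extreme: float = 1.0,
) -> pd.DataFrame:
    """Plant labelled filter violations into a cohort.

    Each selected row is modified to violate exactly one criterion:
    temperature -> T_meas = 10 degC; irradiance -> PPFD = 200; co2 ->
    CO2_meas = 600; drawdown -> g_m lowered so A_n/g_m = 400 umol mol-1;
    outlier_extreme -> T_meas = 25 and g_m,25 = 1.25x the growth-form
    extreme threshold (A_n rescaled to keep the drawdown criterion clean).
    Ground truth goes into ``planted_violation``; rows are chosen disjointly
    across criteria.  A criterion whose rate yields zero rows warns.
    """
    unknown = set(rates) - set(_VIOLATION_CRITERIA)
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    out = df.copy()
    if "planted_violation" not in out.columns:
        out["planted_violation"] = ""
    rng = np.random.default_rng(seed)
    available = list(out.index[out["planted_violation"] == ""])
    rng.shuffle(available)

    herbaceous = {PFT.C3_perennial_herb.value, PFT.C3_annual_herb.value}
    cursor = 0
    for crit in _VIOLATION_CRITERIA:  # fixed order for reproducibility
        rate = rates.get(crit, 0.0)
        k = int(round(rate * len(df)))
        if rate > 0 and k == 0:
            warnings.warn(f"rate for {crit!r} too small: zero rows planted", stacklevel=2)
            continue
        rows = available[cursor:cursor + k]
        cursor += k
        if crit == "temperature":
            out.loc[rows, "T_meas"] = 10.0
        elif crit == "irradiance":
            out.loc[rows, "PPFD"] = 200.0
        elif crit == "co2":
            out.loc[rows, "CO2_meas"] = 600.0
        elif crit == "drawdown":
            an = pd.to_numeric(out.loc[rows, "An"], errors="coerce")
            out.loc[rows, "gm_value"] = an / 400.0
        else:  # outlier_extreme
            thr = np.where(
                out.loc[rows, "pft"].astype(str).isin(herbaceous),
                herbaceous_extreme, woody_extreme,
            )
            out.loc[rows, "T_meas"] = 25.0  # f(25)=1, so gm_value == gm_25
            out.loc[rows, "gm_value"] = thr * 1.25
            out.loc[rows, "An"] = thr * 1.25 * 100.0  # drawdown stays at 100
        out.loc[rows, "planted_violation"] = crit
    return out
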