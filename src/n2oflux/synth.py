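"""Synthetic microcosm-study generator.

Produces complete, internally consistent studies with the statistical
structure the analysis pipeline assumes: a 3 fertilization x 3 temperature x
4 replicate factorial, net-rate monitoring on days 1-30, three-level
acetylene campaigns on days 3/15/30, ammonium/nitrate trajectories, T-RFLP
peak tables for the two nosZ clades, and qPCR Cq tables — plus a truth table
the analysis stages never read.

The generator is phenomenological, not mechanistic.  Cell-level true gross
production P and true consumption ratio rho = C/P are looked up from
calibration tables; expected net rates per acetylene level follow

    0 Pa:    P - C
    10 Pa:   P * (1 - eta_nit * f_nit) - C
    10 kPa:  P * (1 - eta_nit * f_nit) - (1 - eta_cons) * C

where f_nit is the autotrophic-nitrification fraction of production and
eta_nit / eta_cons are the inhibition efficiencies of the 10 Pa and 10 kPa
treatments (1 = complete inhibition, the method's nominal assumption and the
packaged default).  A lognormal replicate effect shared by a replicate's
bottles multiplies (P, C) jointly; independent Gaussian measurement noise is
added per bottle-observation; headspace concentrations are then emitted by
inverting the flux calculation exactly.

The packaged default scenario is calibrated so that treatment-mean
consumption/production ratios are CT 0.63, NPK 0.48, MNPK 0.75 (grand mean
0.62, span 0.48-0.75) and the estimated production-consumption correlation
within a regime is ~0.98.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    Arm, C2H2Level, Fertilization, Scenario,
    CAMPAIGN_DAYS, NET_MONITORING_DAYS, TEMPERATURES_C, enumerate_design,
)
from .fluxcalc import mass_to_conc
from .qpcr import StandardCurve, cq_from_copies

__all__ = [
    "ProcessModel", "SyntheticStudy",
    "paper_default_scenario", "generate_study", "generate_null_study",
]

FERTS = ("CT", "NPK", "MNPK")
COMMUNITY_DAYS = (0, 3, 15, 30)
GENES = ("nosZI", "nosZII")

# --- calibration tables of the packaged default scenario --------------------
# True gross production, ng N2O-N g-1 dry soil d-1, per (fert, day, temp).
# Patterns encoded: rates decline over the incubation everywhere; CT
# production is temperature-enhanced early and trendless late; NPK production
# rises steeply with temperature at days 15 and 30; MNPK peaks at 25 degC at
# every sampling time.
_P_TABLE = {
    "CT":   {3: (6.0, 10.0, 16.0), 15: (4.5, 5.0, 4.2), 30: (2.2, 2.0, 1.8)},
    "NPK":  {3: (15.0, 24.0, 38.0), 15: (8.0, 13.0, 22.0), 30: (3.5, 6.0, 11.0)},
    "MNPK": {3: (12.0, 20.0, 14.0), 15: (6.0, 10.0, 7.0), 30: (2.5, 4.5, 3.0)},
}
# True consumption/production ratio rho per (fert, day, temp).  CT consumption
# rises with temperature at day 3 and falls at day 30; NPK consumption is flat
# across temperature at days 15/30 (so rho falls as production rises); MNPK
# consumption peaks at 25 degC.  Treatment means: CT 0.630, NPK 0.482,
# MNPK 0.748; grand mean 0.620.
_RHO_TABLE = {
    "CT":   {3: (0.55, 0.63, 0.70), 15: (0.62, 0.64, 0.62), 30: (0.72, 0.63, 0.56)},
    "NPK":  {3: (0.61, 0.53, 0.46), 15: (0.75, 0.46, 0.27), 30: (0.66, 0.385, 0.21)},
    "MNPK": {3: (0.70, 0.78, 0.72), 15: (0.72, 0.80, 0.75), 30: (0.73, 0.78, 0.75)},
}

# Nutrient anchors: initial NH4+ (ug g-1) per fert, its fractional decline by
# day 30, initial NO3- and its 30-day net build-up (ug g-1).
_NH4_0 = {"CT": 1.2, "NPK": 13.05, "MNPK": 3.2}
_NH4_DECLINE = {"CT": 0.80, "NPK": 0.24, "MNPK": 0.36}
_NO3_0 = {"CT": 20.0, "NPK": 35.0, "MNPK": 35.0}
_NO3_DELTA = {"CT": 68.0, "NPK": 101.0, "MNPK": 90.0}

# qPCR: standard-curve parameters per gene (slope chosen to give the
# conventional 87.0 % / 90.2 % amplification efficiencies) and abundance
# effect tables (copies per g dry soil).
_CURVES = {"nosZI": (-3.6790, 38.5), "nosZII": (-3.5815, 37.9)}
_ABUND_BASE = {"nosZI": 2.0e7, "nosZII": 5.0e7}
_ABUND_FERT = {
    "nosZI": {"CT": 1.0, "NPK": 0.40, "MNPK": 1.10},
    "nosZII": {"CT": 1.0, "NPK": 0.25, "MNPK": 1.05},
}
_ABUND_TIME = {
    "nosZI": {0: 1.0, 3: 1.1, 15: 0.5, 30: 0.9},     # dip at day 15, recovery
    "nosZII": {0: 1.0, 3: 1.1, 15: 0.6, 30: 0.35},   # monotone decline after day 3
}
# temperature slope per 10 degC, by gene and day (nosZII: none)
_ABUND_TEMP = {
    "nosZI": {0: 0.0, 3: 0.20, 15: 0.20, 30: -0.15},
    "nosZII": {0: 0.0, 3: 0.0, 15: 0.0, 30: 0.0},
}

_N_BINS = 40
_EFFECT_SEED = 202007  # fixed scenario constant: effect directions, bin layout


@dataclass
class ProcessModel:
    """Phenomenological truth model for one synthetic study."""

    production: dict = field(default_factory=lambda: _P_TABLE)
    rho: dict = field(default_factory=lambda: _RHO_TABLE)
    f_nit: float = 0.05
    f_nit_overrides: dict = field(
        default_factory=lambda: {("NPK", 15, 35): 0.35}  # (fert, day, temp)
    )
    eta_nit: float = 1.0
    eta_cons: float = 1.0
    replicate_cv: float = 0.15
    rho_rep_cv: float = 0.15         # replicate heterogeneity of the consumption fraction
    noise_sd: float = 0.3            # absolute noise floor, rate units
    noise_rel: float = 0.10          # proportional measurement error (GC-like)
    ambient_ppbv: float = 330.0
    ambient_jitter_ppbv: float = 4.0
    # community effect strengths (log-scale sd of level shifts)
    community_effects: dict = field(default_factory=lambda: {
        "nosZI": {"fertilization": 0.9, "time": 0.30, "temperature": 0.15},
        "nosZII": {"fertilization": 0.08, "time": 0.70, "temperature": 0.25},
    })
    dirichlet_concentration: float = 50.0
    abundance_cv: float = 0.25
    cq_sd: float = 0.08
    elution_volume_ul: float = 50.0
    dilution: float = 20.0
    template_volume_ul: float = 2.0
    extraction_mass_g: float = 0.5
    scenario: Scenario = field(default_factory=Scenario)

    def __post_init__(self) -> None:
        for frac in (self.f_nit, self.eta_nit, self.eta_cons):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for fert in self.production:
            for day, trip in self.production[fert].items():
                if any(p <= 0 for p in trip):
                    raise ValueError("true production must be positive")
                if any(not 0 <= r < 1 for r in self.rho[fert][day]):
                    raise ValueError("true consumption ratio must lie in [0, 1)")

    def cell_f_nit(self, fert: str, day: int, temp: int) -> float:
        return self.f_nit_overrides.get((fert, day, temp), self.f_nit)

    def true_production(self, fert: str, day: float, temp: int) -> float:
        """Log-linear interpolation over campaign days (extrapolated before day 3)."""
        ti = TEMPERATURES_C.index(temp)
        days = np.array(sorted(self.production[fert]))
        logp = np.log([self.production[fert][d][ti] for d in days])
        if day <= days[0]:  # back-extrapolate with the first segment's slope
            slope = (logp[1] - logp[0]) / (days[1] - days[0])
            return float(np.exp(logp[0] + slope * (day - days[0])))
        return float(np.exp(np.interp(day, days, logp)))

    def true_rho(self, fert: str, day: float, temp: int) -> float:
        ti = TEMPERATURES_C.index(temp)
        days = np.array(sorted(self.rho[fert]))
        vals = np.array([self.rho[fert][d][ti] for d in days])
        return float(np.interp(day, days, vals))


@dataclass
class SyntheticStudy:
    """All generated tables of one synthetic study."""

    seed: int
    config: dict
    design: pd.DataFrame
    gas: pd.DataFrame
    truth: pd.DataFrame
    nutrients: pd.DataFrame
    peaks: dict[str, pd.DataFrame]       # gene -> sample_id, fragment_bp, height
    community_meta: pd.DataFrame
    standards: pd.DataFrame
    qpcr: pd.DataFrame

    def write_csvs(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "design.csv": self.design, "gas.csv": self.gas,
            "truth.csv": self.truth, "nutrients.csv": self.nutrients,
            "community_meta.csv": self.community_meta,
            "standards.csv": self.standards, "qpcr.csv": self.qpcr,
        }
        for gene, frame in self.peaks.items():
            tables[f"peaks_{gene}.csv"] = frame
        for name, frame in tables.items():
            path = outdir / name
            frame.to_csv(path, index=False)
            paths[name] = path
        (outdir / "config.json").write_text(json.dumps(self.config, indent=2, default=str))
        return paths

    def csv_bytes(self) -> bytes:
        """Concatenated CSV bytes of every table (determinism checks)."""
        buf = io.BytesIO()
        for name in ("design", "gas", "truth", "nutrients", "community_meta",
                     "standards", "qpcr"):
            getattr(self, name).to_csv(buf, index=False)
        for gene in sorted(self.peaks):
            self.peaks[gene].to_csv(buf, index=False)
        return buf.getvalue()


def paper_default_scenario() -> ProcessModel:
    """The packaged default scenario (calibration tables above)."""
    return ProcessModel()


def generate_null_study(seed: int, **kwargs) -> SyntheticStudy:
    """Study with all treatment effects zeroed (type-I-error calibration).

    Every cell shares the same true production (8 ng N g-1 d-1), the same
    consumption ratio (0.5), one community distribution and one abundance
    level, so any detected factor effect is a false positive.
    """
    flat_p = {f: {d: (8.0, 8.0, 8.0) for d in CAMPAIGN_DAYS} for f in FERTS}
    flat_rho = {f: {d: (0.5, 0.5, 0.5) for d in CAMPAIGN_DAYS} for f in FERTS}
    model = ProcessModel(
        production=flat_p, rho=flat_rho, f_nit_overrides={},
        community_effects={
            g: {"fertilization": 0.0, "time": 0.0, "temperature": 0.0} for g in GENES
        },
    )
    # abundance effects are neutralized at draw time via the null flag
    return generate_study(model, seed=seed, _null_abundance=True, **kwargs)


def _expected_rates(model: ProcessModel, p: float, c: float, f_nit: float):
    """Expected net rates (r0, r10, r10k) for true (P, C) in one bottle set."""
    inhibited_p = p * (1.0 - model.eta_nit * f_nit)
    return (
        p - c,
        inhibited_p - c,
        inhibited_p - (1.0 - model.eta_cons) * c,
    )


def generate_study(
    model: ProcessModel | None = None,
    seed: int = 0,
    replicates: int = 4,
    _null_abundance: bool = False,
) -> SyntheticStudy:
    """Draw one complete synthetic study.  Deterministic given ``seed``."""
    model = model or paper_default_scenario()
    rng = np.random.default_rng(seed)
    scen = model.scenario
    headspace_l = scen.headspace_volume_l
    dry_mass = scen.soil_dry_mass_g

    # --- design ------------------------------------------------------------
    net_units = enumerate_design(3, 3, replicates, (C2H2Level.P0,),
                                 NET_MONITORING_DAYS, Arm.NET_MONITORING)
    campaign_units = enumerate_design(3, 3, replicates,
                                      (C2H2Level.P10, C2H2Level.KP10),
                                      CAMPAIGN_DAYS, Arm.C2H2_CAMPAIGN)
    from .design import design_to_frame
    design = pd.concat(
        [design_to_frame(net_units), design_to_frame(campaign_units)],
        ignore_index=True,
    )

    # persistent replicate effect, shared across days and C2H2 levels
    sigma = np.sqrt(np.log(1.0 + model.replicate_cv**2))
    rep_effect = {
        (f, t, r): float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
        for f in FERTS for t in TEMPERATURES_C for r in range(1, replicates + 1)
    }

    # --- gas observations ---------------------------------------------------
    rows = []
    truth_rows = []
    for f in FERTS:
        for t in TEMPERATURES_C:
            for day in NET_MONITORING_DAYS:
                p = model.true_production(f, day, t)
                rho = model.true_rho(f, day, t)
                c = rho * p
                fn = model.cell_f_nit(f, day, t) if day in CAMPAIGN_DAYS else model.f_nit
                r0_exp, r10_exp, r10k_exp = _expected_rates(model, p, c, fn)
                if day in CAMPAIGN_DAYS:
                    truth_rows.append({
                        "fertilization": f, "temperature_C": t, "day": day,
                        "true_production": p, "true_consumption": c,
                        "true_net": p - c, "true_rho": rho, "f_nit": fn,
                        "exp_r0": r0_exp, "exp_r10": r10_exp, "exp_r10k": r10k_exp,
                    })
                levels = (
                    [("P0", r0_exp, "net_monitoring"),
                     ("P10", r10_exp, "c2h2_campaign"),
                     ("KP10", r10k_exp, "c2h2_campaign")]
                    if day in CAMPAIGN_DAYS
                    else [("P0", r0_exp, "net_monitoring")]
                )
                for r in range(1, replicates + 1):
                    u = rep_effect[(f, t, r)]
                    # bottle-to-bottle heterogeneity of the consumption
                    # fraction (anaerobic microsites); shared by the
                    # replicate's three C2H2 bottles, mean-one lognormal
                    if model.rho_rep_cv > 0:
                        s_r = np.sqrt(np.log(1.0 + model.rho_rep_cv**2))
                        jit = float(np.exp(rng.normal(-s_r**2 / 2, s_r)))
                        c_rep = min(rho * jit, 0.97) * p
                    else:
                        c_rep = c
                    rep_rates = dict(zip(
                        ("P0", "P10", "KP10"),
                        _expected_rates(model, p, c_rep, fn),
                    ))
                    for level, exp_rate, arm in levels:
                        rate = u * rep_rates[level]
                        sd = max(model.noise_sd, model.noise_rel * abs(rate))
                        if sd > 0:
                            rate += rng.normal(0.0, sd)
                        t0 = model.ambient_ppbv + (
                            rng.normal(0.0, model.ambient_jitter_ppbv)
                            if model.ambient_jitter_ppbv > 0 else 0.0
                        )
                        delta_mass = rate * dry_mass * (scen.enclosure_hours / 24.0)
                        t24 = t0 + mass_to_conc(delta_mass, headspace_l, t + 273.15)
                        rows.append({
                            "fertilization": f, "temperature_C": t, "replicate": r,
                            "c2h2_level": level, "day": day, "arm": arm,
                            "conc_t0_ppbv": t0, "conc_t24_ppbv": t24,
                            "headspace_volume_L": headspace_l,
                            "pressure_Pa": 101325.0,
                        })
    gas = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)

    # --- nutrients ----------------------------------------------------------
    nutrients = _generate_nutrients(rng, replicates)

    # --- community profiles -------------------------------------------------
    peaks, community_meta = _generate_community(model, rng, replicates)

    # --- qPCR ---------------------------------------------------------------
    standards, qpcr = _generate_qpcr(model, rng, replicates, _null_abundance)

    config = {
        "seed": seed, "replicates": replicates,
        "noise_sd": model.noise_sd, "replicate_cv": model.replicate_cv,
        "eta_nit": model.eta_nit, "eta_cons": model.eta_cons,
        "f_nit": model.f_nit,
        "scenario": asdict(scen) | {"design": None},
    }
    return SyntheticStudy(seed, config, design, gas, truth, nutrients,
                          peaks, community_meta, standards, qpcr)


def _generate_nutrients(rng: np.random.Generator, replicates: int) -> pd.DataFrame:
    """First-order NH4+ decay and saturating NO3- accumulation (cosmetic)."""
    rows = []
    for f in FERTS:
        k_nh4 = -np.log(1.0 - _NH4_DECLINE[f]) / 30.0
        # day-0 baseline bottles precede temperature assignment
        for r in range(1, replicates + 1):
            noise = np.exp(rng.normal(0.0, 0.05, size=2))
            rows.append({
                "fertilization": f, "temperature_C": None, "replicate": r,
                "day": 0, "nh4_ug_g": _NH4_0[f] * noise[0],
                "no3_ug_g": _NO3_0[f] * noise[1],
            })
        for t in TEMPERATURES_C:
            temp_scale = 1.0 + 0.10 * (t - 25) / 10.0  # mild T enhancement
            for day in CAMPAIGN_DAYS:
                nh4 = _NH4_0[f] * np.exp(-k_nh4 * day)
                no3 = _NO3_0[f] + _NO3_DELTA[f] * temp_scale * (
                    (1 - np.exp(-0.08 * day)) / (1 - np.exp(-0.08 * 30.0))
                )
                for r in range(1, replicates + 1):
                    noise = np.exp(rng.normal(0.0, 0.05, size=2))
                    rows.append({
                        "fertilization": f, "temperature_C": t, "replicate": r,
                        "day": day, "nh4_ug_g": nh4 * noise[0],
                        "no3_ug_g": no3 * noise[1],
                    })
    return pd.DataFrame(rows)


def _community_design(replicates: int) -> list[tuple[str, int | None, int, int]]:
    cells = [("%s" % f, None, 0, r) for f in FERTS for r in range(1, replicates + 1)]
    cells += [
        (f, t, d, r)
        for f in FERTS for t in TEMPERATURES_C for d in CAMPAIGN_DAYS
        for r in range(1, replicates + 1)
    ]
    return cells


def _generate_community(model: ProcessModel, rng: np.random.Generator,
                        replicates: int):
    """Dirichlet community profiles rendered as T-RFLP peak tables.

    Bin centre lengths and effect direction vectors are fixed scenario
    constants (drawn from an internal fixed seed), so different study seeds
    share one underlying community landscape and differ only in sampling.
    """
    const = np.random.default_rng(_EFFECT_SEED)
    centers = {
        g: np.sort(const.uniform(60.0, 560.0, size=_N_BINS).round(1))
        for g in GENES
    }
    base = {g: np.sort(const.dirichlet(np.full(_N_BINS, 1.2)))[::-1] for g in GENES}
    directions = {
        g: {
            "fertilization": {f: const.normal(0, 1, _N_BINS) for f in FERTS},
            "time": {"early": const.normal(0, 1, _N_BINS),
                     "late": const.normal(0, 1, _N_BINS)},
            "temperature": const.normal(0, 1, _N_BINS),
        }
        for g in GENES
    }

    peaks: dict[str, pd.DataFrame] = {}
    meta_rows = []
    design = _community_design(replicates)
    for gene in GENES:
        eff = model.community_effects[gene]
        rows = []
        for f, t, d, r in design:
            sid = f"{f}_T{t if t is not None else 'NA'}_d{d}_r{r}"
            if gene == GENES[0]:
                meta_rows.append({
                    "sample_id": sid, "fertilization": f, "temperature_C": t,
                    "day": d, "replicate": r,
                })
            shift = eff["fertilization"] * directions[gene]["fertilization"][f]
            shift = shift + eff["time"] * directions[gene]["time"][
                "early" if d <= 3 else "late"
            ] * (1.0 if d in (0, 30) else 0.6)
            if t is not None:
                shift = shift + eff["temperature"] * directions[gene]["temperature"] \
                    * (t - 25) / 10.0
            p_cell = base[gene] * np.exp(shift)
            p_cell /= p_cell.sum()
            rel = rng.dirichlet(model.dirichlet_concentration * p_cell)
            total = np.exp(rng.normal(np.log(5.0e4), 0.3))
            jitter = np.clip(rng.normal(0.0, 0.2, _N_BINS), -0.6, 0.6)
            for b in range(_N_BINS):
                h = rel[b] * total
                if h < 1.0:  # below detection
                    continue
                rows.append({
                    "sample_id": sid,
                    "fragment_bp": round(float(centers[gene][b] + jitter[b]), 2),
                    "height": round(float(h), 1),
                })
            # primer-dimer noise below the 50 bp cutoff
            for _ in range(2):
                rows.append({
                    "sample_id": sid,
                    "fragment_bp": round(float(rng.uniform(25.0, 48.0)), 2),
                    "height": round(float(np.exp(rng.normal(np.log(800), 0.4))), 1),
                })
        peaks[gene] = pd.DataFrame(rows)
    return peaks, pd.DataFrame(meta_rows)


def _standard_curves(model: ProcessModel) -> dict[str, StandardCurve]:
    return {
        g: StandardCurve(
            gene=g, slope=_CURVES[g][0], intercept=_CURVES[g][1], r_squared=1.0,
            efficiency=10.0 ** (-1.0 / _CURVES[g][0]) - 1.0, log10_range=(3.0, 8.0),
        )
        for g in GENES
    }


def _generate_qpcr(model: ProcessModel, rng: np.random.Generator,
                   replicates: int, null: bool):
    curves = _standard_curves(model)
    std_rows = []
    for g in GENES:
        for log_c in range(3, 9):
            for _ in range(3):
                std_rows.append({
                    "gene": g, "log10_copies": float(log_c),
                    "cq": round(cq_from_copies(10.0**log_c, curves[g])
                                + rng.normal(0.0, 0.05), 3),
                })
    standards = pd.DataFrame(std_rows)

    qpcr_rows = []
    scale = (model.extraction_mass_g * model.template_volume_ul
             / (model.dilution * model.elution_volume_ul))
    for f, t, d, r in _community_design(replicates):
        sid = f"{f}_T{t if t is not None else 'NA'}_d{d}_r{r}"
        for g in GENES:
            mu = _ABUND_BASE[g]
            if not null:
                mu *= _ABUND_FERT[g][f] * _ABUND_TIME[g][d]
                if t is not None:
                    mu *= np.exp(_ABUND_TEMP[g][d] * (t - 25) / 10.0)
            copies_g = float(np.exp(rng.normal(
                np.log(mu) - 0.5 * np.log(1 + model.abundance_cv**2),
                np.sqrt(np.log(1 + model.abundance_cv**2)),
            )))
            copies_reaction = copies_g * scale
            for tech in range(1, 4):
                qpcr_rows.append({
                    "sample_id": sid, "gene": g,
                    "fertilization": f, "temperature_C": t, "day": d,
                    "replicate": r, "tech_rep": tech,
                    "cq": round(cq_from_copies(copies_reaction, curves[g])
                                + rng.normal(0.0, model.cq_sd), 3),
                })
    return standards, pd.DataFrame(qpcr_rows)
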