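"""Synthetic compound/xenograft/study cohort generator.

Emulates the statistical structure of a pre-clinical MAPK-inhibitor cohort:
86 xenograft studies across 6 xenograft models and 12 compounds, unbound
IC50 0.2-700 nM (median 7.7), total interval AUC 1.84-4141 nM*h (median 55),
unbound fraction 0.04-2.3% (median 0.53%), at least 14 days of qd or bid
dosing.  Compound-level quantities are drawn from truncated log-normals
calibrated by their medians (truncation by rejection); xenograft g/d ratios
are uniform on the pre-clinical responder range, and study doses are placed
log-uniformly around each compound-xenograft pair's closed-form stasis dose
so the realised coverages span the whole TGI sigmoid.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import DomainError, SchemaError
from .pk import DoseRegimen
from .stasis import stasis_dose
from .tumour import DEFAULT_R0, DrugEffect, Xenograft, simulate_study

__all__ = [
    "GeneratorConfig",
    "generate_compounds",
    "generate_xenografts",
    "generate_studies",
    "generate_cohort",
    "write_records",
    "read_records",
    "STUDY_COLUMNS",
]

STUDY_COLUMNS = [
    "study_id",
    "compound_id",
    "xenograft_id",
    "dose_mgkg",
    "tau_h",
    "n_intervals",
    "ic50_ub_nM",
    "hill",
    "ptr",
    "auc_dn_ub",
    "fu",
    "coverage_cavg_over_ic50",
    "tgi_percent",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator calibration.

    Medians and ranges mirror the emulated cohort; log-sd values and the
    magnitude conventions (reference dose, absolute g range, R0) are
    generator choices documented in the methods note.
    """

    n_compounds: int = 12
    n_xenografts: int = 6
    n_studies: int = 86
    ic50_median: float = 7.7  # nM, unbound
    ic50_bounds: tuple[float, float] = (0.2, 700.0)
    ic50_log_sd: float = 1.5
    auc_total_median: float = 55.0  # nM*h, total drug at the reference dose
    auc_total_bounds: tuple[float, float] = (1.84, 4141.0)
    auc_total_log_sd: float = 1.5
    fu_median: float = 0.0053
    fu_bounds: tuple[float, float] = (0.0004, 0.023)
    fu_log_sd: float = 0.8
    ptr_bounds: tuple[float, float] = (10.0, 300.0)  # log-uniform, at tau = 24 h
    gd_bounds: tuple[float, float] = (0.3, 0.7)  # uniform
    g_bounds: tuple[float, float] = (0.004, 0.008)  # mm/h, uniform
    r0: float = DEFAULT_R0
    study_days: int = 14
    reference_dose: float = 10.0  # mg/kg, defines dose-normalised AUC
    dose_factor_bounds: tuple[float, float] = (0.03, 30.0)  # log-uniform around stasis
    tgi_noise_sd: float = 10.0  # additive Gaussian, TGI units
    hill: float = 1.0
    bid_fraction: float = 0.5  # probability a study uses bid (tau = 12 h)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_xenografts", "n_studies"):
            if getattr(self, name) < 1:
                raise DomainError(f"{name} must be >= 1")
        for name, med in (
            ("ic50", self.ic50_median),
            ("auc_total", self.auc_total_median),
            ("fu", self.fu_median),
        ):
            lo, hi = getattr(self, f"{name}_bounds")
            if not (0 < lo <= med <= hi):
                raise DomainError(
                    f"{name} truncation bounds {lo, hi} must straddle the median {med}"
                )
        if not (1 <= self.ptr_bounds[0] <= self.ptr_bounds[1]):
            raise DomainError("ptr bounds must satisfy 1 <= lo <= hi")
        if not (0 < self.gd_bounds[0] <= self.gd_bounds[1] < 1):
            raise DomainError("gd bounds must lie inside (0, 1)")
        if self.tgi_noise_sd < 0:
            raise DomainError("tgi_noise_sd must be >= 0")


def _truncated_lognormal(
    rng: np.random.Generator,
    median: float,
    log_sd: float,
    bounds: tuple[float, float],
    n: int,
) -> np.ndarray:
    """Log-normal truncated to bounds with the truncated median calibrated.

    Asymmetric truncation shifts the median of a plain rejection sampler, so
    the underlying location mu is solved (bisection) such that the truncated
    distribution's median equals ``median`` exactly; sampling is then by
    rejection against the bounds.
    """
    if log_sd == 0.0:
        return np.full(n, median)
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    target = math.log(median)

    def trunc_median(mu: float) -> float:
        a, b = norm.cdf((lo - mu) / log_sd), norm.cdf((hi - mu) / log_sd)
        return mu + log_sd * norm.ppf((a + b) / 2.0)

    mu = brentq(lambda m: trunc_median(m) - target, lo, hi, xtol=1e-12)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = np.exp(rng.normal(mu, log_sd, size=2 * (n - filled) + 16))
        keep = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_compounds(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-compound table: IC50_ub, fu, PTR and dose-normalised unbound AUC.

    The dose-normalised unbound AUC derives from the sampled total interval
    AUC at the reference dose and the unbound fraction:
    auc_dn_ub = AUC_total * fu / reference_dose (dose linearity is exact in
    the generator).  PTR is quoted at tau = 24 h.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_compounds
    ic50 = _truncated_lognormal(rng, config.ic50_median, config.ic50_log_sd, config.ic50_bounds, n)
    fu = _truncated_lognormal(rng, config.fu_median, config.fu_log_sd, config.fu_bounds, n)
    auc_total = _truncated_lognormal(
        rng, config.auc_total_median, config.auc_total_log_sd, config.auc_total_bounds, n
    )
    ptr = np.exp(rng.uniform(*np.log(config.ptr_bounds), size=n))
    return pd.DataFrame(
        {
            "compound_id": [f"C{i + 1:02d}" for i in range(n)],
            "ic50_ub_nM": ic50,
            "fu": fu,
            "auc_total_ref": auc_total,
            "auc_dn_ub": auc_total * fu / config.reference_dose,
            "ptr": ptr,
            "hill": config.hill,
        }
    )


def generate_xenografts(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-xenograft table of growth and decay rates.

    g/d is uniform on the configured responder range (so d > g always); g is
    uniform on an absolute range chosen so the drug-free control grows at
    least 3-fold in volume over 14 days at the default R0.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n = config.n_xenografts
    gd = rng.uniform(*config.gd_bounds, size=n)
    g = rng.uniform(*config.g_bounds, size=n)
    return pd.DataFrame(
        {
            "xenograft_id": [f"X{i + 1}" for i in range(n)],
            "g_mm_per_h": g,
            "d_mm_per_h": g / gd,
            "gd": gd,
            "r0_mm": config.r0,
        }
    )


def generate_studies(
    compounds: pd.DataFrame,
    xenografts: pd.DataFrame,
    config: GeneratorConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the study table: n_studies records with noisy observed TGI.

    Each study pairs a random compound and xenograft, assigns qd or bid
    dosing with the same daily dose (bid: tau = 12 h, half doses, PTR
    adapted to sqrt of the 24 h value since the elimination rate is a
    compound constant), and places the dose log-uniformly around the pair's
    closed-form stasis dose so coverages span the sigmoid.  Observed TGI is
    the simulated TGI plus additive Gaussian noise.
    """
    if len(compounds) == 0 or len(xenografts) == 0:
        raise DomainError("compounds and xenografts must be non-empty")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    rows = []
    for k in range(config.n_studies):
        comp = compounds.iloc[rng.integers(len(compounds))]
        xeno_row = xenografts.iloc[rng.integers(len(xenografts))]
        bid = rng.random() < config.bid_fraction
        tau = 12.0 if bid else 24.0
        # elimination rate fixed by the 24 h PTR; adapt PTR to the interval
        ptr = float(comp["ptr"]) ** (tau / 24.0)
        n_intervals = int(round(config.study_days * 24.0 / tau))
        xeno = Xenograft(
            g=float(xeno_row["g_mm_per_h"]), d=float(xeno_row["d_mm_per_h"]), r0=config.r0
        )
        effect = DrugEffect(ic50=float(comp["ic50_ub_nM"]), hill=float(comp["hill"]))
        d_stasis = stasis_dose(
            effect.ic50, float(comp["auc_dn_ub"]), tau, ptr, xeno.gd, effect.hill
        )
        lo, hi = config.dose_factor_bounds
        dose = d_stasis * math.exp(rng.uniform(math.log(lo), math.log(hi)))
        regimen = DoseRegimen(
            dose=dose, tau=tau, n_intervals=n_intervals, auc_dn_ub=float(comp["auc_dn_ub"])
        )
        rec = simulate_study(
            effect,
            regimen,
            ptr,
            xeno,
            study_id=f"S{k + 1:03d}",
            compound_id=str(comp["compound_id"]),
            xenograft_id=str(xeno_row["xenograft_id"]),
            fu=float(comp["fu"]),
        )
        noisy = rec.tgi_percent + rng.normal(0.0, config.tgi_noise_sd)
        row = {c: getattr(rec, c) for c in STUDY_COLUMNS}
        row["tgi_percent"] = noisy
        rows.append(row)
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None):
    """Convenience: compounds, xenografts and studies from one config/seed."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    compounds = generate_compounds(config)
    xenografts = generate_xenografts(config)
    studies = generate_studies(compounds, xenografts, config)
    return compounds, xenografts, studies


def write_records(table: pd.DataFrame, path) -> None:
    """Write a study-record table to CSV, floats at 17 significant digits."""
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"table lacks required columns: {missing}")
    table.to_csv(path, index=False, float_format="%.17g")


def read_records(path) -> pd.DataFrame:
    """Read a study-record CSV, validating the schema.

    Missing required columns raise :class:`~stasiskit.errors.SchemaError`
    naming them; extra columns are preserved and passed through.
    """
    df = pd.read_csv(path)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"CSV lacks required columns: {missing}")
    # stable dtypes: whole-valued floats (e.g. tau_h) must not collapse to int
    id_cols = {"study_id", "compound_id", "xenograft_id"}
    for col in STUDY_COLUMNS:
        if col in id_cols:
            continue
        df[col] = df[col].astype(int if col == "n_intervals" else float)
    return df
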