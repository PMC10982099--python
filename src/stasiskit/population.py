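"""Population extension: dose distributions and idiosyncratic resistance.

Replacing the single-patient IC50 and g/d by statistical variables turns the
closed-form stasis dose into a per-patient dose distribution,

    dose_i = tau * MEF(PTR, gd_i) * IC50_i / AUC_DN,ub.

Patients with g/d >= 1 have no finite stasis dose at any potency (tumour
idiosyncratic resistance) and are flagged as non-responders rather than
assigned a dose.  With a continuous g/d distribution of median 1, the
responder fraction is 50% regardless of the IC50 distribution or dose level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .stasis import stasis_dose

__all__ = [
    "DistSpec",
    "PopulationSpec",
    "PopulationDoseResult",
    "sample_population",
    "responder_fraction",
    "human_dose_distribution",
]

_DEFAULT_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


@dataclass(frozen=True)
class DistSpec:
    """Log-normal distribution specified by its median and log-sd.

    log-sd = 0 is the degenerate point distribution at the median.
    """

    median: float
    log_sd: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if not self.median > 0:
            raise DomainError("distribution median must be positive")
        if self.log_sd < 0:
            raise DomainError("log_sd must be >= 0")
        if self.family != "lognormal":
            raise DomainError(f"unsupported distribution family {self.family!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        draws = rng.normal(0.0, 1.0, size=n)  # always consume n draws per stream
        if self.log_sd == 0.0:
            return np.full(n, self.median)
        return self.median * np.exp(self.log_sd * draws)


@dataclass(frozen=True)
class PopulationSpec:
    """Joint population spec for unbound IC50 (nM) and the g/d ratio.

    IC50 and g/d are sampled independently (the default, matching the
    treatment of the two as separate statistical variables); externally
    supplied joint samples -- e.g. imaging-derived g/d tables -- can be fed
    directly to :func:`human_dose_distribution` instead.
    """

    ic50: DistSpec
    gd: DistSpec
    independent: bool = True


def sample_population(spec: PopulationSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw n patients' (ic50, gd); reproducible under a fixed seed."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"ic50": spec.ic50.sample(n, rng), "gd": spec.gd.sample(n, rng)}
    )


def responder_fraction(samples) -> float:
    """Fraction of patients with g/d < 1, i.e. a finite stasis dose exists.

    Independent of the IC50 distribution and of dose: idiosyncratic
    resistance is a property of the tumour's growth/decay balance alone.
    """
    gd = np.asarray(samples["gd"] if hasattr(samples, "columns") else samples, dtype=float)
    if gd.size == 0:
        raise DomainError("samples must be non-empty")
    return float(np.mean(gd < 1.0))


@dataclass(frozen=True)
class PopulationDoseResult:
    """Per-patient stasis doses with resistance flags and responder summary."""

    doses: np.ndarray  # mg/kg; NaN for non-responders
    non_responder: np.ndarray  # boolean mask, True where g/d >= 1
    responder_fraction: float
    quantiles: dict[float, float] = field(default_factory=dict)  # among responders

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_mgkg": self.doses, "non_responder": self.non_responder}
        )


def human_dose_distribution(
    samples,
    ptr: float,
    auc_dn_ub: float,
    tau: float,
    quantiles=_DEFAULT_QUANTILES,
) -> PopulationDoseResult:
    """Per-patient stasis doses for sampled (IC50, g/d) pairs.

    Applies the closed-form stasis dose elementwise; patients with
    g/d >= 1 are flagged non-responders (no finite dose) and excluded from
    the dose quantiles, which are reported among responders only.  PTR is
    treated as a compound constant across the population.
    """
    if hasattr(samples, "columns"):
        ic50 = samples["ic50"].to_numpy(dtype=float)
        gd = samples["gd"].to_numpy(dtype=float)
    else:
        ic50, gd = (np.asarray(a, dtype=float) for a in samples)
    if ic50.size == 0 or ic50.shape != gd.shape:
        raise DomainError("samples must be non-empty with matching ic50/gd shapes")

    resistant = gd >= 1.0
    doses = np.full(gd.shape, np.nan)
    if np.any(~resistant):
        doses[~resistant] = stasis_dose(
            ic50[~resistant], auc_dn_ub, tau, ptr, gd[~resistant]
        )
    frac = float(np.mean(~resistant))
    q = {}
    if np.any(~resistant):
        vals = np.quantile(doses[~resistant], list(quantiles))
        q = {float(p): float(v) for p, v in zip(quantiles, vals)}
    return PopulationDoseResult(
        doses=doses,
        non_responder=resistant,
        responder_fraction=frac,
        quantiles=q,
    )
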