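"""Activity-screen and kinetics computations.

Endpoint screens: subtract no-substrate controls, set the limit of
detection from blank (carrier-protein) replicates as mean + 4*SD, and call
a protein a hit only when it is soluble in >= 2 of 3 expressions AND
active above the LOD in >= 2 of 3 assay replicates.  Rate assays: convert
absorbance slopes to molar rates through the chromophore's extinction
coefficient (DCPIP at 600 nm: 20.7 mM^-1 cm^-1), fit the Michaelis-Menten
model v = V_max*S/(K_M+S) by nonlinear least squares, and derive
k_cat = V_max/[E] and the catalytic efficiency k_cat/K_M.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DCPIP_EXTINCTION_MM = 20.7  # mM^-1 cm^-1 at 600 nm


@dataclass
class PlateMeasurement:
    """Replicated endpoint measurements for one protein x substrate."""

    protein_id: str
    substrate: str
    signals: list[float]
    controls: list[float] = field(default_factory=list)
    soluble_calls: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.signals:
            raise ValueError(
                f"{self.protein_id}/{self.substrate}: need >= 1 replicate"
            )

    def corrected(self) -> list[float]:
        """Signals minus control mean; pass-through when controls are
        empty (pre-subtracted data)."""
        if not self.controls:
            return list(self.signals)
        return subtract_controls(self.signals, self.controls)


class PoorlyConstrainedWarning(UserWarning):
    pass


@dataclass
class KineticFit:
    """Michaelis-Menten parameters with Jacobian-based standard errors."""

    K_M: float  # molar
    V_max: float  # molar / s
    k_cat: float  # 1 / s
    efficiency: float  # 1 / (M s)
    enzyme_conc: float  # molar
    stderr_K_M: float
    stderr_V_max: float

    def to_jsonable(self) -> dict:
        return {
            "K_M_molar": self.K_M,
            "V_max_molar_per_s": self.V_max,
            "k_cat_per_s": self.k_cat,
            "efficiency_per_M_per_s": self.efficiency,
            "enzyme_conc_molar": self.enzyme_conc,
            "stderr_K_M": self.stderr_K_M,
            "stderr_V_max": self.stderr_V_max,
        }


def subtract_controls(
    signals: Sequence[float], controls: Sequence[float]
) -> list[float]:
    """Each signal minus the mean control; negatives are retained, since
    clipping would bias replicate statistics."""
    if not controls:
        raise ValueError("no control measurements to subtract")
    mean_control = float(np.mean(controls))
    return [float(s) - mean_control for s in signals]


def detection_limit(blank_replicates: Sequence[float], k_sd: float = 4.0) -> float:
    """LOD = mean(blanks) + k_sd * sample SD (n-1 denominator)."""
    if len(blank_replicates) < 2:
        raise ValueError("SD undefined: need >= 2 blank replicates")
    blanks = np.asarray(blank_replicates, dtype=float)
    return float(blanks.mean() + k_sd * blanks.std(ddof=1))


def call_hit(
    measurement: PlateMeasurement,
    lod: float,
    min_active: int = 2,
    min_soluble: int = 2,
) -> dict[str, bool]:
    """Replicate-based hit call: soluble >= min_soluble expressions AND
    strictly-above-LOD in >= min_active assay replicates."""
    corrected = measurement.corrected()
    active = sum(1 for v in corrected if v > lod) >= min_active
    soluble = sum(measurement.soluble_calls) >= min_soluble
    return {"soluble": soluble, "active": active, "hit": soluble and active}


def rate_from_absorbance(
    slope: float,
    epsilon_mM: float = DCPIP_EXTINCTION_MM,
    path_cm: float = 1.0,
    enzyme_conc: Optional[float] = None,
) -> tuple[float, Optional[float]]:
    """Convert an absorbance slope (AU/s) to a molar rate via Beer-Lambert.

    v = slope / (epsilon_mM * 1000 * path_cm)  [M/s], the factor 1000
    converting the mM-based extinction coefficient to M^-1 cm^-1.  When an
    enzyme concentration is given, also returns the observed turnover
    k_cat_obs = v / [E].
    """
    if epsilon_mM <= 0 or path_cm <= 0:
        raise ValueError("extinction coefficient and path length must be > 0")
    v = slope / (epsilon_mM * 1000.0 * path_cm)
    if enzyme_conc is None:
        return v, None
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be > 0")
    return v, v / enzyme_conc


def michaelis_menten(S, V_max, K_M):
    S = np.asarray(S, dtype=float)
    return V_max * S / (K_M + S)


def fit_michaelis_menten(
    substrate: Sequence[float],
    velocity: Sequence[float],
    enzyme_conc: float,
) -> KineticFit:
    """Unweighted nonlinear least-squares fit of v = V_max*S/(K_M+S).

    Initialisation: V_max0 = max(v); K_M0 = the substrate concentration
    whose velocity lies closest to V_max0/2.  Standard errors come from
    the Jacobian-based covariance.  A fitted K_M outside (0, 100*max S)
    triggers a poorly-constrained warning — typical when only saturating
    concentrations were measured.
    """
    S = np.asarray(substrate, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if S.shape != v.shape:
        raise ValueError("substrate and velocity lengths differ")
    if len(np.unique(S)) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be > 0")
    vmax0 = float(v.max())
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2))])
    if km0 <= 0:
        km0 = float(np.median(S[S > 0])) if (S > 0).any() else 1.0
    try:
        popt, pcov = curve_fit(
            michaelis_menten, S, v, p0=[vmax0, km0],
            maxfev=20000, xtol=1e-12, ftol=1e-12,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax_fit, km_fit = float(popt[0]), float(popt[1])
    stderr = np.sqrt(np.diag(pcov))
    if not (0 < km_fit < 100 * S.max()):
        warnings.warn(
            f"poorly constrained: fitted K_M={km_fit:.3g} M outside "
            f"(0, {100 * S.max():.3g})",
            PoorlyConstrainedWarning,
        )
    k_cat = vmax_fit / enzyme_conc
    return KineticFit(
        K_M=km_fit,
        V_max=vmax_fit,
        k_cat=k_cat,
        efficiency=k_cat / km_fit if km_fit > 0 else float("nan"),
        enzyme_conc=enzyme_conc,
        stderr_K_M=float(stderr[1]),
        stderr_V_max=float(stderr[0]),
    )


def catalytic_efficiency(k_cat: float, K_M: float) -> float:
    """k_cat / K_M in M^-1 s^-1 — the specificity constant."""
    if K_M <= 0:
        raise ValueError("K_M must be > 0")
    return k_cat / K_M


def read_kinetics_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """TSV with columns substrate_M and velocity_M_per_s."""
    df = pd.read_csv(path, sep="\t")
    required = {"substrate_M", "velocity_M_per_s"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df["substrate_M"].to_numpy(float), df["velocity_M_per_s"].to_numpy(float)


def read_plate_table(path: str | Path) -> list[PlateMeasurement]:
    """TSV with columns protein_id, substrate, replicate, signal,
    is_control (0/1) and optional soluble (0/1 per expression replicate)."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "substrate", "replicate", "signal", "is_control"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out: list[PlateMeasurement] = []
    for (protein, substrate), group in df.groupby(
        ["protein_id", "substrate"], sort=False
    ):
        is_control = group["is_control"].astype(int) == 1
        soluble: list[bool] = []
        if "soluble" in group.columns:
            sol = group.loc[~is_control, "soluble"].dropna()
            soluble = [bool(int(x)) for x in sol]
        out.append(
            PlateMeasurement(
                protein_id=str(protein),
                substrate=str(substrate),
                signals=group.loc[~is_control, "signal"].astype(float).tolist(),
                controls=group.loc[is_control, "signal"].astype(float).tolist(),
                soluble_calls=soluble,
            )
        )
    return out


def write_fit_json(fit: KineticFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_jsonable(), indent=2) + "\n")
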