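"""Enzyme kinetics: Michaelis–Menten fits, Arrhenius fits and KIE decomposition.

The module follows a model/results layout: a model object is built from
data, its :meth:`fit` returns a results object carrying estimates, standard
errors, the parameter covariance and a ``summary()`` table.

Scientific background
---------------------
For a Kemp eliminase acting on 5-nitrobenzisoxazole, saturation kinetics at a
single temperature follow the Michaelis–Menten law

    v([S]) = kcat * [S] / (KM + [S])        (after background subtraction)

and the temperature dependence of a rate constant follows the Arrhenius law

    ln k = ln A - Ea / (R * T)

with Ea the activation energy (kcal/mol, enthalpic component) and A the
pre-exponential factor (collision-frequency / entropic component).  A primary
H/D kinetic isotope effect decomposes via two Arrhenius fits into

    kH/kD = (A_H/A_D) * exp((Ea_D - Ea_H) / (R*T))

which separates an activation-energy KIE from a pre-exponential KIE; both
carry first-order (delta-method) propagated standard errors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from kemplab.constants import GAS_CONSTANT_KCAL

__all__ = [
    "RateTable",
    "MichaelisMenten",
    "MichaelisMentenResults",
    "Arrhenius",
    "ArrheniusResults",
    "KIEDecomposition",
    "kie_decomposition",
    "kie_table",
    "DEFAULT_KIE_TEMPERATURE",
]

#: Temperature (K) at which tabulated kinetic constants are reported.
DEFAULT_KIE_TEMPERATURE = 303.0

#: Canonical variant order along the evolutionary trajectory (B = buffer /
#: nonenzymatic background reaction).
TRAJECTORY_ORDER = ["B", "R1", "R4", "R5", "R6", "R7", "R7-2"]

RATE_COLUMNS = ["variant", "isotope", "conc_mM", "temp_K", "rate_per_s", "replicate"]


class RateTable:
    """Replicate rate constants indexed by variant, isotope, [S] and T.

    Thin wrapper around a :class:`pandas.DataFrame` with the canonical
    columns ``variant, isotope, conc_mM, temp_K, rate_per_s, replicate``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in RATE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"rate table missing columns: {missing}")
        if (frame["temp_K"] <= 0).any():
            raise ValueError("temperatures must be positive (K)")
        if (frame["conc_mM"] < 0).any():
            raise ValueError("substrate concentrations must be non-negative")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def variants(self) -> list[str]:
        return sorted(self.frame["variant"].unique())

    def select(self, variant=None, isotope=None, temp_K=None) -> pd.DataFrame:
        df = self.frame
        if variant is not None:
            df = df[df["variant"] == variant]
        if isotope is not None:
            df = df[df["isotope"] == isotope]
        if temp_K is not None:
            df = df[np.isclose(df["temp_K"], temp_K)]
        return df

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Michaelis–Menten
# ---------------------------------------------------------------------------

def _mm_model(s, kcat, km):
    return kcat * s / (km + s)


class MichaelisMenten:
    """Michaelis–Menten saturation model at a single temperature.

    Parameters
    ----------
    conc_mM : array-like
        Substrate concentrations, mM.  At least 5 distinct values.
    rate_per_s : array-like
        Observed rates (kcat-normalised velocities), s^-1, *including* any
        background (uncatalysed) contribution.
    background : float
        Rate of the uncatalysed reaction, s^-1, subtracted from every
        observation before fitting.
    """

    def __init__(self, conc_mM, rate_per_s, background: float = 0.0):
        conc = np.asarray(conc_mM, dtype=float)
        rate = np.asarray(rate_per_s, dtype=float)
        if conc.shape != rate.shape:
            raise ValueError("conc_mM and rate_per_s must have equal length")
        if background < 0:
            raise ValueError("background rate must be >= 0")
        n_distinct = len(np.unique(conc))
        if n_distinct < 5:
            raise ValueError(
                f"need >=5 distinct substrate concentrations, got {n_distinct}"
            )
        self.conc = conc
        self.rate = rate
        self.background = float(background)

    def fit(self) -> "MichaelisMentenResults":
        v = self.rate - self.background
        if np.all(np.abs(v) <= 1e-12 + 1e-9 * self.background):
            raise ValueError("no signal above background after subtraction")
        kcat0, km0 = self._initial_guess(self.conc, v)
        # log-parameterisation enforces positivity
        theta0 = np.log([max(kcat0, 1e-12), max(km0, 1e-9)])

        def model(s, lk, lkm):
            return _mm_model(s, np.exp(lk), np.exp(lkm))

        converged = True
        message = ""
        try:
            theta, theta_cov = curve_fit(
                model, self.conc, v, p0=theta0, maxfev=20000
            )
        except RuntimeError as exc:  # non-convergence: flagged, not raised
            converged = False
            message = str(exc)
            theta, theta_cov = theta0, np.full((2, 2), np.nan)
        kcat, km = np.exp(theta)
        # delta method back to the natural scale: d kcat = kcat d(log kcat)
        jac = np.diag([kcat, km])
        cov = jac @ theta_cov @ jac.T
        se = np.sqrt(np.diag(cov))
        return MichaelisMentenResults(
            kcat=float(kcat),
            KM=float(km),
            se_kcat=float(se[0]),
            se_KM=float(se[1]),
            cov=cov,
            background=self.background,
            converged=converged,
            message=message,
            n_obs=len(self.conc),
            model=self,
        )

    @staticmethod
    def _initial_guess(s, v):
        """Double-reciprocal (Lineweaver–Burk) linearisation for a start point."""
        mask = (s > 0) & (v > 0)
        if mask.sum() >= 2:
            x, y = 1.0 / s[mask], 1.0 / v[mask]
            slope, intercept = np.polyfit(x, y, 1)
            if intercept > 0:
                kcat0 = 1.0 / intercept
                km0 = slope * kcat0
                if km0 > 0:
                    return kcat0, km0
        return max(np.max(v), 1e-9), np.median(s[s > 0]) if (s > 0).any() else 1.0


@dataclass
class MichaelisMentenResults:
    kcat: float  # s^-1
    KM: float  # mM
    se_kcat: float
    se_KM: float
    cov: np.ndarray
    background: float
    converged: bool
    message: str
    n_obs: int
    model: MichaelisMenten | None = None

    @property
    def efficiency(self) -> float:
        """kcat/KM in s^-1 M^-1 (KM converted from mM to M)."""
        return self.kcat / (self.KM * 1e-3)

    @property
    def se_efficiency(self) -> float:
        """Delta-method SE of kcat/KM using the full fit covariance."""
        g = np.array([1.0 / (self.KM * 1e-3), -self.kcat / (self.KM**2 * 1e-3)])
        return float(np.sqrt(g @ self.cov @ g))

    def predict(self, conc_mM) -> np.ndarray:
        return _mm_model(np.asarray(conc_mM, dtype=float), self.kcat, self.KM)

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten fit",
            f"  n obs        : {self.n_obs}",
            f"  background   : {self.background:.3e} s^-1",
            f"  kcat         : {self.kcat:.4g} +/- {self.se_kcat:.2g} s^-1",
            f"  KM           : {self.KM:.4g} +/- {self.se_KM:.2g} mM",
            f"  kcat/KM      : {self.efficiency:.4g} +/- {self.se_efficiency:.2g} s^-1 M^-1",
            f"  converged    : {self.converged}" + ("" if self.converged else f" ({self.message})"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kcat_per_s": self.kcat,
            "KM_mM": self.KM,
            "se_kcat": self.se_kcat,
            "se_KM": self.se_KM,
            "efficiency_per_s_per_M": self.efficiency,
            "se_efficiency": self.se_efficiency,
            "background_per_s": self.background,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


# ---------------------------------------------------------------------------
# Arrhenius
# ---------------------------------------------------------------------------

class Arrhenius:
    """Linear Arrhenius model ln k = ln A - Ea/(R T).

    Fit by (optionally weighted) least squares of ln k on 1/T; the default is
    ordinary least squares on the log-rates, matching the usual Arrhenius-plot
    analysis.
    """

    def __init__(self, temp_K, rate_per_s, weights=None):
        T = np.asarray(temp_K, dtype=float)
        k = np.asarray(rate_per_s, dtype=float)
        if T.shape != k.shape:
            raise ValueError("temp_K and rate_per_s must have equal length")
        if np.any(T <= 0):
            raise ValueError("temperatures must be positive")
        if np.any(k <= 0):
            raise ValueError("all rates must be positive for a log fit")
        if len(np.unique(T)) < 3:
            raise ValueError("need >=3 distinct temperatures")
        self.T = T
        self.k = k
        self.weights = None if weights is None else np.asarray(weights, float)

    def fit(self) -> "ArrheniusResults":
        import statsmodels.api as sm

        x = 1.0 / self.T
        y = np.log(self.k)
        X = sm.add_constant(x)
        if self.weights is None:
            res = sm.OLS(y, X).fit()
        else:
            res = sm.WLS(y, X, weights=self.weights).fit()
        intercept, slope = res.params
        cov_io = np.asarray(res.cov_params())  # (intercept, slope) order
        R = GAS_CONSTANT_KCAL
        lnA = intercept
        Ea = -slope * R
        # transform covariance: (lnA, Ea) = (intercept, -R*slope)
        Jt = np.array([[1.0, 0.0], [0.0, -R]])
        cov = Jt @ cov_io @ Jt.T  # order (lnA, Ea)
        return ArrheniusResults(
            Ea=float(Ea),
            lnA=float(lnA),
            se_Ea=float(np.sqrt(cov[1, 1])),
            se_lnA=float(np.sqrt(cov[0, 0])),
            cov_lnA_Ea=cov,
            temperature_range=(float(self.T.min()), float(self.T.max())),
            n_points=len(self.T),
            resid=np.asarray(res.resid),
        )

    @classmethod
    def from_dict(cls, k_by_T: dict) -> "Arrhenius":
        items = sorted(k_by_T.items())
        return cls([t for t, _ in items], [k for _, k in items])


@dataclass
class ArrheniusResults:
    Ea: float  # kcal/mol
    lnA: float  # ln of A in s^-1
    se_Ea: float
    se_lnA: float
    cov_lnA_Ea: np.ndarray  # 2x2, order (lnA, Ea)
    temperature_range: tuple[float, float]
    n_points: int
    resid: np.ndarray = field(default_factory=lambda: np.array([]))

    @classmethod
    def from_params(cls, Ea, lnA, se_Ea=0.0, se_lnA=0.0, cov_lnA_Ea=None,
                    temperature_range=(283.0, 323.0), n_points=0):
        """Build a results object from externally tabulated parameters."""
        if cov_lnA_Ea is None:
            cov_lnA_Ea = np.diag([se_lnA**2, se_Ea**2])
        return cls(Ea=float(Ea), lnA=float(lnA), se_Ea=float(se_Ea),
                   se_lnA=float(se_lnA), cov_lnA_Ea=np.asarray(cov_lnA_Ea),
                   temperature_range=temperature_range, n_points=n_points)

    def predict_rate(self, temp_K) -> np.ndarray | float:
        """Evaluate k = exp(lnA - Ea/(R T))."""
        T = np.asarray(temp_K, dtype=float)
        if np.any(T <= 0):
            raise ValueError("temperature must be positive")
        out = np.exp(self.lnA - self.Ea / (GAS_CONSTANT_KCAL * T))
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        lo, hi = self.temperature_range
        return "\n".join([
            "Arrhenius fit (ln k = ln A - Ea/RT)",
            f"  n points    : {self.n_points} over {lo:.0f}-{hi:.0f} K",
            f"  Ea          : {self.Ea:.3g} +/- {self.se_Ea:.2g} kcal/mol",
            f"  ln A        : {self.lnA:.3g} +/- {self.se_lnA:.2g}",
        ])

    def to_dict(self) -> dict:
        return {
            "Ea_kcal_per_mol": self.Ea,
            "lnA": self.lnA,
            "se_Ea": self.se_Ea,
            "se_lnA": self.se_lnA,
            "temperature_range_K": list(self.temperature_range),
            "n_points": self.n_points,
        }


def fit_arrhenius_from_table(table: RateTable, variant: str, isotope: str,
                             background_variant: str | None = "B") -> ArrheniusResults:
    """Fit Arrhenius parameters for ``kcat(T)`` from a rate table.

    At each temperature with several substrate concentrations, a full
    Michaelis–Menten fit (after subtracting the background variant's mean
    rate at that temperature) yields kcat; single-concentration series fall
    back to the background-corrected mean rate.  The Arrhenius model is then
    fitted to kcat(T).
    """
    df = table.select(variant=variant, isotope=isotope)
    if df.empty:
        raise ValueError(f"no rates for variant={variant} isotope={isotope}")
    bg_by_T = None
    if background_variant is not None and background_variant != variant:
        bg = table.select(variant=background_variant, isotope=isotope)
        if not bg.empty:
            bg_by_T = bg.groupby("temp_K")["rate_per_s"].mean()
    temps, kcats = [], []
    for T, grp in df.groupby("temp_K"):
        background = 0.0
        if bg_by_T is not None:
            exact = bg_by_T.index[np.isclose(bg_by_T.index, T)]
            if len(exact):
                background = float(bg_by_T.loc[exact[0]])
        by_conc = grp.groupby("conc_mM")["rate_per_s"].mean()
        if len(by_conc) >= 5:
            fit = MichaelisMenten(by_conc.index.to_numpy(),
                                  by_conc.to_numpy(), background).fit()
            if not fit.converged:
                continue
            kcat = fit.kcat
        else:
            kcat = float(grp["rate_per_s"].mean()) - background
        if kcat > 0:
            temps.append(float(T))
            kcats.append(kcat)
    return Arrhenius(np.array(temps), np.array(kcats)).fit()


# ---------------------------------------------------------------------------
# KIE decomposition
# ---------------------------------------------------------------------------

@dataclass
class KIEDecomposition:
    """H/D kinetic isotope effect split into Arrhenius components.

    ``kie_at_T = A_ratio * exp(delta_Ea / (R*T))`` holds by construction.
    """

    variant: str
    temperature: float  # K
    delta_Ea: float  # Ea(D) - Ea(H), kcal/mol
    se_delta_Ea: float
    A_ratio: float  # A_H / A_D
    se_A_ratio: float
    kie_at_T: float  # kH/kD
    se_kie_at_T: float

    def summary(self) -> str:
        return "\n".join([
            f"KIE decomposition ({self.variant} at {self.temperature:.0f} K)",
            f"  Ea(D)-Ea(H) : {self.delta_Ea:.3g} +/- {self.se_delta_Ea:.2g} kcal/mol",
            f"  A_H/A_D     : {self.A_ratio:.3g} +/- {self.se_A_ratio:.2g}",
            f"  kH/kD       : {self.kie_at_T:.3g} +/- {self.se_kie_at_T:.2g}",
        ])

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "temperature_K": self.temperature,
            "delta_Ea_kcal_per_mol": self.delta_Ea,
            "se_delta_Ea": self.se_delta_Ea,
            "A_ratio": self.A_ratio,
            "se_A_ratio": self.se_A_ratio,
            "kie": self.kie_at_T,
            "se_kie": self.se_kie_at_T,
        }


def kie_decomposition(fit_H: ArrheniusResults, fit_D: ArrheniusResults,
                      temperature: float = DEFAULT_KIE_TEMPERATURE,
                      variant: str = "") -> KIEDecomposition:
    """Decompose a KIE into activation-energy and pre-exponential parts.

    Standard errors are first-order (delta-method) propagated from the two
    independent fits' full (lnA, Ea) covariance matrices.
    """
    RT = GAS_CONSTANT_KCAL * temperature
    delta_Ea = fit_D.Ea - fit_H.Ea
    se_delta_Ea = float(np.sqrt(fit_H.se_Ea**2 + fit_D.se_Ea**2))
    A_ratio = float(np.exp(fit_H.lnA - fit_D.lnA))
    se_A_ratio = A_ratio * float(np.sqrt(fit_H.se_lnA**2 + fit_D.se_lnA**2))
    kie = A_ratio * np.exp(delta_Ea / RT)
    # ln kie = lnA_H - lnA_D - Ea_H/RT + Ea_D/RT; gradient per fit in the
    # (lnA, Ea) order, then quadratic form with each fit's covariance.
    gH = np.array([1.0, -1.0 / RT])
    gD = np.array([-1.0, 1.0 / RT])
    var_ln = float(gH @ fit_H.cov_lnA_Ea @ gH + gD @ fit_D.cov_lnA_Ea @ gD)
    se_kie = kie * float(np.sqrt(max(var_ln, 0.0)))
    return KIEDecomposition(
        variant=variant,
        temperature=float(temperature),
        delta_Ea=float(delta_Ea),
        se_delta_Ea=se_delta_Ea,
        A_ratio=A_ratio,
        se_A_ratio=se_A_ratio,
        kie_at_T=float(kie),
        se_kie_at_T=se_kie,
    )


def kie_table(table: RateTable, temperature: float = DEFAULT_KIE_TEMPERATURE,
              variants: list[str] | None = None,
              background_variant: str | None = "B") -> pd.DataFrame:
    """Per-variant KIE decompositions across the evolutionary trajectory.

    Variants missing either isotope series are skipped with a warning.  The
    output is ordered along the canonical trajectory (B, R1, R4..R7-2) with
    any other variants appended alphabetically, and is independent of the
    input row order.
    """
    if variants is None:
        variants = table.variants()
    order = [v for v in TRAJECTORY_ORDER if v in variants]
    order += sorted(v for v in variants if v not in TRAJECTORY_ORDER)
    rows = []
    for variant in order:
        try:
            fit_H = fit_arrhenius_from_table(table, variant, "H", background_variant)
            fit_D = fit_arrhenius_from_table(table, variant, "D", background_variant)
        except ValueError as exc:
            warnings.warn(f"variant {variant!r} skipped: {exc}", stacklevel=2)
            continue
        dec = kie_decomposition(fit_H, fit_D, temperature, variant=variant)
        row = dec.to_dict()
        row.update({
            "Ea_H": fit_H.Ea, "se_Ea_H": fit_H.se_Ea,
            "Ea_D": fit_D.Ea, "se_Ea_D": fit_D.se_Ea,
            "lnA_H": fit_H.lnA, "se_lnA_H": fit_H.se_lnA,
            "lnA_D": fit_D.lnA, "se_lnA_D": fit_D.se_lnA,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def write_kie_results(df: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    """Serialise a ``kie_table`` result as TSV and/or JSON records."""
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
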