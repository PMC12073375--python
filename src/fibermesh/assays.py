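"""Gravimetric absorption capacity and molar-mass-distribution averages.

Absorption capacity of a hydrated mesh is the percent weight gain over the
dry weight, AC(%) = (W_h - W_d) / W_d * 100.  A soak time series is scanned
for the equilibrium plateau: the first time point from which every
subsequent consecutive relative change in AC stays below a tolerance
(default 2%) through the end of the series.

Molar-mass averages of a polymer distribution {(M_i, N_i)} are the usual
moment ratios: Mn = sum(N M)/sum(N), Mw = sum(N M^2)/sum(N M),
Mz = sum(N M^3)/sum(N M^2), and the polydispersity index PDI = Mw/Mn.
The power-mean inequality guarantees Mn <= Mw <= Mz (equality only for a
monodisperse sample), so PDI >= 1 always.  Input may be a number-fraction
table or raw per-molecule masses (each with N_i = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "absorption_capacity",
    "AbsorptionSeriesResult",
    "absorption_series",
    "MolarMassAverages",
    "mwd_averages",
    "read_absorption_csv",
    "read_mwd_csv",
]


def absorption_capacity(W_h: float, W_d: float) -> float:
    """AC(%) = (W_h - W_d) / W_d * 100.

    Negative values (net mass loss) are allowed and simply returned; the
    caller decides whether to flag them.
    """
    if not W_d > 0:
        raise ValidationError("W_d must be positive")
    if W_h < 0:
        raise ValidationError("W_h must be non-negative")
    return (W_h - W_d) / W_d * 100.0


@dataclass
class AbsorptionSeriesResult:
    """Per-time-point AC plus the equilibrium summary of a soak series."""

    table: pd.DataFrame  # time_h, W_h_g, W_d_g, medium, AC_percent, mass_loss_flag
    equilibrium_time_h: float | None
    final_AC_percent: float
    tol: float

    @property
    def equilibrium_reached(self) -> bool:
        return self.equilibrium_time_h is not None


def absorption_series(
    records: pd.DataFrame, tol: float = 0.02
) -> AbsorptionSeriesResult:
    """Compute AC over a soak time series and locate the equilibrium plateau.

    ``records`` needs columns time_h, W_h_g, W_d_g (medium optional).
    Times must be strictly increasing.  Equilibrium is the first time point
    from which the relative change in AC between every pair of consecutive
    points stays below ``tol`` through the series end; ``None`` if never.
    """
    df = pd.DataFrame(records).copy()
    for col in ("time_h", "W_h_g", "W_d_g"):
        if col not in df.columns:
            raise ValidationError(f"absorption table is missing column {col!r}")
    if "medium" not in df.columns:
        df["medium"] = "water"
    t = df["time_h"].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValidationError("absorption table is empty")
    if np.any(t < 0):
        raise ValidationError("time_h must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time_h must be strictly increasing (no duplicates)")
    if not tol > 0:
        raise ValidationError("tol must be positive")
    ac = np.array(
        [absorption_capacity(wh, wd) for wh, wd in zip(df["W_h_g"], df["W_d_g"])]
    )
    df["AC_percent"] = ac
    df["mass_loss_flag"] = ac < 0

    eq_time: float | None
    if len(ac) == 1:
        eq_time = float(t[0])
    else:
        denom = np.maximum(np.abs(ac[:-1]), 1e-12)
        rel = np.abs(np.diff(ac)) / denom
        stable = rel < tol  # stable[i]: step i -> i+1 is a plateau step
        eq_idx = None
        for i in range(len(ac) - 1):
            if stable[i:].all():
                eq_idx = i
                break
        eq_time = float(t[eq_idx]) if eq_idx is not None else None
    return AbsorptionSeriesResult(
        table=df,
        equilibrium_time_h=eq_time,
        final_AC_percent=float(ac[-1]),
        tol=tol,
    )


@dataclass
class MolarMassAverages:
    """Moment averages of a molar-mass distribution, in g/mol."""

    Mn: float
    Mw: float
    Mz: float
    PDI: float


def mwd_averages(M, N=None) -> MolarMassAverages:
    """Mn, Mw, Mz and PDI from a molar-mass distribution.

    ``M`` is a sequence of molar masses (g/mol); ``N`` the matching
    abundances, or ``None`` for raw per-molecule samples (N_i = 1).
    Invariant to rescaling all abundances by a positive constant.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 1 or M.size == 0:
        raise ValidationError("M must be a non-empty 1-D sequence")
    if np.any(M <= 0):
        raise ValidationError("molar masses must be positive")
    if N is None:
        N = np.ones_like(M)
    else:
        N = np.asarray(N, dtype=float)
        if N.shape != M.shape:
            raise ValidationError("M and N must have the same length")
        if np.any(N < 0):
            raise ValidationError("abundances must be non-negative")
    s0 = float(N.sum())
    if s0 <= 0:
        raise ValidationError("all abundances are zero")
    s1 = float((N * M).sum())
    s2 = float((N * M**2).sum())
    s3 = float((N * M**3).sum())
    Mn, Mw, Mz = s1 / s0, s2 / s1, s3 / s2
    return MolarMassAverages(Mn=Mn, Mw=Mw, Mz=Mz, PDI=Mw / Mn)


def read_absorption_csv(path) -> pd.DataFrame:
    """Read a soak series CSV (columns time_h, W_h_g, W_d_g[, medium])."""
    return pd.read_csv(path)


def read_mwd_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a molar-mass table CSV (columns M_g_per_mol[, N])."""
    df = pd.read_csv(path)
    if "M_g_per_mol" not in df.columns:
        raise ValidationError("MWD table is missing column 'M_g_per_mol'")
    M = df["M_g_per_mol"].to_numpy(dtype=float)
    N = df["N"].to_numpy(dtype=float) if "N" in df.columns else None
    return M, N
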