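"""Re-entrant condensation phase analysis.

A cationic protein titrated with a polyvalent anion condenses between two
critical anion concentrations, C* (condensation) and C** (redissolution).
This module computes solution ionic strengths, locates the boundaries in
precipitation series, fits the empirical linear relation

    c* = m*·c_p + c^f

(m*: ions bound per protein at the condensation boundary, c^f: free-ion
concentration in equilibrium with the protein–ion complex), converts m*
into a charge contribution, and computes NaCl-equivalent ionic strengths.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sequence import HST5_MW

DEFAULT_RETENTION_THRESHOLD = 0.95


def ionic_strength(species) -> float:
    """I = ½ Σ cᵢ zᵢ² with concentrations in mol/L.

    `species` is an iterable of (concentration, valence) pairs; counterions
    must be listed explicitly (see :func:`salt_species`).
    """
    total = 0.0
    for c, z in species:
        if c < 0:
            raise ValueError("concentrations must be non-negative")
        total += c * z * z
    return 0.5 * total


def salt_species(conc: float, anion_valence: float, cation_valence: float = 1.0):
    """Expand a fully dissociated salt into its electroneutral ion pair.

    E.g. 0.011 mol/L Na₅TPP → [(0.055, +1), (0.011, −5)].
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if anion_valence >= 0 or cation_valence <= 0:
        raise ValueError("expected anion_valence < 0 < cation_valence")
    n_cation = abs(anion_valence) / cation_valence
    return [(conc * n_cation, cation_valence), (conc, anion_valence)]


def cs_cp(anion_conc_mM: float, protein_conc_mg_per_mL: float, mw: float = HST5_MW) -> float:
    """Molar anion-to-protein ratio Cs/Cp.

    anion in mM, protein in mg/mL, MW in Da: protein molarity (mM) is
    protein_conc/mw × 10³.
    """
    if anion_conc_mM <= 0 or protein_conc_mg_per_mL <= 0 or mw <= 0:
        raise ValueError("inputs must be strictly positive")
    protein_mM = protein_conc_mg_per_mL / mw * 1e3
    return anion_conc_mM / protein_mM


@dataclass
class PrecipitationSeries:
    """Supernatant protein concentration vs anion concentration.

    `anion_conc` in mM (ascending), `supernatant_conc` in mg/mL,
    `protein_conc_initial` in mg/mL, `protein_mw` in Da.
    """

    anion_conc: np.ndarray
    supernatant_conc: np.ndarray
    protein_conc_initial: float
    protein_mw: float = HST5_MW
    anion_label: str = "TPP"

    def __post_init__(self) -> None:
        self.anion_conc = np.asarray(self.anion_conc, float)
        self.supernatant_conc = np.asarray(self.supernatant_conc, float)
        if len(self.anion_conc) != len(self.supernatant_conc):
            raise ValueError("array length mismatch")
        if np.any(np.diff(self.anion_conc) <= 0):
            raise ValueError("anion concentrations must be strictly ascending")
        if np.any(self.supernatant_conc < 0):
            raise ValueError("supernatant concentrations must be non-negative")
        if np.any(self.supernatant_conc > 1.05 * self.protein_conc_initial):
            raise ValueError("supernatant exceeds the initial protein concentration by > 5%")


@dataclass(frozen=True)
class PhaseBoundaries:
    """C*, C** and C_max in mM, with the matching anion-per-protein ratios.

    A boundary that the series never crosses is None (missing), not zero.
    """

    c_star: float | None
    c_double_star: float | None
    c_max: float | None
    ratios: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PhaseFitResult:
    """Slope/intercept of c* = m*·c_p + c^f with regression standard errors."""

    m_star: float
    c_f: float  # mM
    m_star_err: float
    c_f_err: float  # mM
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("the phase-line fit needs at least 2 points")


def detect_boundaries(
    series: PrecipitationSeries,
    retention_threshold: float = DEFAULT_RETENTION_THRESHOLD,
) -> PhaseBoundaries:
    """Locate C*, C** and C_max in one titration series.

    A point is condensed when the supernatant falls below
    `retention_threshold` × initial concentration.  The condensation
    window is the contiguous condensed run containing the minimum
    supernatant point (isolated sub-threshold points elsewhere are treated
    as noise).  C* is the linear interpolation of the threshold crossing
    between the last soluble and first condensed point on the rising side;
    C** likewise on the recovery side.  C_max is the anion concentration
    at minimum supernatant (ties broken toward the lower concentration).
    """
    if len(series.anion_conc) < 4:
        raise ValueError("need at least 4 titration points")
    level = retention_threshold * series.protein_conc_initial
    c = series.anion_conc
    sn = series.supernatant_conc
    condensed = sn < level
    if not condensed.any():
        return PhaseBoundaries(c_star=None, c_double_star=None, c_max=None)
    cond_all = np.flatnonzero(condensed)
    anchor = int(cond_all[np.argmin(sn[cond_all])])
    first = anchor
    while first > 0 and condensed[first - 1]:
        first -= 1
    last = anchor
    while last < len(condensed) - 1 and condensed[last + 1]:
        last += 1

    def crossing(i_sol: int, i_con: int) -> float | None:
        if i_sol < 0 or i_sol >= len(c):
            return None
        y0, y1 = sn[i_sol], sn[i_con]
        if y1 == y0:
            return float(c[i_con])
        t = (level - y0) / (y1 - y0)
        return float(c[i_sol] + t * (c[i_con] - c[i_sol]))

    c_star = crossing(first - 1, first)
    c_dstar = crossing(last + 1, last)
    c_max = float(c[anchor])
    ratios = {
        name: cs_cp(val, series.protein_conc_initial, series.protein_mw)
        for name, val in (("c_star", c_star), ("c_double_star", c_dstar), ("c_max", c_max))
        if val is not None
    }
    return PhaseBoundaries(c_star=c_star, c_double_star=c_dstar, c_max=c_max, ratios=ratios)


def fit_cstar_line(points) -> PhaseFitResult:
    """OLS fit of c* = m*·c_p + c^f over (protein molarity, C*) pairs.

    `points`: iterable of (protein_conc mol/L, c_star mol/L).  The slope
    m* is the number of ions bound per protein at the boundary; the
    intercept is returned in mM.
    """
    pts = np.asarray(list(points), float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least 2 (c_p, c*) points")
    cp, cstar = pts[:, 0], pts[:, 1]
    if np.ptp(cp) == 0:
        raise ValueError("degenerate abscissae: all protein concentrations equal")
    if len(pts) == 2:
        m = (cstar[1] - cstar[0]) / (cp[1] - cp[0])
        b = cstar[0] - m * cp[0]
        return PhaseFitResult(m_star=float(m), c_f=float(b * 1e3),
                              m_star_err=0.0, c_f_err=0.0, n_points=2)
    res = stats.linregress(cp, cstar)
    return PhaseFitResult(
        m_star=float(res.slope),
        c_f=float(res.intercept * 1e3),
        m_star_err=float(res.stderr),
        c_f_err=float(res.intercept_stderr * 1e3),
        n_points=len(pts),
    )


def charge_contribution(m_star: float, anion_valence: float) -> float:
    """Charge neutralized per protein at C*: |z| × m*."""
    if m_star < 0:
        raise ValueError("m_star must be non-negative")
    return abs(anion_valence) * m_star


def nacl_equivalent(target_ionic_strength: float, background_species=()) -> float:
    """NaCl concentration (mol/L) that brings the background to `target_ionic_strength`.

    For a 1:1 salt each mol/L adds exactly 1 mol/L of ionic strength, so
    c = I_target − I_background.
    """
    bg = ionic_strength(background_species)
    if target_ionic_strength < bg - 1e-15:
        raise ValueError("target ionic strength below the background")
    return max(0.0, target_ionic_strength - bg)


# ---------------------------------------------------------------------------
# CSV I/O  (columns: anion_mM, supernatant_mg_per_mL; '#key=value' header)
# ---------------------------------------------------------------------------

def write_precipitation_csv(series: PrecipitationSeries, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#protein_conc_initial={series.protein_conc_initial}\n")
        fh.write(f"#protein_mw={series.protein_mw}\n")
        fh.write(f"#anion_label={series.anion_label}\n")
        fh.write("anion_mM,supernatant_mg_per_mL\n")
        for a, s in zip(series.anion_conc, series.supernatant_conc):
            fh.write(f"{a:.10g},{s:.10g}\n")


def read_precipitation_csv(path: str | os.PathLike) -> PrecipitationSeries:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        else:
            data_lines.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(data_lines)))
    if "protein_conc_initial" not in meta:
        raise ValueError(f"missing '#protein_conc_initial=' header in {path}")
    return PrecipitationSeries(
        anion_conc=df["anion_mM"].to_numpy(),
        supernatant_conc=df["supernatant_mg_per_mL"].to_numpy(),
        protein_conc_initial=float(meta["protein_conc_initial"]),
        protein_mw=float(meta.get("protein_mw", HST5_MW)),
        anion_label=meta.get("anion_label", "TPP"),
    )
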