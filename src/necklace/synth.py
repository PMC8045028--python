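"""Synthetic inputs with known ground truth.

Three generators, all pure functions of their parameters and a seed:

* :func:`gen_system` — overlap-free initial configurations (self-avoiding
  random-walk chains plus uniformly placed explicit ions) for the MC engine;
* :func:`gen_guinier_curve` — Guinier-regime scattering curves with
  multiplicative lognormal noise, emulating buffer-subtracted low-q data;
* :func:`gen_precipitation` — anion-titration series with a condensation
  well between linearly protein-concentration-dependent boundaries, so the
  full boundary-detection → phase-line-fit pipeline can be validated
  against exact ground truth.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .energy import ForceField, SystemState, sites_from_topologies
from .phase import PrecipitationSeries
from .saxs import SAXSCurve
from .sequence import ChainTopology, HST5_MW

_MAX_RETRIES = 2000


def _overlaps(pos: np.ndarray, others: np.ndarray, min_dist: float,
              box: float, periodic: bool) -> bool:
    if len(others) == 0:
        return False
    d = others - pos
    if periodic:
        d -= box * np.round(d / box)
    return bool(np.any(np.sum(d * d, axis=1) < min_dist**2))


def gen_system(
    topologies: list[ChainTopology],
    n_ions: dict[str, int] | None = None,
    box_length: float = 250.0,
    seed: int = 0,
    ff: ForceField | None = None,
    periodic: bool = True,
) -> SystemState:
    """Grow chains as self-avoiding random walks (bond length r₀) and place
    ions uniformly, rejecting hard-sphere overlaps.

    Raises RuntimeError if a legal placement cannot be found within a
    bounded number of retries (overcrowded box).
    """
    ff = ff or ForceField()
    rng = np.random.default_rng(seed)
    n_ions = n_ions or {}
    placed: list[np.ndarray] = []

    def grown_chain(n_beads: int) -> np.ndarray:
        for _ in range(_MAX_RETRIES):
            pos = [rng.uniform(0, box_length, 3)]
            prior = np.array(placed).reshape(-1, 3)
            ok = not _overlaps(pos[0], prior, 2 * ff.bead_radius, box_length, periodic)
            while ok and len(pos) < n_beads:
                for _ in range(50):
                    v = rng.normal(size=3)
                    cand = pos[-1] + ff.r0 * v / np.linalg.norm(v)
                    obstacles = np.vstack([prior, np.array(pos)]) if len(pos) else prior
                    if not _overlaps(cand, obstacles, 2 * ff.bead_radius, box_length, periodic):
                        pos.append(cand)
                        break
                else:
                    ok = False
            if ok and len(pos) == n_beads:
                return np.array(pos)
        raise RuntimeError("chain placement failed: box too crowded")

    chain_coords = []
    for topo in topologies:
        coords = grown_chain(len(topo.beads))
        chain_coords.append(coords)
        placed.extend(coords)
    ion_species: list[str] = []
    ion_coords: list[np.ndarray] = []
    for sp, count in n_ions.items():
        for _ in range(count):
            for _ in range(_MAX_RETRIES):
                cand = rng.uniform(0, box_length, 3)
                prior = np.array(placed).reshape(-1, 3)
                if not _overlaps(cand, prior, 2 * ff.bead_radius, box_length, periodic):
                    ion_coords.append(cand)
                    ion_species.append(sp)
                    placed.append(cand)
                    break
            else:
                raise RuntimeError("ion placement failed: box too crowded")
    return sites_from_topologies(
        topologies,
        np.vstack(chain_coords) if chain_coords else np.empty((0, 3)),
        ff,
        ion_species=ion_species,
        ion_coords=np.array(ion_coords) if ion_coords else None,
        box_length=box_length,
        periodic=periodic,
    )


def gen_guinier_curve(
    rg: float,
    i0: float,
    q_grid=None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> SAXSCurve:
    """I(q) = i0·exp(−q²rg²/3) with multiplicative lognormal noise.

    The lognormal factor has mean 1 and coefficient of variation
    `noise_cv`; the σ column is noise_cv·I (absent when noise_cv = 0
    would make it zero — a tiny floor keeps the fit weights finite).
    """
    if rg <= 0 or i0 <= 0:
        raise ValueError("rg and i0 must be strictly positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if q_grid is None:
        q_grid = np.linspace(0.005, 1.2 / rg, 120)
    q = np.asarray(q_grid, float)
    ideal = i0 * np.exp(-(q**2) * rg**2 / 3.0)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        s2 = math.log(1.0 + noise_cv**2)
        factor = rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=q.size)
        intensity = ideal * factor
        sigma = noise_cv * intensity
    else:
        intensity = ideal
        sigma = None
    return SAXSCurve(q=q, intensity=intensity, sigma=sigma,
                     metadata={"rg_true": rg, "i0_true": i0,
                               "noise_cv": noise_cv, "seed": seed})


def _condensation_well(
    c_grid: np.ndarray,
    c_star: float,
    c_dstar: float,
    p0: float,
    depth: float,
    threshold: float,
    log_width: float,
) -> np.ndarray:
    """Smooth supernatant curve with exact threshold crossings at C*/C**.

    Shape: product of two logistic shoulders in log-concentration,
    normalized so the minimum equals `depth`, and offset-calibrated so the
    supernatant equals threshold×p0 exactly at C* and C**.
    """
    u = np.log(c_grid)
    u1, u2 = math.log(c_star), math.log(c_dstar)
    delta = (u2 - u1) / log_width
    a = (1.0 - threshold) * p0 / (p0 - depth)  # well fraction at the boundaries
    if not 0 < a < 1:
        raise ValueError("depth/threshold combination leaves no condensation well")

    def sigma(x):
        return 1.0 / (1.0 + np.exp(-x))

    def boundary_frac(b):
        return sigma(b) * sigma(delta + b) / sigma(delta / 2.0 + b) ** 2 - a

    b = brentq(boundary_frac, -delta / 2.0, 40.0, xtol=1e-14)
    x = (u - u1) / log_width
    well = sigma(x + b) * sigma(delta - x + b) / sigma(delta / 2.0 + b) ** 2
    return p0 - (p0 - depth) * well


def gen_precipitation(
    m_star: float,
    c_f: float,
    protein_concs=(2.6, 5.2, 7.8, 10.4),
    window_width_ratio: float = 6.0,
    depth: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    mw: float = HST5_MW,
    threshold: float = 0.95,
    n_points: int = 25,
    log_width: float = 0.15,
    anion_label: str = "TPP",
) -> list[PrecipitationSeries]:
    """Titration series with ground-truth boundaries C* = m*·c_p + c^f and
    C** = C*·window_width_ratio.

    `c_f` in mM, `protein_concs` in mg/mL, `depth` (minimum supernatant) in
    mg/mL; additive Gaussian noise of sd `noise_sd` truncated to the
    physical range [0, 1.05·c_p].  C* and C** are included in the anion
    grid, so with noise_sd = 0 boundary detection recovers them exactly.
    """
    if m_star < 0 or c_f <= 0 or depth <= 0 or noise_sd < 0:
        raise ValueError("parameters must be positive")
    if window_width_ratio <= 1:
        raise ValueError("window_width_ratio must exceed 1")
    if depth > min(protein_concs):
        raise ValueError("depth must not exceed the smallest protein concentration")
    rng = np.random.default_rng(seed)
    out = []
    for p0 in protein_concs:
        cp_mM = p0 / mw * 1e3
        c_star = m_star * cp_mM + c_f
        c_dstar = c_star * window_width_ratio
        grid = np.geomspace(c_star / 8.0, c_dstar * 8.0, n_points)
        grid = np.unique(np.concatenate([grid, [c_star, c_dstar]]))
        sn = _condensation_well(grid, c_star, c_dstar, p0, depth, threshold, log_width)
        if noise_sd > 0:
            sn = sn + rng.normal(0.0, noise_sd, sn.size)
        sn = np.clip(sn, 0.0, 1.05 * p0)
        out.append(
            PrecipitationSeries(
                anion_conc=grid,
                supernatant_conc=sn,
                protein_conc_initial=p0,
                protein_mw=mw,
                anion_label=anion_label,
            )
        )
    return out
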