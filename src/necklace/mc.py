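"""Metropolis Monte Carlo sampling of the bead-necklace model (NVT ensemble).

Move set: single-particle translations (amino-acid beads and explicit ions
share this class), pivot rotations about a random backbone bead, rigid
whole-chain translations and a slithering (reptation) move.  Single-particle
moves are proposed 20× more often than each of the other three.

A "step" is one proposed move.  Energy bookkeeping is incremental for
single-particle moves (ΔU of the moved site) and recomputed for chain
moves; the running total is revalidated against a full recomputation at a
fixed cadence.  Runs are reproducible: identical (seed, config, initial
state) gives an identical trajectory.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyCalculator, ForceField, SystemState

MOVE_TYPES = ("single_particle", "pivot", "chain_translate", "slither")

#: revalidation cadence (steps) and absolute drift tolerance (kT)
REVALIDATE_EVERY = 10_000
DRIFT_TOLERANCE = 1e-6


@dataclass
class MCConfig:
    """Run parameters.

    `move_amplitudes`: maximum single-particle displacement (Å), pivot
    rotation (rad) and chain translation (Å); amplitudes are auto-tuned
    toward 30–50 % acceptance during equilibration and frozen for
    production (tuning during production would violate detailed balance).
    """

    n_equilibration: int = 500_000
    n_production: int = 1_000_000
    seed: int = 0
    sample_interval: int = 500
    move_amplitudes: dict = field(
        default_factory=lambda: {"single_particle": 3.0, "pivot": math.pi, "chain_translate": 10.0}
    )
    move_weights: dict = field(
        default_factory=lambda: {
            "single_particle": 20.0,
            "pivot": 1.0,
            "chain_translate": 1.0,
            "slither": 1.0,
        }
    )
    tune: bool = True

    def __post_init__(self) -> None:
        if self.n_equilibration < 0 or self.n_production < 0:
            raise ValueError("step counts must be non-negative")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        for k, w in self.move_weights.items():
            if k not in MOVE_TYPES:
                raise ValueError(f"unknown move type {k!r}")
            if w < 0:
                raise ValueError("move weights must be non-negative")


@dataclass
class Trajectory:
    """Sampled production frames with energies and acceptance statistics."""

    frames: list
    energies: np.ndarray
    acceptance: dict
    config_echo: MCConfig
    final_state: SystemState
    tuned_amplitudes: dict

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def metropolis_accept(delta_u: float, rng_draw: float) -> bool:
    """Metropolis criterion: accept iff ΔU ≤ 0 or draw < exp(−ΔU); +∞ never."""
    if delta_u <= 0.0:
        return True
    if math.isinf(delta_u):
        return False
    return rng_draw < math.exp(-delta_u)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about `axis` (unit) by `angle`."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


class _Proposal:
    """Indices moved and their new (unwrapped-then-wrapped) positions."""

    __slots__ = ("idx", "new_pos", "move_type")

    def __init__(self, idx, new_pos, move_type):
        self.idx = np.atleast_1d(np.asarray(idx, int))
        self.new_pos = np.atleast_2d(np.asarray(new_pos, float))
        self.move_type = move_type


def _unwrapped_chain(state: SystemState, idx: np.ndarray) -> np.ndarray:
    """Chain coordinates unwrapped by bond-walking (bonds ≪ box)."""
    pos = state.coords[idx].copy()
    for k in range(1, len(idx)):
        step = state.displacement(pos[k - 1], state.coords[idx[k]])
        pos[k] = pos[k - 1] + step
    return pos


def _propose(state: SystemState, move_type: str, rng: np.random.Generator,
             amplitudes: dict, r0: float) -> _Proposal:
    if move_type == "single_particle":
        i = int(rng.integers(state.n_sites))
        disp = rng.uniform(-amplitudes["single_particle"], amplitudes["single_particle"], 3)
        return _Proposal([i], [state.coords[i] + disp], move_type)
    chains = state.chain_ids
    if not chains:
        raise ValueError(f"move {move_type!r} requires at least one chain")
    chain = chains[int(rng.integers(len(chains)))]
    idx = state.chain_indices(chain)
    if move_type == "chain_translate":
        disp = rng.uniform(-amplitudes["chain_translate"], amplitudes["chain_translate"], 3)
        return _Proposal(idx, state.coords[idx] + disp, move_type)
    if move_type == "pivot":
        if len(idx) < 3:
            raise ValueError("pivot requires a chain of length ≥ 3")
        pos = _unwrapped_chain(state, idx)
        h = int(rng.integers(len(idx)))
        left, right = np.arange(h), np.arange(h + 1, len(idx))
        if len(left) == len(right):
            arm = left if rng.random() < 0.5 else right
        else:
            arm = left if len(left) < len(right) else right
        angle = rng.uniform(-amplitudes["pivot"], amplitudes["pivot"])
        R = _rotation_matrix(_random_unit_vector(rng), angle)
        new_pos = pos.copy()
        if arm.size:
            new_pos[arm] = (pos[arm] - pos[h]) @ R.T + pos[h]
        return _Proposal(idx, new_pos, move_type)
    if move_type == "slither":
        if len(idx) < 2:
            raise ValueError("slither requires a chain of length ≥ 2")
        pos = _unwrapped_chain(state, idx)
        u = _random_unit_vector(rng)
        new_pos = np.empty_like(pos)
        if rng.random() < 0.5:  # head bead removed, grown at the tail
            new_pos[:-1] = pos[1:]
            new_pos[-1] = pos[-1] + r0 * u
        else:
            new_pos[1:] = pos[:-1]
            new_pos[0] = pos[0] + r0 * u
        return _Proposal(idx, new_pos, move_type)
    raise ValueError(f"unknown move type {move_type!r}")


def propose_move(state: SystemState, move_type: str, rng: np.random.Generator,
                 amplitudes: dict | None = None, r0: float = 4.1) -> SystemState:
    """Return a new state with one symmetric trial move applied.

    `single_particle` covers both amino-acid beads and explicit ions
    (`ion_translate` is accepted as an alias restricted to ion sites).
    """
    amps = dict(MCConfig().move_amplitudes)
    if amplitudes:
        amps.update(amplitudes)
    if move_type == "single_bead":
        # restrict the uniform site choice to protein beads
        bead_idx = np.flatnonzero(state.chain_id >= 0)
        if bead_idx.size == 0:
            raise ValueError("no protein beads to move")
        i = int(bead_idx[rng.integers(bead_idx.size)])
        disp = rng.uniform(-amps["single_particle"], amps["single_particle"], 3)
        prop = _Proposal([i], [state.coords[i] + disp], "single_particle")
    elif move_type == "ion_translate":
        ions = state.ion_indices
        if ions.size == 0:
            raise ValueError("no ions to move")
        i = int(ions[rng.integers(ions.size)])
        disp = rng.uniform(-amps["single_particle"], amps["single_particle"], 3)
        prop = _Proposal([i], [state.coords[i] + disp], "single_particle")
    else:
        prop = _propose(state, move_type, rng, amps, r0)
    new = state.copy()
    new.coords[prop.idx] = prop.new_pos
    if new.periodic:
        new.coords = np.mod(new.coords, new.box_length)
    return new


def _applicable_moves(state: SystemState, cfg: MCConfig) -> tuple[list[str], np.ndarray]:
    chains = state.chain_ids
    max_len = max((len(state.chain_indices(c)) for c in chains), default=0)
    moves, weights = [], []
    for m, w in cfg.move_weights.items():
        if w <= 0:
            continue
        if m in ("pivot", "chain_translate", "slither") and not chains:
            continue
        if m == "pivot" and max_len < 3:
            continue
        if m == "slither" and max_len < 2:
            continue
        moves.append(m)
        weights.append(w)
    if not moves:
        raise ValueError("no applicable move types")
    w = np.array(weights, float)
    return moves, np.cumsum(w / w.sum())


def run_mc(initial: SystemState, ff: ForceField, cfg: MCConfig) -> Trajectory:
    """Run equilibration + production Metropolis MC and collect a trajectory.

    The initial state must be free of hard-sphere overlaps.  Production
    frames are recorded every `cfg.sample_interval` steps (frame count =
    floor(n_production / sample_interval)).
    """
    state = initial.copy()
    calc = EnergyCalculator(state, ff)
    if calc.has_overlap(state):
        raise ValueError("initial state contains hard-sphere overlaps")
    u_total = calc.total(state)
    rng = np.random.default_rng(cfg.seed)
    amps = dict(cfg.move_amplitudes)
    moves, cumw = _applicable_moves(state, cfg)
    accepted = {m: 0 for m in moves}
    attempted = {m: 0 for m in moves}
    frames: list[SystemState] = []
    energies: list[float] = []
    tune_window = {m: [0, 0] for m in moves}  # accepted, attempted

    def do_step(tuning: bool) -> None:
        nonlocal u_total
        m = moves[int(np.searchsorted(cumw, rng.random(), side="right"))]
        attempted[m] += 1
        prop = _propose(state, m, rng, amps, ff.r0)
        if m == "single_particle":
            i = int(prop.idx[0])
            u_old = calc.site_energy(state, i)
            u_new = calc.site_energy(state, i, pos=prop.new_pos[0])
            delta = u_new - u_old
        else:
            u_old = calc.subset_energy(state, prop.idx)
            u_new = calc.subset_energy(state, prop.idx, pos=prop.new_pos)
            delta = u_new - u_old
        if metropolis_accept(delta, rng.random()):
            state.coords[prop.idx] = prop.new_pos
            if state.periodic:
                state.coords[prop.idx] = np.mod(state.coords[prop.idx], state.box_length)
            u_total += delta
            accepted[m] += 1
            if tuning:
                tune_window[m][0] += 1
        if tuning:
            tune_window[m][1] += 1

    def revalidate() -> None:
        nonlocal u_total
        u_ref = calc.total(state)
        if abs(u_ref - u_total) > DRIFT_TOLERANCE:
            raise RuntimeError(
                f"incremental energy drift {abs(u_ref - u_total):.3e} kT exceeds tolerance"
            )
        u_total = u_ref

    tunable = {"single_particle": (0.05, 30.0), "pivot": (0.01, math.pi),
               "chain_translate": (0.05, 60.0)}
    for step in range(cfg.n_equilibration):
        do_step(tuning=cfg.tune)
        if cfg.tune and (step + 1) % 2000 == 0:
            for m, (lo, hi) in tunable.items():
                if m not in tune_window:
                    continue
                acc, att = tune_window[m]
                if att >= 50:
                    frac = acc / att
                    if frac > 0.5:
                        amps[m] = min(amps[m] * 1.15, hi)
                    elif frac < 0.3:
                        amps[m] = max(amps[m] * 0.85, lo)
                tune_window[m] = [0, 0]
        if (step + 1) % REVALIDATE_EVERY == 0:
            revalidate()

    # freeze amplitudes; reset acceptance counters for production statistics
    accepted = {m: 0 for m in moves}
    attempted = {m: 0 for m in moves}
    for step in range(cfg.n_production):
        do_step(tuning=False)
        if (step + 1) % REVALIDATE_EVERY == 0:
            revalidate()
        if (step + 1) % cfg.sample_interval == 0:
            frames.append(state.copy())
            energies.append(u_total)

    return Trajectory(
        frames=frames,
        energies=np.array(energies),
        acceptance={m: (accepted[m], attempted[m]) for m in moves},
        config_echo=dataclasses.replace(cfg),
        final_state=state.copy(),
        tuned_amplitudes=dict(amps),
    )
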