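"""The discrete-event grid engine.

Five equally sized 2-D grids (dissolution, GI/tissue spaces A, B and C, and
plasma) hold per-site drug amounts; a scalar pool accumulates eliminated
drug.  One simulation cycle executes a fixed sequence of event classes —
elimination from plasma, then GI-to-plasma transfer, then dissolution-to-GI
transfer — followed by the remaining events (A-to-C, B-to-C, and dispersion on
each grid) in a per-cycle pseudorandom order.  Amounts are continuous
non-negative reals; stochastic transfers are Bernoulli per site per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AnalogParameters, TransferChannel

__all__ = [
    "AnalogState",
    "init_state",
    "intergrid_transfer",
    "dissolution_split_transfer",
    "disperse",
    "run_cycle",
    "run_simulation",
    "TRAJECTORY_COLUMNS",
]

GRID_NAMES = ("dissolution", "gi_a", "gi_b", "gi_c", "plasma")
TRAJECTORY_COLUMNS = ("cycle", "dissolution", "gi_a", "gi_b", "gi_c", "plasma", "eliminated")


@dataclass
class AnalogState:
    """Mutable per-run state: the five grids, the eliminated pool and clock."""

    clock: int
    dissolution: np.ndarray
    gi_a: np.ndarray
    gi_b: np.ndarray
    gi_c: np.ndarray
    plasma: np.ndarray
    eliminated: float = 0.0

    def grids(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in GRID_NAMES}

    def total(self) -> float:
        """Total drug in the system including the eliminated pool."""
        return float(sum(g.sum() for g in self.grids().values()) + self.eliminated)

    def totals_row(self) -> dict[str, float]:
        row = {name: float(getattr(self, name).sum()) for name in GRID_NAMES}
        row["eliminated"] = float(self.eliminated)
        row["cycle"] = self.clock
        return row


def init_state(params: AnalogParameters, seed: int | None = None) -> AnalogState:
    """Fresh state at clock 0: the dose spread uniformly over the dissolution
    grid, everything else empty.  ``seed`` is accepted for interface symmetry
    with :func:`run_simulation`; initialization itself is deterministic."""
    shape = (params.grid_height, params.grid_width)
    per_site = params.init_dose / (params.grid_width * params.grid_height)
    return AnalogState(
        clock=0,
        dissolution=np.full(shape, per_site, dtype=float),
        gi_a=np.zeros(shape, dtype=float),
        gi_b=np.zeros(shape, dtype=float),
        gi_c=np.zeros(shape, dtype=float),
        plasma=np.zeros(shape, dtype=float),
        eliminated=0.0,
    )


def _site_moves(
    src: np.ndarray, channel: TransferChannel, clock: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Per-site amounts moved by one firing of ``channel``, or None if the
    channel is still delay-gated (no RNG consumed in that case)."""
    if not channel.active(clock):
        return None
    p = rng.random(size=src.shape)
    fire = p <= channel.prob
    return np.where(fire, src * channel.fract, 0.0)


def intergrid_transfer(
    src: np.ndarray,
    dst: np.ndarray | None,
    channel: TransferChannel,
    clock: int,
    rng: np.random.Generator,
) -> float:
    """Apply one stochastic transfer event in place.

    ``dst`` is a grid of identical shape, or None for transfer into a scalar
    pool (the caller accumulates the returned total).  Returns the total
    amount moved.
    """
    if dst is not None and dst.shape != src.shape:
        raise ValueError(f"grid shape mismatch: {src.shape} vs {dst.shape}")
    moved = _site_moves(src, channel, clock, rng)
    if moved is None:
        return 0.0
    src -= moved
    if dst is not None:
        dst += moved
    return float(moved.sum())


def dissolution_split_transfer(
    state: AnalogState, params: AnalogParameters, rng: np.random.Generator
) -> float:
    """Dissolution-to-GI transfer with the A/B split: of each site's moved
    amount, ``diff_g_ratio`` goes to space A and the rest to space B."""
    moved = _site_moves(state.dissolution, params.channel("d_to_g"), state.clock, rng)
    if moved is None:
        return 0.0
    state.dissolution -= moved
    state.gi_a += moved * params.diff_g_ratio
    state.gi_b += moved * (1.0 - params.diff_g_ratio)
    return float(moved.sum())


def disperse(
    grid: np.ndarray, disperse_rate: float, evap_rate: float, iterations: int
) -> np.ndarray:
    """Local dispersion: per iteration each site sends ``disperse_rate/4`` of
    its amount to each von-Neumann neighbor, synchronously from a snapshot.
    Shares directed out of bounds stay at the source (no-flux boundary), so a
    uniform field is a fixed point.  After movement every site is multiplied
    by ``1 - evap_rate``.  Returns a new array; the input is untouched."""
    g = np.array(grid, dtype=float, copy=True)
    if g.size == 0:
        return g
    for _ in range(iterations):
        send = g * (disperse_rate / 4.0)
        new = g - 4.0 * send
        # inflow from the four neighbors
        new[1:, :] += send[:-1, :]
        new[:-1, :] += send[1:, :]
        new[:, 1:] += send[:, :-1]
        new[:, :-1] += send[:, 1:]
        # no-flux: out-of-bounds shares are retained at the boundary source
        new[0, :] += send[0, :]
        new[-1, :] += send[-1, :]
        new[:, 0] += send[:, 0]
        new[:, -1] += send[:, -1]
        g = new * (1.0 - evap_rate)
    return g


def run_cycle(
    state: AnalogState, params: AnalogParameters, rng: np.random.Generator
) -> AnalogState:
    """Execute one simulation cycle in place and advance the clock.

    Ordered event classes first: (1) elimination from plasma, (2) transfer
    from GI/tissue spaces A, B, C to plasma, (3) dissolution-to-GI with the
    A/B split.  The remaining events — A-to-C, B-to-C, and dispersion on each
    of the five grids — run in a pseudorandom permutation drawn per cycle.
    """
    clock = state.clock
    state.eliminated += intergrid_transfer(
        state.plasma, None, params.channel("p_to_e"), clock, rng
    )
    intergrid_transfer(state.gi_a, state.plasma, params.channel("ga_to_p"), clock, rng)
    intergrid_transfer(state.gi_b, state.plasma, params.channel("gb_to_p"), clock, rng)
    intergrid_transfer(state.gi_c, state.plasma, params.channel("gc_to_p"), clock, rng)
    dissolution_split_transfer(state, params, rng)

    g_to_c = params.channel("g_to_c")

    def a_to_c() -> None:
        intergrid_transfer(state.gi_a, state.gi_c, g_to_c, clock, rng)

    def b_to_c() -> None:
        intergrid_transfer(state.gi_b, state.gi_c, g_to_c, clock, rng)

    def disp(name: str):
        def run() -> None:
            setattr(
                state,
                name,
                disperse(
                    getattr(state, name),
                    params.disperse_rate,
                    params.evap_rate,
                    params.disperse_count,
                ),
            )

        return run

    events = [a_to_c, b_to_c] + [disp(name) for name in GRID_NAMES]
    for idx in rng.permutation(len(events)):
        events[idx]()

    state.clock = clock + 1
    return state


def run_simulation(
    params: AnalogParameters, n_cycles: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Run a fresh analog instantiation for ``n_cycles`` cycles.

    Measurements are taken at the end of every cycle and stamped with the
    post-cycle clock value (1..n_cycles), so row ``cycle`` holds the state
    after that many completed cycles.  Returns per-cycle totals of each grid
    and the eliminated pool.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    state = init_state(params, seed)
    rows = []
    for _ in range(n_cycles):
        run_cycle(state, params, rng)
        rows.append(state.totals_row())
    return pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))
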