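"""Independent oracles used only by the tests.

``scalar_simulation`` is a hand-coded scalar difference-equation model of
the deterministic limit: 1x1 grids, so every grid is a single number.  It
re-derives the per-cycle event schedule (ordered elimination, GI-to-plasma
and dissolution-to-GI steps, then a pseudorandom permutation of the
remaining events) from the seed alone, without touching the grid engine.

``trapezoid_auc`` is a brute-force linear-trapezoid area computation.
"""

from __future__ import annotations

import numpy as np


def trapezoid_auc(times, conc) -> float:
    total = 0.0
    for i in range(len(times) - 1):
        total += (times[i + 1] - times[i]) * (conc[i] + conc[i + 1]) / 2.0
    return total


def scalar_simulation(params, n_cycles: int, seed: int) -> np.ndarray:
    """Scalar trajectory for 1x1 grids: rows of
    (cycle, dissolution, gi_a, gi_b, gi_c, plasma, eliminated).

    Matches the engine bitwise when all transfer probabilities are 1 (the
    Bernoulli draws then never veto a transfer, but are still consumed so the
    per-cycle event permutation stays aligned with the engine's stream).
    """
    rng = np.random.default_rng(seed)
    diss = params.init_dose
    a = b = c = pl = 0.0
    elim = 0.0

    def transfer(amount: float, delay: int, fract: float, prob: float, clock: int):
        """Returns (moved, remaining); None moved while delay-gated."""
        if clock < delay:
            return None, amount
        u = rng.random()
        if u <= prob:
            moved = amount * fract
            return moved, amount - moved
        return 0.0, amount

    def disperse_1x1(value: float) -> float:
        # a single site retains all four outbound shares (no-flux), then loses
        # the evaporated fraction; arithmetic mirrors the grid kernel exactly
        for _ in range(params.disperse_count):
            send = value * (params.disperse_rate / 4.0)
            v = value - 4.0 * send
            v += send
            v += send
            v += send
            v += send
            value = v * (1.0 - params.evap_rate)
        return value

    rows = []
    for clock in range(n_cycles):
        moved, pl = transfer(pl, params.p_to_e_delay, params.p_to_e_fract,
                             params.p_to_e_prob, clock)
        if moved is not None:
            elim += moved
        moved, a = transfer(a, params.ga_to_p_delay, params.ga_to_p_fract,
                            params.ga_to_p_prob, clock)
        if moved is not None:
            pl += moved
        moved, b = transfer(b, params.gb_to_p_delay, params.gb_to_p_fract,
                            params.gb_to_p_prob, clock)
        if moved is not None:
            pl += moved
        moved, c = transfer(c, params.gc_to_p_delay, params.gc_to_p_fract,
                            params.gc_to_p_prob, clock)
        if moved is not None:
            pl += moved
        moved, diss = transfer(diss, params.d_to_g_delay, params.d_to_g_fract,
                               params.d_to_g_prob, clock)
        if moved is not None:
            a += moved * params.diff_g_ratio
            b += moved * (1.0 - params.diff_g_ratio)

        # remaining events in the engine's order convention:
        # 0 A->C, 1 B->C, 2..6 dispersion on dissolution, A, B, C, plasma
        for idx in rng.permutation(7):
            if idx == 0:
                moved, a = transfer(a, params.g_to_c_delay, params.g_to_c_fract,
                                    params.g_to_c_prob, clock)
                if moved is not None:
                    c += moved
            elif idx == 1:
                moved, b = transfer(b, params.g_to_c_delay, params.g_to_c_fract,
                                    params.g_to_c_prob, clock)
                if moved is not None:
                    c += moved
            elif idx == 2:
                diss = disperse_1x1(diss)
            elif idx == 3:
                a = disperse_1x1(a)
            elif idx == 4:
                b = disperse_1x1(b)
            elif idx == 5:
                c = disperse_1x1(c)
            else:
                pl = disperse_1x1(pl)
        rows.append((clock + 1, diss, a, b, c, pl, elim))
    return np.array(rows, dtype=float)
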