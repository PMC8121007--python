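"""Counter-style random streams for common-random-numbers (CRN) pairing.

Every stochastic decision in the simulation is addressed by the tuple
``(master seed, cycle, slot, individual)``.  Because the draw for a given
address never depends on the scenario being simulated, two scenario arms run
with the same master seed consume *identical* uniforms, so their contrast
reflects the intervention and not Monte-Carlo noise.

Slots partition decisions within a cycle (non-CVD death, CVD fatality, event
occurrence, event type) and, with ``cycle = 0``, the one-off care-cascade
draws (awareness, initiation, persistence, compliance, sector).
"""

from __future__ import annotations

import numpy as np

# Per-cycle decision slots.
SLOT_NONCVD_DEATH = 0
SLOT_CVD_FATALITY = 1
SLOT_EVENT = 2
SLOT_EVENT_TYPE = 3

# One-off cascade slots (used with cycle = 0).
SLOT_AWARE = 100
SLOT_INITIATE = 101
SLOT_PERSIST = 102
SLOT_COMPLY = 103
SLOT_SECTOR = 104


def _check_nonneg_int(name: str, value: int) -> None:
    if not isinstance(value, (int, np.integer)) or value < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")


def uniform_array(seed: int, cycle: int, slot: int, n: int) -> np.ndarray:
    """Return the ``n`` uniforms for all individuals at one (cycle, slot) address.

    Individual ``i`` (its position in the cohort) owns element ``i``; the
    array is a pure function of ``(seed, cycle, slot)``.
    """
    for name, v in (("seed", seed), ("cycle", cycle), ("slot", slot)):
        _check_nonneg_int(name, v)
    if n < 0:
        raise ValueError("n must be non-negative")
    ss = np.random.SeedSequence((int(seed), int(cycle), int(slot)))
    return np.random.default_rng(ss).random(int(n))


def paired_streams(seed: int, individual_id: int, cycle: int, slot: int) -> float:
    """Scalar uniform draw for one individual at one (cycle, slot) address.

    Identical arguments always yield the identical draw, regardless of which
    scenario is being run; distinct slots are independent streams.
    """
    _check_nonneg_int("individual_id", individual_id)
    return float(uniform_array(seed, cycle, slot, individual_id + 1)[individual_id])
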