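"""Block-design timing for the two scanning sessions.

Each run consists of 16 experimental blocks of 16 s (4 conditions x 4
repeats, pseudo-random order) interleaved with seven 16-s fixation blocks:
one at the start, one at the end, and one after the 3rd, 5th, 8th, 11th and
13th experimental blocks.  In the binocular session every experimental
block is followed by a 2-s response window (modeled as rest), giving a
400-s run; the nonstereoscopic session has no response window (368 s).
TR is 2 s throughout, so all block boundaries are TR-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SESSION_CONDITIONS", "ExperimentDesign", "make_design"]

SESSION_CONDITIONS: dict[str, tuple[str, ...]] = {
    "binocular": ("mirror", "painted", "anti_mirror", "flat"),
    "nonstereoscopic": ("glossy", "matte", "rough", "textured"),
}

RESPONSE_GAP_S = {"binocular": 2.0, "nonstereoscopic": 0.0}
RUN_RANGES = {"binocular": (7, 10), "nonstereoscopic": (8, 10)}

# experimental-block counts after which a fixation block is inserted
_FIXATION_AFTER = (3, 5, 8, 11, 13)
N_EXP_BLOCKS = 16
N_FIX_BLOCKS = 7
BLOCK_S = 16.0
TR_S = 2.0
BLOCK_TRS = 8


@dataclass(frozen=True)
class ExperimentDesign:
    """Timing grid and per-run condition orders for one subject session."""

    session: str
    n_runs: int
    seed: int
    block_orders: tuple[tuple[str, ...], ...] = field(repr=False)
    tr: float = TR_S
    block_len_trs: int = BLOCK_TRS

    @property
    def conditions(self) -> tuple[str, ...]:
        return SESSION_CONDITIONS[self.session]

    @property
    def response_gap_s(self) -> float:
        return RESPONSE_GAP_S[self.session]

    @property
    def run_duration_s(self) -> float:
        """Scheduled run length: 16 x (16 + gap) + 7 x 16 seconds."""
        return N_EXP_BLOCKS * (BLOCK_S + self.response_gap_s) + N_FIX_BLOCKS * BLOCK_S

    @property
    def n_trs_per_run(self) -> int:
        return int(round(self.run_duration_s / self.tr))

    def events(self, run: int) -> pd.DataFrame:
        """BIDS-style event table (onset, duration, trial_type) for one run."""
        order = self.block_orders[run]
        rows = []
        t = 0.0
        n_done = 0
        rows.append({"onset": t, "duration": BLOCK_S, "trial_type": "fixation"})
        t += BLOCK_S
        for cond in order:
            rows.append({"onset": t, "duration": BLOCK_S, "trial_type": cond})
            t += BLOCK_S + self.response_gap_s
            n_done += 1
            if n_done in _FIXATION_AFTER:
                rows.append({"onset": t, "duration": BLOCK_S, "trial_type": "fixation"})
                t += BLOCK_S
        rows.append({"onset": t, "duration": BLOCK_S, "trial_type": "fixation"})
        t += BLOCK_S
        df = pd.DataFrame(rows)
        assert t == self.run_duration_s
        return df

    def block_onset_trs(self, run: int, trial_types: str | None = None) -> pd.DataFrame:
        """Events with onsets expressed in TR indices (adds ``onset_tr``)."""
        ev = self.events(run)
        ev["onset_tr"] = (ev["onset"] / self.tr).round().astype(int)
        if trial_types == "experimental":
            ev = ev[ev["trial_type"] != "fixation"]
        elif trial_types == "fixation":
            ev = ev[ev["trial_type"] == "fixation"]
        return ev.reset_index(drop=True)


def make_design(session: str, n_runs: int, seed: int) -> ExperimentDesign:
    """Build a seeded pseudo-random design for one subject session.

    Each run contains every condition exactly four times in a seeded random
    order.  ``n_runs`` outside the session's observed range (7-10 binocular,
    8-10 nonstereoscopic) is rejected unless obviously intentional (>= 2).
    """
    if session not in SESSION_CONDITIONS:
        raise ValueError(f"unknown session {session!r}; choose from {sorted(SESSION_CONDITIONS)}")
    if n_runs < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out analyses")
    rng = np.random.default_rng(seed)
    conds = SESSION_CONDITIONS[session]
    base = np.repeat(np.arange(4), 4)
    orders = tuple(
        tuple(conds[i] for i in rng.permutation(base)) for _ in range(n_runs)
    )
    return ExperimentDesign(session=session, n_runs=n_runs, seed=seed, block_orders=orders)
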