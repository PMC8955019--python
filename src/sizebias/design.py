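"""Trial-table construction for a blocked 2AFC size-discrimination session.

The experiment presents two circular images side by side and asks which looks
larger.  Four comparison conditions are run: two *direct* comparisons between
familiar objects (Balls: soccer ball vs. tennis ball; Coins: 10-cent vs. 2-euro
coin) and two *indirect* comparisons of each ball against an unfamiliar grey
disc (Soccer, Tennis).  On every trial the test image is scaled by a signed
percentage of the reference image; each (condition, size) cell is shown with
the test on the left and on the right an equal number of times.

All sizes are handled as fractions of the reference image, never as physical
lengths: on an uncontrolled display the absolute scale is unknown, while the
ratio of the two images is exact.  The nominal on-screen geometry is kept as
config metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyConfig",
    "TRIAL_COLUMNS",
    "INVERTED_CONDITIONS",
    "build_trial_table",
    "plan_blocks",
    "shuffle_trials",
]

#: Conditions whose fitted bias is sign-inverted during analysis so that a
#: negative bias always means assimilation (the test object's image is judged
#: larger than it is, i.e. perception is pulled toward the larger familiar
#: size).  For the coins the nominal reference (2-euro coin) is the *larger*
#: familiar object, opposite to every other condition, hence the inversion.
INVERTED_CONDITIONS = frozenset({"Coins"})

#: Column order of the long-format trial table.
TRIAL_COLUMNS = (
    "participant_id",
    "block",
    "trial",
    "condition",
    "size_diff_pct",
    "test_side",
    "response",
)


def _default_size_levels() -> tuple[float, ...]:
    return tuple(np.arange(-10.0, 10.0 + 1e-9, 2.5))


@dataclass(frozen=True)
class StudyConfig:
    """Design parameters of one session.

    Defaults reproduce the full factorial design: 4 conditions x 9 size
    levels (-10% ... +10% in 2.5% steps) x 2 sides x 5 repetitions = 360
    trials, with Balls/Soccer/Tennis sharing one block and Coins in another.
    """

    conditions: tuple[str, ...] = ("Balls", "Coins", "Soccer", "Tennis")
    size_levels: tuple[float, ...] = field(default_factory=_default_size_levels)
    repetitions_per_side: int = 5
    reference_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "Balls": "tennis ball",
            "Coins": "2-euro coin",
            "Soccer": "grey disc",
            "Tennis": "grey disc",
        }
    )
    test_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "Balls": "soccer ball",
            "Coins": "10-cent coin",
            "Soccer": "soccer ball",
            "Tennis": "tennis ball",
        }
    )
    #: condition -> block id; blocks are presented contiguously.
    block_plan: Mapping[str, int] = field(
        default_factory=lambda: {"Balls": 0, "Soccer": 0, "Tennis": 0, "Coins": 1}
    )
    #: Real-world diameters (cm) of the depicted objects; the grey disc has
    #: none.  Used for documentation/plots only — analysis is scale free.
    real_diameters_cm: Mapping[str, float | None] = field(
        default_factory=lambda: {
            "tennis ball": 6.7,
            "soccer ball": 22.0,
            "10-cent coin": 1.975,
            "2-euro coin": 2.575,
            "grey disc": None,
        }
    )
    # Nominal on-screen geometry (approximate, for a 14-inch display).
    # Metadata only: every analysed quantity is a percentage of the reference.
    image_diameter_cm: float = 5.0
    image_separation_cm: float = 15.0

    def validate(self) -> None:
        if not self.size_levels:
            raise ValueError("size_levels must be non-empty")
        if self.repetitions_per_side < 1:
            raise ValueError("repetitions_per_side must be >= 1")
        levels = np.asarray(self.size_levels, dtype=float)
        if not np.allclose(np.sort(levels), -np.sort(levels)[::-1]):
            raise ValueError("size_levels must be symmetric about 0")
        for cond in self.conditions:
            if cond not in self.reference_map or cond not in self.test_map:
                raise ValueError(f"condition {cond!r} lacks a reference/test object")
            if cond not in self.block_plan:
                raise ValueError(f"condition {cond!r} missing from block_plan")

    @property
    def n_trials(self) -> int:
        return len(self.conditions) * len(self.size_levels) * 2 * self.repetitions_per_side


def build_trial_table(config: StudyConfig, participant_id: str) -> pd.DataFrame:
    """Fully crossed trial table for one participant, in deterministic order.

    Rows are the factorial expansion conditions x size_levels x {left, right}
    x repetitions.  ``size_diff_pct`` is the test image's diameter minus the
    reference's, as a percentage of the reference: positive means the test
    image is physically larger on screen.  The ``response`` column (which
    side was judged larger) is empty until simulated or collected.
    """
    config.validate()
    rows = []
    for cond in config.conditions:
        for size in config.size_levels:
            for side in ("left", "right"):
                for _ in range(config.repetitions_per_side):
                    rows.append((participant_id, config.block_plan[cond], cond, float(size), side))
    table = pd.DataFrame(rows, columns=["participant_id", "block", "condition", "size_diff_pct", "test_side"])
    table["trial"] = np.arange(len(table))
    table["response"] = pd.Series([pd.NA] * len(table), dtype="object")
    return table.loc[:, list(TRIAL_COLUMNS)]


def plan_blocks(table: pd.DataFrame, config: StudyConfig, block_order: int = 0) -> pd.DataFrame:
    """Order the table so each block is contiguous; ``block_order`` picks which
    block comes first (counterbalanced across participants by alternating it).

    ``block_order = 0`` presents blocks in ascending block-id order (the ball
    block, then Coins under the default plan); ``1`` reverses them.
    """
    config.validate()
    missing = set(table["condition"]) - set(config.block_plan)
    if missing:
        raise ValueError(f"conditions missing from block_plan: {sorted(missing)}")
    block_ids = sorted(set(config.block_plan[c] for c in table["condition"].unique()))
    if block_order % 2 == 1:
        block_ids = block_ids[::-1]
    order = {b: i for i, b in enumerate(block_ids)}
    out = (
        table.assign(_key=table["block"].map(order))
        .sort_values(["_key", "trial"], kind="stable")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    out["trial"] = np.arange(len(out))
    return out


def shuffle_trials(table: pd.DataFrame, seed: int | np.random.Generator) -> pd.DataFrame:
    """Permute trials uniformly at random *within* each block.

    Blocks keep their relative order and contiguity; the multiset of rows is
    unchanged.  Same seed, same order.
    """
    rng = np.random.default_rng(seed)
    pieces = []
    # groupby(sort=False) preserves block presentation order
    for _, block in table.groupby("block", sort=False):
        perm = rng.permutation(len(block))
        pieces.append(block.iloc[perm])
    out = pd.concat(pieces).reset_index(drop=True)
    out["trial"] = np.arange(len(out))
    return out
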