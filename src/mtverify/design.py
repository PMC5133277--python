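"""Stimulus design combinatorics for the sentence-scene verification experiment.

A base set of ``n_scenes`` photographic scenes is crossed with two two-level
within-item factors — plausibility (is the depicted event consistent with
world knowledge?) and congruency (do sentence and scene convey the same
content?) — yielding an item bank of ``4 * n_scenes`` sentence-scene
pairings.  The bank is partitioned into Latin-square lists so that no
participant ever sees the same base scene twice, and per-participant trial
schedules are drawn from the lists with balanced condition cells.

Two between-participants factors complete the design: the order of modality
presentation (sentence-first vs. scene-first) and the left/right
counterbalancing of the yes/no response buttons.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

PLAUSIBILITY_LEVELS = ("plausible", "implausible")
CONGRUENCY_LEVELS = ("congruent", "incongruent")
ORDER_LEVELS = ("sentence_first", "scene_first")
COUNTERBALANCE_LEVELS = ("yes_left", "yes_right")

#: The four cells of the plausibility x congruency cross, in canonical order.
CONDITION_CELLS: tuple[tuple[str, str], ...] = tuple(
    itertools.product(PLAUSIBILITY_LEVELS, CONGRUENCY_LEVELS)
)


def build_item_bank(n_scenes: int) -> pd.DataFrame:
    """Cross every base scene with the four plausibility x congruency cells.

    Parameters
    ----------
    n_scenes
        Number of unique base scenes (225 in the reference design).

    Returns
    -------
    pandas.DataFrame
        One row per item with columns ``scene_id`` (1-based),
        ``plausibility`` and ``congruency``; ``4 * n_scenes`` rows in total.
    """
    if not isinstance(n_scenes, (int, np.integer)) or n_scenes < 1:
        raise ValueError(f"n_scenes must be a positive integer, got {n_scenes!r}")
    rows = [
        (scene, plaus, cong)
        for scene in range(1, n_scenes + 1)
        for plaus, cong in CONDITION_CELLS
    ]
    return pd.DataFrame(rows, columns=["scene_id", "plausibility", "congruency"])


def build_latin_lists(bank: pd.DataFrame, n_lists: int = 4, seed: int = 0) -> pd.DataFrame:
    """Partition an item bank into Latin-square lists.

    Each list holds every base scene exactly once, and across the four lists
    each scene contributes each condition cell exactly once.  The rotation of
    cells over scenes is randomized by ``seed`` (which scene starts in which
    cell), but the Latin structure itself is deterministic.

    Returns a copy of the bank with an additional ``list_id`` column
    (1-based).
    """
    n_cells = len(CONDITION_CELLS)
    if n_lists != n_cells:
        raise ValueError(
            f"n_lists must equal the number of condition cells ({n_cells}) "
            f"for a proper Latin rotation, got {n_lists}"
        )
    if len(bank) % n_lists != 0:
        raise ValueError(
            f"bank size {len(bank)} is not divisible by n_lists {n_lists}"
        )
    scenes = np.sort(bank["scene_id"].unique())
    rng = np.random.default_rng(seed)
    # per-scene phase of the cell rotation; balanced so every list holds a
    # near-equal number of items from each condition cell
    phases = rng.permutation(
        np.resize(np.arange(n_cells), len(scenes))
    )
    cell_index = {cell: i for i, cell in enumerate(CONDITION_CELLS)}

    out = bank.copy()
    scene_phase = dict(zip(scenes.tolist(), phases.tolist()))
    idx = out.apply(
        lambda r: cell_index[(r["plausibility"], r["congruency"])], axis=1
    )
    out["list_id"] = (
        (idx.to_numpy() - out["scene_id"].map(scene_phase).to_numpy()) % n_cells
    ) + 1
    return out


def build_schedules(
    lists: pd.DataFrame,
    n_participants: int,
    per_participant: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-participant trial schedules from the Latin lists.

    Participants are assigned to lists round-robin; the between-participants
    factors (order of modality presentation, yes/no counterbalancing) are
    crossed as evenly as possible with list assignment.  Within a schedule
    the four condition cells are balanced (``per_participant // 4`` each,
    remainder spread deterministically), and item usage within each
    (list, cell) pool is rotated round-robin across participants so that
    across the whole experiment every bank item is used an equal number of
    times up to remainder.

    Returns
    -------
    pandas.DataFrame
        One row per scheduled trial: ``participant_id``, ``trial_index``
        (0-based presentation position, randomized per participant),
        ``list_id``, ``scene_id``, ``plausibility``, ``congruency``,
        ``order``, ``counterbalance``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be positive")
    list_ids = np.sort(lists["list_id"].unique())
    n_lists = len(list_ids)
    list_sizes = lists.groupby("list_id").size()
    if per_participant > int(list_sizes.min()):
        raise ValueError(
            f"per_participant {per_participant} exceeds smallest list size "
            f"{int(list_sizes.min())}"
        )
    rng = np.random.default_rng(seed)

    # per (list, cell): shuffled item pool and a cyclic cursor
    pools: dict[tuple[int, tuple[str, str]], np.ndarray] = {}
    cursors: dict[tuple[int, tuple[str, str]], int] = {}
    for lid in list_ids:
        sub = lists[lists["list_id"] == lid]
        for cell in CONDITION_CELLS:
            plaus, cong = cell
            pool = sub[
                (sub["plausibility"] == plaus) & (sub["congruency"] == cong)
            ]["scene_id"].to_numpy()
            pools[(lid, cell)] = rng.permutation(pool)
            cursors[(lid, cell)] = 0

    base = per_participant // 4
    remainder = per_participant % 4

    rows = []
    for p in range(n_participants):
        pid = p + 1
        lid = int(list_ids[p % n_lists])
        within = p // n_lists  # index among participants sharing this list
        # cycle the four (order, counterbalance) combinations, phase-staggered
        # by list, so both factors and their crossing stay balanced
        combo = (within + p % n_lists) % 4
        order = ORDER_LEVELS[combo % 2]
        counterbalance = COUNTERBALANCE_LEVELS[combo // 2]

        trial_items: list[tuple[int, str, str]] = []
        # rotate which cells absorb the remainder so cells stay near-balanced
        extra_cells = {
            CONDITION_CELLS[(p + j) % 4] for j in range(remainder)
        }
        for cell in CONDITION_CELLS:
            take = base + (1 if cell in extra_cells else 0)
            pool = pools[(lid, cell)]
            if take > len(pool):
                raise ValueError(
                    f"cell {cell} of list {lid} holds {len(pool)} items; "
                    f"cannot draw {take} without repeating a scene"
                )
            cur = cursors[(lid, cell)]
            picked = [int(pool[(cur + j) % len(pool)]) for j in range(take)]
            cursors[(lid, cell)] = (cur + take) % len(pool)
            trial_items.extend((s, cell[0], cell[1]) for s in picked)

        perm = rng.permutation(len(trial_items))
        for trial_index, k in enumerate(perm):
            scene, plaus, cong = trial_items[k]
            rows.append(
                (pid, trial_index, lid, scene, plaus, cong, order, counterbalance)
            )

    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "trial_index",
            "list_id",
            "scene_id",
            "plausibility",
            "congruency",
            "order",
            "counterbalance",
        ],
    )


def participant_table(schedules: pd.DataFrame) -> pd.DataFrame:
    """Collapse a schedule table to one row per participant."""
    return (
        schedules[["participant_id", "list_id", "order", "counterbalance"]]
        .drop_duplicates()
        .sort_values("participant_id")
        .reset_index(drop=True)
    )
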