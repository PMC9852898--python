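"""Food-image inventories and constrained pair-sequence generation.

Each eating context (healthy / typical / unrestricted) gets its own image
inventory, stratified by the number of nutrient warning labels (NWL, 0-3) a
food carries; no image is shared between contexts. Within a context, a
participant's choice sequence pairs images whose NWL counts differ, with
every unordered count combination shown equally often, under two ordering
constraints: an image must skip at least two pairs before reappearing, and
images with the same NWL count may not occupy the same side for more than
three consecutive pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FoodImage",
    "ContextInventory",
    "TrialSpec",
    "ConstraintReport",
    "NWL_COMBOS",
    "DEFAULT_STRATA",
    "build_inventories",
    "generate_pair_sequence",
    "validate_sequence",
]

# All six unordered pairs of distinct NWL counts.
NWL_COMBOS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
)

# Per-context stratum sizes (NWL count -> number of images).
DEFAULT_STRATA: dict[str, dict[int, int]] = {
    "healthy": {0: 8, 1: 6, 2: 8, 3: 10},
    "typical": {0: 7, 1: 6, 2: 7, 3: 9},
    "unrestricted": {0: 8, 1: 6, 2: 8, 3: 11},
}


@dataclass(frozen=True)
class FoodImage:
    image_id: str
    category: str
    nwl_count: int
    kcal: float
    sat_fat_g: float
    sugar_g: float
    sodium_mg: float

    def __post_init__(self) -> None:
        if self.nwl_count not in (0, 1, 2, 3):
            raise ValueError(f"nwl_count must be 0..3, got {self.nwl_count}")
        for name in ("kcal", "sat_fat_g", "sugar_g", "sodium_mg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ContextInventory:
    context: str
    images: list[FoodImage]

    @property
    def strata_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for img in self.images:
            counts[img.nwl_count] = counts.get(img.nwl_count, 0) + 1
        return counts

    def by_stratum(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in (0, 1, 2, 3)}
        for img in self.images:
            out[img.nwl_count].append(img.image_id)
        return out

    @property
    def nwl_of(self) -> dict[str, int]:
        return {img.image_id: img.nwl_count for img in self.images}


@dataclass(frozen=True)
class TrialSpec:
    position: int
    left_image: str
    right_image: str
    nwl_left: int
    nwl_right: int
    context: str

    def __post_init__(self) -> None:
        if self.left_image == self.right_image:
            raise ValueError("a pair cannot show the same image twice")
        if self.nwl_left == self.nwl_right:
            raise ValueError("pair members must differ in NWL count")

    @property
    def combo(self) -> tuple[int, int]:
        return tuple(sorted((self.nwl_left, self.nwl_right)))  # type: ignore


class StratumShortfallError(ValueError):
    """Raised when a context requests more images from a stratum than exist."""

    def __init__(self, context: str, stratum: int, requested: int, available: int):
        self.context, self.stratum = context, stratum
        self.requested, self.available = requested, available
        super().__init__(
            f"context {context!r}: stratum {stratum} NWL needs {requested} "
            f"images but only {available} remain (shortfall {requested - available})"
        )


def build_inventories(
    image_table: pd.DataFrame,
    strata_spec: Mapping[str, Mapping[int, int]] = DEFAULT_STRATA,
    rng: np.random.Generator | None = None,
) -> dict[str, ContextInventory]:
    """Partition an image table into per-context inventories by stratified
    sampling without replacement; no image is assigned to two contexts.

    ``image_table`` needs columns image_id, category, nwl_count, kcal,
    sat_fat_g, sugar_g, sodium_mg. With ``rng`` the draw within each stratum
    is randomized; otherwise table order is used.
    """
    required = {"image_id", "category", "nwl_count", "kcal", "sat_fat_g", "sugar_g", "sodium_mg"}
    missing = required - set(image_table.columns)
    if missing:
        raise ValueError(f"image table missing columns: {sorted(missing)}")
    if image_table["image_id"].duplicated().any():
        raise ValueError("image ids must be unique")

    pools: dict[int, list[dict]] = {}
    for c in (0, 1, 2, 3):
        rows = image_table.loc[image_table["nwl_count"] == c].to_dict("records")
        if rng is not None:
            order = rng.permutation(len(rows))
            rows = [rows[i] for i in order]
        pools[c] = rows

    inventories: dict[str, ContextInventory] = {}
    for context, spec in strata_spec.items():
        images: list[FoodImage] = []
        for stratum, count in sorted(spec.items()):
            if len(pools[stratum]) < count:
                raise StratumShortfallError(context, stratum, count, len(pools[stratum]))
            taken, pools[stratum] = pools[stratum][:count], pools[stratum][count:]
            images.extend(
                FoodImage(
                    image_id=str(r["image_id"]),
                    category=str(r["category"]),
                    nwl_count=int(r["nwl_count"]),
                    kcal=float(r["kcal"]),
                    sat_fat_g=float(r["sat_fat_g"]),
                    sugar_g=float(r["sugar_g"]),
                    sodium_mg=float(r["sodium_mg"]),
                )
                for r in taken
            )
        inventories[context] = ContextInventory(context=context, images=images)
    return inventories


class SequenceInfeasibleError(RuntimeError):
    pass


_REAPPEAR_GAP = 2  # an image must skip this many pairs before returning
_MAX_SIDE_RUN = 3  # same NWL count on the same side at most this many pairs in a row


def generate_pair_sequence(
    inventory: ContextInventory,
    pairs_per_combo: int = 15,
    rng: np.random.Generator | None = None,
    max_retries: int = 1000,
) -> list[TrialSpec]:
    """Pseudo-random pair sequence for one context.

    Exactly ``pairs_per_combo`` pairs per NWL-count combination, in shuffled
    order; rejection sampling with full restart when the reappearance-gap or
    side-run constraint cannot be extended at some position.
    """
    rng = np.random.default_rng() if rng is None else rng
    strata = inventory.by_stratum()
    for combo in NWL_COMBOS:
        for c in combo:
            if len(strata[c]) < 2:
                raise SequenceInfeasibleError(
                    f"stratum {c} of context {inventory.context!r} has "
                    f"{len(strata[c])} images; at least 2 required"
                )
    combo_order = [combo for combo in NWL_COMBOS for _ in range(pairs_per_combo)]
    last_fail = "none"
    for _ in range(max_retries):
        order = [combo_order[i] for i in rng.permutation(len(combo_order))]
        seq: list[TrialSpec] = []
        recent: list[set[str]] = []  # image ids of the preceding pairs
        runs: dict[tuple[int, str], int] = {}
        ok = True
        for pos, combo in enumerate(order):
            sides = [(combo[0], combo[1]), (combo[1], combo[0])]
            rng.shuffle(sides)
            placed = False
            for c_left, c_right in sides:
                if runs.get((c_left, "L"), 0) >= _MAX_SIDE_RUN:
                    continue
                if runs.get((c_right, "R"), 0) >= _MAX_SIDE_RUN:
                    continue
                forbidden = set().union(*recent[-_REAPPEAR_GAP:]) if recent else set()
                cand_left = [i for i in strata[c_left] if i not in forbidden]
                cand_right = [i for i in strata[c_right] if i not in forbidden]
                if not cand_left or not cand_right:
                    last_fail = "reappearance-gap"
                    continue
                left = cand_left[rng.integers(len(cand_left))]
                right = cand_right[rng.integers(len(cand_right))]
                seq.append(
                    TrialSpec(
                        position=pos,
                        left_image=left,
                        right_image=right,
                        nwl_left=c_left,
                        nwl_right=c_right,
                        context=inventory.context,
                    )
                )
                recent.append({left, right})
                for c in (0, 1, 2, 3):
                    runs[(c, "L")] = runs.get((c, "L"), 0) + 1 if c == c_left else 0
                    runs[(c, "R")] = runs.get((c, "R"), 0) + 1 if c == c_right else 0
                placed = True
                break
            if not placed:
                if last_fail == "none":
                    last_fail = "side-run"
                ok = False
                break
        if ok:
            return seq
    raise SequenceInfeasibleError(
        f"no feasible sequence for context {inventory.context!r} after "
        f"{max_retries} restarts (last violated constraint: {last_fail})"
    )


@dataclass
class ConstraintReport:
    """Violations found by the independent sequence checker."""

    census_violations: list[str] = field(default_factory=list)
    reappearance_violations: list[tuple[int, str]] = field(default_factory=list)
    side_run_violations: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.census_violations
            or self.reappearance_violations
            or self.side_run_violations
        )

    def counts(self) -> dict[str, int]:
        return {
            "census": len(self.census_violations),
            "reappearance": len(self.reappearance_violations),
            "side_run": len(self.side_run_violations),
        }


def validate_sequence(
    seq: Sequence[TrialSpec],
    pairs_per_combo: int | None = None,
) -> ConstraintReport:
    """Audit a sequence against the three design rules.

    Implemented by direct scanning, independently of the generator: combo
    census (when ``pairs_per_combo`` given), reappearance gap >= 2 pairs, and
    no NWL count on one side for more than 3 consecutive pairs.
    """
    report = ConstraintReport()
    if pairs_per_combo is not None:
        census: dict[tuple[int, int], int] = {c: 0 for c in NWL_COMBOS}
        for trial in seq:
            census[trial.combo] = census.get(trial.combo, 0) + 1
        for combo, n in census.items():
            if n != pairs_per_combo:
                report.census_violations.append(
                    f"combo {combo}: {n} pairs, expected {pairs_per_combo}"
                )

    last_seen: dict[str, int] = {}
    for pos, trial in enumerate(seq):
        for img in (trial.left_image, trial.right_image):
            if img in last_seen and pos - last_seen[img] <= _REAPPEAR_GAP:
                report.reappearance_violations.append((pos, img))
            last_seen[img] = pos

    # side runs: longest stretch of consecutive pairs with count c on side s
    for c in (0, 1, 2, 3):
        for side, attr in (("L", "nwl_left"), ("R", "nwl_right")):
            run = 0
            for pos, trial in enumerate(seq):
                if getattr(trial, attr) == c:
                    run += 1
                    if run == _MAX_SIDE_RUN + 1:
                        report.side_run_violations.append((pos, c, side))
                else:
                    run = 0
    return report
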