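"""Recording-date-disjoint train/validation/test splits.

Classifiers trained on clip datasets recorded in sessions can learn to
recognize the *session* (background signature of a recording night) instead
of the animal, so naive random splits leak label information.  The defence
is to keep the recording dates of train, validation and test disjoint
within every species: models are then validated and tested only on days
they never saw in training.

Assignment is greedy: within each species, date groups are processed
largest-first (ties shuffled by the seed) and each group goes to the split
with the largest remaining deficit against its target clip count.  Species
with fewer than ``min_dates_per_species`` distinct dates cannot be split
disjointly in a useful way; they are flagged and assigned entirely to
train.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = ["SplitSpec", "split_by_date", "verify_split", "SPLIT_NAMES"]

SPLIT_NAMES = ("train", "val", "test")


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    min_dates_per_species: int = 3

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")
        if self.min_dates_per_species < 1:
            raise ValueError("min_dates_per_species must be >= 1")


def split_by_date(manifest: pd.DataFrame, spec: SplitSpec | None = None) -> pd.DataFrame:
    """Assign every manifest row a split label, date-disjoint per species.

    Returns a copy of the manifest with the ``split`` column filled.
    Deterministic for a given seed.
    """
    spec = spec or SplitSpec()
    if manifest.empty:
        raise ValueError("empty manifest")
    df = manifest.copy()
    for col in ("species", "date"):
        if df[col].isna().any() or (df[col].astype(str).str.strip() == "").any():
            raise ValueError(f"every manifest row needs a non-empty {col!r}")
    # one independent generator stream per call; species processed in sorted
    # order so the assignment is order-independent of the input manifest
    rng = np.random.default_rng(spec.seed)
    df["split"] = ""
    for species in sorted(df["species"].unique()):
        mask = df["species"] == species
        date_counts = df.loc[mask, "date"].value_counts()
        dates = list(date_counts.index)
        if len(dates) < spec.min_dates_per_species:
            warnings.warn(
                f"species {species!r} has only {len(dates)} distinct recording "
                f"date(s) (< {spec.min_dates_per_species}); assigning all clips "
                "to train — a date-disjoint split is not meaningful here",
                stacklevel=2,
            )
            df.loc[mask, "split"] = "train"
            continue
        assignment = _greedy_assign(
            counts=[int(date_counts[d]) for d in dates],
            fractions=spec.fractions,
            rng=rng,
        )
        for date, split_idx in zip(dates, assignment):
            df.loc[mask & (df["date"] == date), "split"] = SPLIT_NAMES[split_idx]
    return df


def _greedy_assign(counts: list[int], fractions: tuple[float, float, float],
                   rng: np.random.Generator) -> list[int]:
    """Largest-group-first greedy assignment to the most deficient split."""
    total = sum(counts)
    targets = np.asarray(fractions, dtype=float) * total
    assigned = np.zeros(3)
    order = rng.permutation(len(counts))  # seeded tie order...
    order = sorted(order, key=lambda i: -counts[i])  # ...under largest-first
    result = [0] * len(counts)
    for i in order:
        deficits = targets - assigned
        best = np.flatnonzero(deficits == deficits.max())
        choice = int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])
        result[i] = choice
        assigned[choice] += counts[i]
    return result


def verify_split(manifest: pd.DataFrame) -> list[tuple[str, str, list[str]]]:
    """List every (species, date) that appears in more than one split.

    An empty return value means the split is date-disjoint.  Rows with an
    empty split label are ignored.
    """
    if manifest.empty:
        return []
    labelled = manifest[manifest["split"].astype(str).str.len() > 0]
    violations = []
    for (species, date), group in labelled.groupby(["species", "date"]):
        splits = sorted(set(group["split"]))
        if len(splits) > 1:
            violations.append((str(species), str(date), splits))
    return violations
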