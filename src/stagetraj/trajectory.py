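"""Cumulative-intersection screen for continuing and deviated genes.

Given the per-transition differential-expression sets S_1..S_K of one
direction (ordered by the design's transition sequence), the continuing set
at stage k is the running intersection C_k = S_1 ∩ ... ∩ S_k: the genes
still significantly regulated in the same direction at every comparison so
far. A gene that is continuing at stage k but not at stage k+1 "deviates"
there: D_k = C_k \\ C_{k+1}. The deviated set is attached to the earlier
stage of the transition, so the count identity |C_k| = |C_{k+1}| + |D_k|
holds exactly for every k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd


class TrajectoryError(ValueError):
    """Raised when continuing sets violate the monotone-nesting invariant."""


@dataclass(frozen=True)
class TrajectoryResult:
    """Continuing sets C_1..C_K and deviated sets D_1..D_{K-1}.

    ``stage_labels`` names the stage each C_k is attached to (the later
    stage of the k-th transition); D_k sits on the same label as C_k.
    """

    direction: str
    stage_labels: tuple[str, ...]
    continuing: tuple[frozenset[str], ...]
    deviated: tuple[frozenset[str], ...]

    def __post_init__(self):
        if len(self.continuing) != len(self.stage_labels):
            raise TrajectoryError("one continuing set per stage label required")
        if len(self.deviated) != max(len(self.continuing) - 1, 0):
            raise TrajectoryError("need exactly K-1 deviated sets")
        for k, (ck, ck1, dk) in enumerate(
            zip(self.continuing, self.continuing[1:], self.deviated)
        ):
            if not ck >= ck1:
                raise TrajectoryError(f"continuing sets not nested at position {k}")
            if dk != ck - ck1:
                raise TrajectoryError(f"deviated set {k} is not C_k \\ C_k+1")

    @property
    def persistent(self) -> frozenset[str]:
        """Genes continuing through the final stage."""
        return self.continuing[-1] if self.continuing else frozenset()


def cumulative_continuing(
    selections: Sequence[frozenset[str] | set[str]],
) -> list[frozenset[str]]:
    """Running intersection of ordered per-transition DE sets."""
    if len(selections) == 0:
        raise TrajectoryError("at least one transition selection is required")
    out: list[frozenset[str]] = []
    acc = frozenset(selections[0])
    out.append(acc)
    for s in selections[1:]:
        acc = acc & frozenset(s)
        out.append(acc)
    return out


def partition_deviated(
    continuing: Sequence[frozenset[str] | set[str]],
) -> list[frozenset[str]]:
    """Set differences D_k = C_k \\ C_{k+1} of nested continuing sets."""
    cont = [frozenset(c) for c in continuing]
    for k, (ck, ck1) in enumerate(zip(cont, cont[1:])):
        if not ck >= ck1:
            raise TrajectoryError(f"continuing sets not monotone at position {k}")
    return [ck - ck1 for ck, ck1 in zip(cont, cont[1:])]


def build_trajectory(
    selections: Sequence[frozenset[str] | set[str]],
    stage_labels: Sequence[str],
    direction: str,
) -> TrajectoryResult:
    """Screen one direction end-to-end: intersections then partition."""
    continuing = cumulative_continuing(selections)
    deviated = partition_deviated(continuing)
    return TrajectoryResult(
        direction=direction,
        stage_labels=tuple(stage_labels),
        continuing=tuple(continuing),
        deviated=tuple(deviated),
    )


def restrict(result: TrajectoryResult, genes: set[str] | frozenset[str]) -> TrajectoryResult:
    """Restrict a trajectory to a gene subset (e.g. one cellular compartment).

    Intersecting every continuing set with the subset preserves nesting, and
    the deviated partition is recomputed so the count identity still holds.
    """
    genes = frozenset(genes)
    continuing = [c & genes for c in result.continuing]
    return TrajectoryResult(
        direction=result.direction,
        stage_labels=result.stage_labels,
        continuing=tuple(continuing),
        deviated=tuple(partition_deviated(continuing)),
    )


def count_table(result: TrajectoryResult) -> pd.DataFrame:
    """Per-stage continuing/deviated counts with the identity re-verified.

    The last stage has no outgoing transition, so its deviated count is
    missing (<NA>).
    """
    n_cont = [len(c) for c in result.continuing]
    n_dev = [len(d) for d in result.deviated]
    for k, (ck, ck1, dk) in enumerate(zip(n_cont, n_cont[1:], n_dev)):
        if ck != ck1 + dk:
            raise TrajectoryError(
                f"count identity broken at stage {result.stage_labels[k]}: "
                f"{ck} != {ck1} + {dk}"
            )
    return pd.DataFrame(
        {
            "stage": result.stage_labels,
            "direction": result.direction,
            "n_continuing": n_cont,
            "n_deviated": pd.array(n_dev + [pd.NA], dtype="Int64"),
        }
    )


def nested_sets_from_counts(counts: Sequence[int], prefix: str = "g") -> list[frozenset[str]]:
    """Construct nested gene sets realizing a non-increasing count series.

    Useful for exercising the partition on published continuing-count
    series: the k-th set holds the first ``counts[k]`` synthetic gene ids,
    so the sets are nested by construction.
    """
    counts = list(counts)
    if any(a < b for a, b in zip(counts, counts[1:])):
        raise TrajectoryError("count series must be non-increasing")
    if counts and counts[0] > 0:
        universe = [f"{prefix}{i + 1:06d}" for i in range(counts[0])]
    else:
        universe = []
    return [frozenset(universe[:c]) for c in counts]
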