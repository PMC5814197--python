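"""Per-transition two-group differential expression screening.

Each stage transition is tested gene-by-gene with a one-way ANOVA between
the later and earlier stage groups (for two groups the F statistic is
exactly the square of the pooled-variance t statistic). Raw p-values are
Bonferroni-corrected across the genes of the matrix, and genes are selected
when the adjusted p-value falls below ``alpha`` and the linear fold change
clears the threshold in either direction. Fold change is the ratio of group
means after back-transforming the log2 intensities to the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import StageDesign

#: Smallest positive double; p-values below machine range are floored here
#: instead of being reported as an exact zero.
TINY_P = np.nextafter(0.0, 1.0)


class InsufficientReplicatesError(ValueError):
    """A test group has fewer than 2 samples."""


@dataclass(frozen=True)
class DESelection:
    """Significant genes of one transition, split by direction."""

    transition: tuple[str, str]
    up: frozenset[str]
    down: frozenset[str]
    alpha: float
    fc_threshold: float

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")


def anova_two_group(values_a, values_b) -> tuple[float, float]:
    """One-way ANOVA F test between two groups of log2 intensities.

    Returns ``(F, p)`` with F on 1 and ``n_a + n_b - 2`` degrees of freedom.
    Degenerate inputs are defined, not errors: zero pooled variance with
    equal means gives ``(0, 1)``; zero pooled variance with distinct means
    gives ``(inf, TINY_P)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError("each group needs at least 2 samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite expression values")
    F, p = _anova_arrays(a[None, :], b[None, :])
    return float(F[0]), float(p[0])


def _anova_arrays(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-group one-way ANOVA over rows (genes)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    ssw = ((a - ma[:, None]) ** 2).sum(axis=1) + ((b - mb[:, None]) ** 2).sum(axis=1)
    grand = (na * ma + nb * mb) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    dfw = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / dfw)
    # ssw == 0: no within-group variance. Equal means -> no evidence (F=0,
    # p=1); distinct means -> perfect separation (F=inf, p floored).
    zero_w = ssw == 0
    F = np.where(zero_w & (ssb == 0), 0.0, F)
    F = np.where(zero_w & (ssb > 0), np.inf, F)
    p = stats.f.sf(F, 1, dfw)
    p = np.where(np.isinf(F), TINY_P, p)
    return F, np.maximum(p, TINY_P)


def test_transition(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    transition: tuple[str, str],
    design: StageDesign | None = None,
) -> pd.DataFrame:
    """Test every gene for the given (earlier, later) stage pair.

    Returns a per-gene table with columns ``gene, F, p, p_adj, fold_change,
    direction``. The Bonferroni factor is the number of genes in the matrix;
    fold change is later-over-earlier on the linear scale; direction is
    ``up`` for fold change > 1, ``down`` for < 1, ``none`` at exactly 1.
    """
    earlier, later = transition
    if design is not None:
        if earlier not in design.labels or later not in design.labels:
            raise KeyError(f"transition {transition} not in design {design.labels}")
    stages = set(meta["stage"])
    for label in (earlier, later):
        if label not in stages:
            raise KeyError(f"stage {label!r} absent from sample metadata")

    cols_a = meta.loc[meta["stage"] == earlier, "sample_id"].tolist()
    cols_b = meta.loc[meta["stage"] == later, "sample_id"].tolist()
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise InsufficientReplicatesError(
            f"transition {transition} needs >= 2 samples per stage"
        )
    a = expr[cols_a].to_numpy(dtype=float)
    b = expr[cols_b].to_numpy(dtype=float)
    F, p = _anova_arrays(a, b)

    m = len(expr)
    p_adj = np.minimum(1.0, m * p)
    fc = np.exp2(b).mean(axis=1) / np.exp2(a).mean(axis=1)
    direction = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    return pd.DataFrame(
        {
            "gene": expr.index,
            "F": F,
            "p": p,
            "p_adj": p_adj,
            "fold_change": fc,
            "direction": direction,
        }
    ).reset_index(drop=True)


def select_de(
    tests: pd.DataFrame,
    transition: tuple[str, str],
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
) -> DESelection:
    """Select significant genes by adjusted p-value and linear fold change.

    Up-regulated: ``p_adj < alpha`` and ``fold_change >= fc_threshold`` with
    fold change strictly above 1; down-regulated mirrors with ``1 /
    fc_threshold``. A threshold of 1.0 therefore reduces to significance
    plus direction.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if fc_threshold < 1.0:
        raise ValueError("fc_threshold must be >= 1")
    sig = tests["p_adj"] < alpha
    fc = tests["fold_change"]
    up = tests.loc[sig & (fc >= fc_threshold) & (fc > 1.0), "gene"]
    down = tests.loc[sig & (fc <= 1.0 / fc_threshold) & (fc < 1.0), "gene"]
    return DESelection(
        transition=tuple(transition),
        up=frozenset(up),
        down=frozenset(down),
        alpha=alpha,
        fc_threshold=fc_threshold,
    )


def screen_transitions(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    design: StageDesign,
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
) -> tuple[list[pd.DataFrame], list[DESelection]]:
    """Run every adjacent stage-pair comparison of a design in order."""
    tables, selections = [], []
    for transition in design.transitions:
        tab = test_transition(expr, meta, transition, design=design)
        tables.append(tab)
        selections.append(select_de(tab, transition, alpha=alpha, fc_threshold=fc_threshold))
    return tables, selections
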