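"""Synthetic data with planted stage trajectories, annotations and modules.

The generator emulates the structure the stage-wise screen assumes: a log2
expression matrix over an ordered multi-stage design in which a planted
"continuously up-regulated" gene gains a fixed log2 shift at every stage
transition up to its drop point and is flat afterwards (down-regulated genes
are the mirror image; null genes are flat throughout). Ground truth — class,
drop transition, compartment and module membership — is recorded so that
every downstream stage of the pipeline can be tested for parameter recovery
without any external data.

Drop-stage convention: with K transitions, ``drop_stage = d`` means the gene
trends across transitions ``1..d`` and is flat from transition ``d+1`` on, so
a perfect screen places it in the deviated set attached to the d-th
continuing stage; ``drop_stage = K`` marks a gene that never drops
(persistent through the last stage).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import StageDesign, default_design

CLASSES = ("continuous_up", "continuous_down", "null")

#: Default GO-style compartment vocabulary: term ids, display names, and the
#: truth class whose genes are preferentially annotated with the compartment.
DEFAULT_COMPARTMENTS: dict[str, dict] = {
    "extracellular": {
        "terms": {
            "GO:0031012": "extracellular matrix",
            "GO:0005615": "extracellular space",
        },
        "target_class": "continuous_up",
    },
    "mitochondrion": {
        "terms": {"GO:0005739": "mitochondrion"},
        "target_class": "continuous_down",
    },
}

DEFAULT_BP_TERMS: dict[str, tuple[str, str]] = {
    # term id -> (display name, truth class it is enriched in)
    "BP:0001": ("cell migration", "continuous_up"),
    "BP:0002": ("inflammatory cell chemotaxis", "continuous_up"),
    "BP:0003": ("aerobic respiration", "continuous_down"),
    "BP:0004": ("fatty acid metabolism", "continuous_down"),
}

DEFAULT_FRACTIONS = {
    "p_up": 0.8,  # P(extracellular | planted up gene)
    "p_down": 0.8,  # P(mitochondrion | planted down gene)
    "background": 0.1,  # compartment probability for non-target genes
    "bp_foreground": 0.6,  # P(BP term | gene of the term's target class)
    "bp_background": 0.05,
}


class ParameterError(ValueError):
    """Raised for generator parameters outside their documented domain."""


def stage_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage generator fanned out from one top-level seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of ``n`` items proportional to ``fractions``.

    Floors each share, then hands remaining items to the largest fractional
    remainders (ties broken by position), so the counts always sum to ``n``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.min() < 0 or not np.isclose(fractions.sum(), 1.0):
        raise ParameterError("class fractions must be non-negative and sum to 1")
    raw = n * fractions
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    short = n - counts.sum()
    for i in np.argsort(-rem, kind="stable")[:short]:
        counts[i] += 1
    return counts.tolist()


@dataclass
class SyntheticDataset:
    """Bundle of everything one simulation run produced."""

    design: StageDesign
    expression: pd.DataFrame  # genes x samples, log2 scale
    metadata: pd.DataFrame  # sample_id, stage
    truth: pd.DataFrame  # gene, class, drop_stage, module_id
    seed: int
    annotation_pairs: pd.DataFrame | None = None
    term_metadata: pd.DataFrame | None = None
    edges: pd.DataFrame | None = None
    compartments: dict = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i + 1:06d}" for i in range(n)]


def simulate_expression(
    design: StageDesign | None = None,
    n_genes: int = 2000,
    class_fractions: Mapping[str, float] | None = None,
    effect: float = 1.5,
    sigma: float = 0.5,
    drop_schedule: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> SyntheticDataset:
    """Simulate a log2 expression matrix with planted monotone trajectories.

    Parameters
    ----------
    design
        Stage design; defaults to the seven-stage progression series.
    n_genes
        Total genes; ids are ``g000001``...
    class_fractions
        Proportions of ``continuous_up`` / ``continuous_down`` / ``null``
        genes (largest-remainder rounded). Default 0.1 / 0.1 / 0.8.
    effect
        Per-transition log2 shift of a trending gene (>= 0; 0 reduces every
        gene to the null model).
    sigma
        Within-stage Gaussian noise SD on the log2 scale (> 0).
    drop_schedule
        Per-class probability vector over drop stages ``1..K`` (K = number of
        transitions). Default: uniform.
    """
    design = design or default_design()
    if effect < 0:
        raise ParameterError("effect must be >= 0")
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    fractions = dict(class_fractions or {"continuous_up": 0.1, "continuous_down": 0.1, "null": 0.8})
    unknown = set(fractions) - set(CLASSES)
    if unknown:
        raise ParameterError(f"unknown gene classes {sorted(unknown)}")

    K = design.n_transitions
    rng = stage_rng(seed, "expression")
    genes = _gene_ids(n_genes)
    per_class = dict(
        zip(CLASSES, largest_remainder(n_genes, [fractions.get(c, 0.0) for c in CLASSES]))
    )
    classes = np.repeat(list(CLASSES), [per_class[c] for c in CLASSES])

    schedule = {c: np.full(K, 1.0 / K) for c in ("continuous_up", "continuous_down")}
    if drop_schedule:
        for cls, probs in drop_schedule.items():
            probs = np.asarray(probs, dtype=float)
            if cls not in CLASSES or cls == "null":
                raise ParameterError(f"drop schedule for unknown/null class {cls!r}")
            if len(probs) != K or probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
                raise ParameterError("drop schedule must be a length-K probability vector")
            schedule[cls] = probs

    drop = np.zeros(n_genes, dtype=int)  # 0 encodes "not applicable" (null)
    for cls in ("continuous_up", "continuous_down"):
        mask = classes == cls
        drop[mask] = rng.choice(np.arange(1, K + 1), size=mask.sum(), p=schedule[cls])

    sign = np.where(classes == "continuous_up", 1.0, np.where(classes == "continuous_down", -1.0, 0.0))
    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)

    # Stage mean of gene g at stage index s (0-based): base + sign*effect*min(s, drop)
    stage_idx = np.arange(design.n_stages)
    steps = np.minimum(stage_idx[None, :], drop[:, None])  # genes x stages
    means = base[:, None] + sign[:, None] * effect * steps

    sample_ids: list[str] = []
    sample_stage: list[str] = []
    cols = []
    for s, (label, count) in enumerate(zip(design.labels, design.counts)):
        block = means[:, s][:, None] + rng.normal(0.0, sigma, size=(n_genes, count))
        cols.append(block)
        sample_ids.extend(f"{label}.{j + 1}" for j in range(count))
        sample_stage.extend([label] * count)

    expr = pd.DataFrame(np.hstack(cols), index=pd.Index(genes, name="gene"), columns=sample_ids)
    meta = pd.DataFrame({"sample_id": sample_ids, "stage": sample_stage})
    truth = pd.DataFrame(
        {
            "gene": genes,
            "class": classes,
            "drop_stage": pd.array(
                [d if c != "null" else pd.NA for d, c in zip(drop, classes)], dtype="Int64"
            ),
            "module_id": pd.array([pd.NA] * n_genes, dtype="Int64"),
        }
    )
    return SyntheticDataset(design=design, expression=expr, metadata=meta, truth=truth, seed=seed)


def simulate_annotations(
    truth: pd.DataFrame,
    compartments: Mapping[str, Mapping] | None = None,
    bp_terms: Mapping[str, tuple[str, str]] | None = None,
    enrichment_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign GO-style CC compartments and BP terms to genes.

    Genes of a compartment's target class receive one of its terms with the
    class-specific probability (``p_up`` / ``p_down``); all other genes with
    the ``background`` probability. Each BP term is enriched in one truth
    class (``bp_foreground`` vs ``bp_background``).

    Returns ``(pairs, term_metadata)``: the (gene, term) association table
    and the term id/name/namespace table.
    """
    compartments = dict(compartments or DEFAULT_COMPARTMENTS)
    bp_terms = dict(bp_terms or DEFAULT_BP_TERMS)
    frac = {**DEFAULT_FRACTIONS, **(enrichment_fractions or {})}
    for key, v in frac.items():
        if not 0.0 <= float(v) <= 1.0:
            raise ParameterError(f"fraction {key}={v} outside [0, 1]")
    bad = set(truth["class"]) - set(CLASSES)
    if bad:
        raise ParameterError(f"unknown class label(s) in truth table: {sorted(bad)}")

    rng = stage_rng(seed, "annotation")
    class_prob = {"continuous_up": frac["p_up"], "continuous_down": frac["p_down"]}
    rows: list[tuple[str, str]] = []
    genes = truth["gene"].to_numpy()
    classes = truth["class"].to_numpy()

    for comp in sorted(compartments):
        comp_def = compartments[comp]
        terms = sorted(comp_def["terms"])
        target = comp_def["target_class"]
        p = np.where(classes == target, class_prob.get(target, frac["background"]), frac["background"])
        hit = rng.random(len(genes)) < p
        which = rng.integers(0, len(terms), size=len(genes))
        rows.extend((g, terms[w]) for g, w in zip(genes[hit], which[hit]))

    for term in sorted(bp_terms):
        _, target = bp_terms[term]
        if target not in CLASSES:
            raise ParameterError(f"BP term {term} targets unknown class {target!r}")
        p = np.where(classes == target, frac["bp_foreground"], frac["bp_background"])
        hit = rng.random(len(genes)) < p
        rows.extend((g, term) for g in genes[hit])

    pairs = pd.DataFrame(rows, columns=["gene", "term"]).sort_values(
        ["gene", "term"], ignore_index=True
    )
    meta_rows = []
    for comp in sorted(compartments):
        for term, name in sorted(compartments[comp]["terms"].items()):
            meta_rows.append((term, name, "CC"))
    for term in sorted(bp_terms):
        meta_rows.append((term, bp_terms[term][0], "BP"))
    term_meta = pd.DataFrame(meta_rows, columns=["term", "name", "namespace"])
    return pairs, term_meta


def _combine_scores(*channels: np.ndarray) -> np.ndarray:
    """STRING-style noisy-or combination of 0-1000 channel scores."""
    keep = np.ones(len(channels[0]), dtype=float)
    for ch in channels:
        keep *= 1.0 - ch / 1000.0
    return np.rint(1000.0 * (1.0 - keep)).astype(int)


def simulate_interactions(
    truth: pd.DataFrame,
    n_modules: int = 3,
    module_size: int = 6,
    intra_density: float = 0.9,
    background_density: float = 0.01,
    score_range: tuple[int, int] = (400, 999),
    seed: int = 0,
) -> pd.DataFrame:
    """Plant near-clique modules among non-null genes over a random background.

    Module members are drawn (disjointly) from the non-null genes; each
    within-module pair is an edge with probability ``intra_density``, and
    every gene pair is additionally a background edge with probability
    ``background_density``. Module membership is recorded in-place in the
    truth table's ``module_id`` column. Every edge carries ``experimental``
    and ``coexpression`` channel scores plus the combined score, STRING-style
    integers in 0-1000.
    """
    if not (0.0 <= intra_density <= 1.0 and 0.0 <= background_density <= 1.0):
        raise ParameterError("densities must lie in [0, 1]")
    if module_size < 3:
        raise ParameterError("module_size must be >= 3")
    lo, hi = score_range
    if not (0 < lo <= hi <= 1000):
        raise ParameterError("score_range must satisfy 0 < lo <= hi <= 1000")

    rng = stage_rng(seed, "interactions")
    genes = truth["gene"].tolist()
    nonnull = truth.loc[truth["class"] != "null", "gene"].tolist()
    needed = n_modules * module_size
    if needed > len(nonnull):
        raise ParameterError(
            f"{n_modules} modules x {module_size} genes need {needed} non-null genes, "
            f"only {len(nonnull)} available"
        )

    picked = rng.choice(len(nonnull), size=needed, replace=False) if needed else np.array([], int)
    truth["module_id"] = pd.array([pd.NA] * len(truth), dtype="Int64")
    edge_set: set[tuple[str, str]] = set()
    for m in range(n_modules):
        members = sorted(nonnull[i] for i in picked[m * module_size : (m + 1) * module_size])
        truth.loc[truth["gene"].isin(members), "module_id"] = m + 1
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < intra_density:
                    edge_set.add((members[i], members[j]))

    if background_density > 0 and len(genes) > 1:
        iu, ju = np.triu_indices(len(genes), k=1)
        hit = rng.random(len(iu)) < background_density
        for i, j in zip(iu[hit], ju[hit]):
            a, b = genes[i], genes[j]
            edge_set.add((a, b) if a < b else (b, a))

    edges = sorted(edge_set)
    n = len(edges)
    experimental = rng.integers(lo, hi + 1, size=n)
    coexpression = rng.integers(0, 301, size=n)
    table = pd.DataFrame(
        {
            "protein1": [e[0] for e in edges],
            "protein2": [e[1] for e in edges],
            "coexpression": coexpression,
            "experimental": experimental,
            "combined_score": _combine_scores(experimental, coexpression) if n else [],
        }
    )
    return table


def simulate_dataset(
    design: StageDesign | None = None,
    seed: int = 0,
    expression_params: Mapping | None = None,
    annotation_params: Mapping | None = None,
    interaction_params: Mapping | None = None,
) -> SyntheticDataset:
    """Full simulation: expression + truth, annotations, interaction table."""
    ds = simulate_expression(design=design, seed=seed, **(expression_params or {}))
    ds.annotation_pairs, ds.term_metadata = simulate_annotations(
        ds.truth, seed=seed, **(annotation_params or {})
    )
    ds.edges = simulate_interactions(ds.truth, seed=seed, **(interaction_params or {}))
    ds.compartments = dict(DEFAULT_COMPARTMENTS)
    return ds
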