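"""Ordered disease-stage designs.

A study design is an ordered sequence of disease stages, each with a sample
count, from which the sequence of adjacent stage-pair comparisons
("transitions") is derived. The default mirrors a seven-stage colorectal
cancer progression series: normal mucosa, primary tumor stages I-IV, liver
metastasis, lung metastasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class InvalidDesignError(ValueError):
    """Raised when stage labels and sample counts cannot form a valid design."""


#: Seven-stage colorectal cancer progression design (sample counts per stage).
DEFAULT_LABELS = ("normal", "I", "II", "III", "IV", "liver_met", "lung_met")
DEFAULT_COUNTS = (54, 28, 50, 49, 58, 47, 20)


@dataclass(frozen=True)
class StageDesign:
    """Ordered stages with per-stage sample counts.

    Parameters
    ----------
    labels : tuple of str
        Stage names in progression order.
    counts : tuple of int
        Number of samples per stage; each must be >= 2 so that a two-group
        variance test is defined for every transition.
    """

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    transitions: tuple[tuple[str, str], ...] = field(init=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        counts = tuple(int(c) for c in self.counts)
        if len(labels) != len(counts):
            raise InvalidDesignError(
                f"{len(labels)} labels but {len(counts)} counts"
            )
        if len(labels) < 2:
            raise InvalidDesignError("a design needs at least two stages")
        if len(set(labels)) != len(labels):
            raise InvalidDesignError("stage labels must be unique")
        bad = [l for l, c in zip(labels, counts) if c < 2]
        if bad:
            raise InvalidDesignError(
                f"stages {bad} have fewer than 2 samples; the two-group test "
                "needs at least 2 replicates per group"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(
            self,
            "transitions",
            tuple((labels[k], labels[k + 1]) for k in range(len(labels) - 1)),
        )

    @property
    def n_stages(self) -> int:
        return len(self.labels)

    @property
    def n_transitions(self) -> int:
        return len(self.labels) - 1

    @property
    def n_samples(self) -> int:
        return sum(self.counts)

    def count_of(self, label: str) -> int:
        try:
            return self.counts[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown stage label {label!r}") from None


def make_design(labels, counts) -> StageDesign:
    """Build a :class:`StageDesign` from parallel label/count sequences."""
    return StageDesign(tuple(labels), tuple(counts))


def default_design() -> StageDesign:
    """The seven-stage colorectal progression design used throughout."""
    return make_design(DEFAULT_LABELS, DEFAULT_COUNTS)
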