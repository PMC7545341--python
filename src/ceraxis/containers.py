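"""Core in-memory containers shared across pipeline stages.

Expression data live in :class:`ExpressionMatrix` objects (one per RNA
class, features in rows, samples in columns, log2 scale).  The
responder/nonresponder assignment is a :class:`pandas.Series` mapping
sample id -> group label, validated by :func:`validate_design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESPONDER = "responder"
NONRESPONDER = "nonresponder"
GROUPS = (RESPONDER, NONRESPONDER)

#: accepted aliases for group labels in design files ("well"/"weak" is a
#: common clinical shorthand for treatment responder/nonresponder)
GROUP_ALIASES = {
    "responder": RESPONDER,
    "well": RESPONDER,
    "nonresponder": NONRESPONDER,
    "non-responder": NONRESPONDER,
    "weak": NONRESPONDER,
}

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")


@dataclass
class ExpressionMatrix:
    """A features x samples log2 expression table for one RNA class."""

    values: pd.DataFrame
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(
                f"unknown RNA class {self.rna_class!r}; expected one of {RNA_CLASSES}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.rna_class)


def normalize_group_label(label: str) -> str:
    try:
        return GROUP_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown group label {label!r}; expected one of {sorted(GROUP_ALIASES)}"
        ) from None


def validate_design(design: pd.Series, samples=None, min_per_group: int = 2) -> pd.Series:
    """Validate a sample -> group design.

    Labels are normalized via :data:`GROUP_ALIASES`; each group must hold at
    least ``min_per_group`` samples and, if ``samples`` is given, the design
    must cover those samples exactly once each.
    """
    design = pd.Series(
        [normalize_group_label(v) for v in design], index=design.index, name="group"
    )
    if design.index.duplicated().any():
        raise ValueError("duplicate sample ids in design")
    for g in GROUPS:
        n = int((design == g).sum())
        if n < min_per_group:
            raise ValueError(f"group {g!r} has {n} samples; need >= {min_per_group}")
    if samples is not None:
        samples = pd.Index(samples)
        if not samples.isin(design.index).all():
            missing = samples[~samples.isin(design.index)].tolist()
            raise ValueError(f"samples missing from design: {missing}")
        if not design.index.isin(samples).all():
            extra = design.index[~design.index.isin(samples)].tolist()
            raise ValueError(f"design samples absent from matrix: {extra}")
    return design


def group_samples(design: pd.Series, group: str) -> list[str]:
    group = normalize_group_label(group)
    return list(design.index[design == group])


@dataclass
class SequenceSet:
    """FASTA-like record set: ordered id -> RNA sequence (ACGU, uppercase)."""

    records: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: str) -> str:
        return self.records[key]

    def items(self):
        return self.records.items()
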