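"""Core in-memory containers for metabolite profiling data.

The central object is :class:`MetaboliteTable`, a samples x metabolites
abundance matrix (arbitrary peak-area units) that tracks its processing
state through the preprocessing chain raw -> normalized -> log_scaled ->
imputed.  Sample factors (genotype, oxygen condition, sampling day,
replicate) live in :class:`SampleMetadata`; compound annotation and
pathway membership are carried separately so that metabolite identifiers
can stay opaque keys (GC-MS profiles routinely mix named compounds with
retention-index-only unknowns).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableState",
    "MetaboliteTable",
    "SampleMetadata",
    "MetaboliteAnnotation",
    "MetaboliteSetCollection",
    "ValidationError",
    "CONDITIONS",
]

#: Recognised oxygen conditions, in display order.
CONDITIONS = ("normoxia", "hypoxia")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class TableState(str, enum.Enum):
    """Processing state of a :class:`MetaboliteTable`."""

    RAW = "raw"
    NORMALIZED = "normalized"
    LOG_SCALED = "log_scaled"
    IMPUTED = "imputed"


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicated {kind} id: {x!r}")
        seen.add(x)


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundance matrix.

    Parameters
    ----------
    values
        DataFrame with sample ids as index and metabolite ids as columns.
        Missing measurements are NaN, never zero.
    state
        Processing state; raw tables must be non-negative.
    """

    values: pd.DataFrame
    state: TableState = TableState.RAW

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.state = TableState(self.state)
        self.values = self.values.astype(float)
        _check_unique(list(self.values.index), "sample")
        _check_unique(list(self.values.columns), "metabolite")
        if self.state is TableState.RAW:
            arr = self.values.to_numpy()
            bad = np.argwhere(arr < 0)
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    "negative abundance at sample "
                    f"{self.values.index[i]!r}, metabolite {self.values.columns[j]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self, state: TableState | None = None) -> "MetaboliteTable":
        return MetaboliteTable(self.values.copy(), state or self.state)

    def require_state(self, *states: TableState) -> None:
        if self.state not in states:
            wanted = ", ".join(s.value for s in states)
            raise ValidationError(
                f"table is in state {self.state.value!r}; expected {wanted}"
            )

    def require_complete(self) -> None:
        if self.n_missing():
            raise ValidationError(
                f"table contains {self.n_missing()} missing entries; "
                "run the preprocessing chain (imputation) first"
            )


@dataclass
class SampleMetadata:
    """Per-sample experimental factors.

    One row per sample with columns ``genotype``, ``condition``
    (normoxia / hypoxia), ``time_das`` (days after sowing) and
    ``replicate``.  The (genotype, condition, time_das, replicate)
    tuple identifies a sample uniquely.
    """

    frame: pd.DataFrame

    REQUIRED = ("genotype", "condition", "time_das", "replicate")

    def __post_init__(self) -> None:
        df = self.frame
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata lacks required columns: {missing}")
        _check_unique(list(df.index), "sample")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(
                f"unknown condition labels {sorted(bad_cond)}; expected {CONDITIONS}"
            )
        df = df.copy()
        df["time_das"] = df["time_das"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be positive integers")
        tuples = list(
            zip(df["genotype"], df["condition"], df["time_das"], df["replicate"])
        )
        if len(set(tuples)) != len(tuples):
            dup = next(t for t in tuples if tuples.count(t) > 1)
            raise ValidationError(f"duplicated design tuple {dup}")
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())

    def group_key(self, factors: Sequence[str] = ("genotype", "condition", "time_das")) -> pd.Series:
        """Series mapping sample id -> tuple of factor levels."""
        return self.frame[list(factors)].apply(tuple, axis=1)

    def select(self, **levels) -> list[str]:
        """Sample ids matching the given factor levels (e.g. condition='hypoxia')."""
        mask = pd.Series(True, index=self.frame.index)
        for factor, value in levels.items():
            if factor not in self.frame.columns:
                raise ValidationError(f"unknown metadata factor {factor!r}")
            if isinstance(value, (list, tuple, set)):
                mask &= self.frame[factor].isin(list(value))
            else:
                mask &= self.frame[factor] == value
        return list(self.frame.index[mask])

    def validate_against(self, table: MetaboliteTable) -> None:
        """Every table sample must have exactly one metadata row."""
        orphans = [s for s in table.sample_ids if s not in self.frame.index]
        if orphans:
            raise ValidationError(
                f"samples present in matrix but absent from metadata: {orphans}"
            )


@dataclass
class MetaboliteAnnotation:
    """Optional compound annotation: display name, chemical class, KEGG id, RI."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "metabolite_id" in df.columns:
            df = df.set_index("metabolite_id")
        _check_unique(list(df.index), "metabolite")
        for col in ("display_name", "chem_class", "kegg_compound", "retention_index"):
            if col not in df.columns:
                df = df.copy()
                df[col] = np.nan
        ri = pd.to_numeric(df["retention_index"], errors="coerce")
        if (ri.dropna() <= 0).any():
            raise ValidationError("retention_index values must be positive")
        self.frame = df

    @classmethod
    def empty(cls, metabolite_ids: Sequence[str]) -> "MetaboliteAnnotation":
        return cls(pd.DataFrame(index=pd.Index(metabolite_ids, name="metabolite_id")))

    def chem_class_of(self, metabolite_id: str) -> str | None:
        if metabolite_id not in self.frame.index:
            return None
        v = self.frame.loc[metabolite_id, "chem_class"]
        return None if pd.isna(v) else str(v)


class MetaboliteSetCollection(Mapping[str, list]):
    """Ordered map from pathway/set id to member metabolite ids (GMT semantics).

    Members may overlap between sets; each set has at least one member.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, list[str]] = {}
        self._descriptions: dict[str, str] = {}
        for set_id, members in sets.items():
            members = list(members)
            if not members:
                raise ValidationError(f"metabolite set {set_id!r} has no members")
            self._sets[set_id] = members
            self._descriptions[set_id] = (descriptions or {}).get(set_id, "")

    def __getitem__(self, set_id: str) -> list[str]:
        return self._sets[set_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def description(self, set_id: str) -> str:
        return self._descriptions[set_id]

    def restrict(self, universe: Sequence[str], min_size: int = 1) -> "MetaboliteSetCollection":
        """Drop members outside `universe` and sets below `min_size`."""
        uni = set(universe)
        kept = {
            sid: [m for m in members if m in uni] for sid, members in self._sets.items()
        }
        kept = {sid: m for sid, m in kept.items() if len(m) >= min_size}
        return MetaboliteSetCollection(kept, self._descriptions)
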