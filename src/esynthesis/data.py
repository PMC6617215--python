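"""Data model and I/O for grouped dose-response cohort tables.

A dose-response table holds one row per dose group: the dose level ``d_i``
(opaque numeric, in the units of the source study), the number of subjects
``n_i`` and the number of subjects with the effect ``y_i``.  The observed
group rate ``r_i = y_i / n_i`` is always derived from the counts, never
read from an input column, so it cannot be inconsistent with them.

The paracetamol-asthma cohort (five dose groups, 297,282 person-years,
299 incident asthma diagnoses) ships as a built-in fixture and drives the
package's worked example.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "DoseGroup",
    "DoseResponseTable",
    "read_dose_table",
    "write_dose_table",
    "observed_rates",
    "paracetamol_asthma_table",
]


@dataclass(frozen=True)
class DoseGroup:
    """One dose group: dose level, group size n, event count y."""

    dose: float
    n: int
    events: int

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValidationError(f"dose must be non-negative, got {self.dose}")
        if self.n <= 0 or int(self.n) != self.n:
            raise ValidationError(f"group size n must be a positive integer, got {self.n}")
        if self.events < 0 or int(self.events) != self.events:
            raise ValidationError(f"event count must be a non-negative integer, got {self.events}")
        if self.events > self.n:
            raise ValidationError(
                f"event count {self.events} exceeds group size {self.n} at dose {self.dose}"
            )

    @property
    def rate(self) -> float:
        return self.events / self.n


@dataclass(frozen=True)
class DoseResponseTable:
    """Ordered collection of dose groups, sorted ascending by dose.

    Doses must be distinct: ties are rejected rather than merged, because
    silent pooling would change the likelihood.  A table may hold a single
    group for storage; posterior assessment of dose-responsiveness requires
    at least three groups (enforced downstream).
    """

    groups: tuple[DoseGroup, ...]
    label: str = ""

    def __init__(self, groups: Iterable[DoseGroup], label: str = ""):
        groups = tuple(sorted(groups, key=lambda g: g.dose))
        if not groups:
            raise ValidationError("a dose-response table needs at least one group")
        doses = [g.dose for g in groups]
        if len(set(doses)) != len(doses):
            dupes = sorted({d for d in doses if doses.count(d) > 1})
            raise ValidationError(f"duplicate dose levels {dupes}: merge or correct the input")
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "label", label)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def doses(self) -> np.ndarray:
        return np.array([g.dose for g in self.groups], dtype=float)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([g.n for g in self.groups], dtype=np.int64)

    @property
    def events(self) -> np.ndarray:
        return np.array([g.events for g in self.groups], dtype=np.int64)

    @property
    def rates(self) -> np.ndarray:
        return self.events / self.sizes

    def subset(self, indices: Sequence[int]) -> "DoseResponseTable":
        """Table restricted to the given group indices (0-based)."""
        return DoseResponseTable([self.groups[i] for i in indices], label=self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": self.doses,
                "n": self.sizes,
                "events": self.events,
                "rate": self.rates,
            }
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "groups": [
                {"dose": g.dose, "n": int(g.n), "events": int(g.events), "rate": g.rate}
                for g in self.groups
            ],
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        payload = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


DEFAULT_COLUMNS: dict[str, str] = {"dose": "dose", "n": "n", "events": "events"}


def read_dose_table(
    source: str | Path,
    columns: Mapping[str, str] | None = None,
    label: str = "",
    sep: str | None = None,
) -> DoseResponseTable:
    """Read a grouped dose-response table from delimited text.

    Parameters
    ----------
    source
        Path to a CSV/TSV file with a header row.
    columns
        Mapping from the logical names ``dose``, ``n``, ``events`` to the
        column names used in the file.  Defaults to the logical names.
    label
        Free-text metadata (drug, effect, population).
    sep
        Field delimiter; inferred from the file when omitted.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    try:
        df = pd.read_csv(source, sep=sep, engine="python", encoding="utf-8")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {source}: {exc}") from exc
    missing = [colmap[key] for key in ("dose", "n", "events") if colmap[key] not in df.columns]
    if missing:
        raise FormatError(
            f"{source}: missing required column(s) {missing}; present: {list(df.columns)}"
        )
    groups = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        record = dict(zip(df.columns, row))
        try:
            groups.append(
                DoseGroup(
                    dose=float(record[colmap["dose"]]),
                    n=int(record[colmap["n"]]),
                    events=int(record[colmap["events"]]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{source}, line {row_number}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{source}, line {row_number}: {exc}") from exc
    return DoseResponseTable(groups, label=label)


def write_dose_table(table: DoseResponseTable, path: str | Path, sep: str = ",") -> None:
    """Write a table as delimited text with a derived ``rate`` column."""
    table.to_frame().to_csv(path, sep=sep, index=False)


def observed_rates(table: DoseResponseTable) -> np.ndarray:
    """Observed group rates r_i = y_i / n_i, in dose order."""
    return table.rates


#: Paracetamol-asthma cohort groups: (dose, n, events).  Doses are kept
#: exactly as published (31.67, 86.67), not reconstructed interval midpoints.
_PARACETAMOL_ASTHMA_GROUPS: tuple[tuple[float, int, int], ...] = (
    (0.0, 137568, 108),
    (10.0, 99922, 112),
    (31.67, 32077, 41),
    (60.0, 10656, 16),
    (86.67, 17059, 22),
)


def paracetamol_asthma_table() -> DoseResponseTable:
    """The paracetamol-asthma dose-response cohort (built-in fixture).

    Five dose groups from a prospective cohort study of asthma incidence
    in women (1990-1996, 297,282 person-years, 299 incident diagnoses),
    grouped by paracetamol use.
    """
    return DoseResponseTable(
        [DoseGroup(d, n, y) for d, n, y in _PARACETAMOL_ASTHMA_GROUPS],
        label="paracetamol-asthma cohort",
    )
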