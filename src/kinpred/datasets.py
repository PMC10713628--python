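"""Kinetics datasets: records, filtering, log transform, and split protocols.

A dataset is a list of :class:`KineticsRecord` — one enzyme–substrate
(optionally –condition) sample with a measured parameter (kcat in s⁻¹, Km in
mM, or kcat/Km in s⁻¹·mM⁻¹) modelled on the log10 scale. Preprocessing drops
multi-component SMILES (any string containing ".") and non-positive values
before taking log10. Split protocols: repeated random holdout (e.g. 90/10),
k-fold cross-validation, the nested 64/16/20 split used to train the
environmental-factor stacked model, and the strict unseen-enzyme-or-substrate
test subset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARAMETER_KINDS = ("kcat", "km", "kcat_over_km")
CONDITION_KINDS = ("pH", "temperature")


@dataclass(frozen=True)
class KineticsRecord:
    """One enzyme–substrate(–condition) sample with a log-scale parameter value."""

    enzyme_sequence: str
    substrate_smiles: str
    raw_value: float | None = None
    log_value: float | None = None
    parameter_kind: str = "kcat"
    condition_kind: str | None = None
    condition_value: float | None = None
    wild_type: bool | None = None
    organism: str | None = None

    def __post_init__(self):
        if self.parameter_kind not in PARAMETER_KINDS:
            raise ValueError(f"unknown parameter kind {self.parameter_kind!r}")
        if (self.condition_kind is None) != (self.condition_value is None):
            raise ValueError("condition_kind and condition_value must be set together")
        if self.condition_kind is not None and self.condition_kind not in CONDITION_KINDS:
            raise ValueError(f"unknown condition kind {self.condition_kind!r}")
        if self.log_value is not None:
            if self.raw_value is None or self.raw_value <= 0:
                raise ValueError("log_value requires a positive raw_value")
            if abs(self.log_value - math.log10(self.raw_value)) > 1e-9:
                raise ValueError("log_value inconsistent with log10(raw_value)")


@dataclass(frozen=True)
class ColumnSchema:
    """Maps dataset columns to record fields."""

    sequence: str = "enzyme_sequence"
    smiles: str = "substrate_smiles"
    value: str = "value"
    condition: str | None = None
    condition_kind: str | None = None
    organism: str | None = None
    wild_type: str | None = None


@dataclass
class DropReport:
    """Counts of records excluded by each preprocessing rule.

    A record violating both rules is counted under both reasons; ``n_dropped``
    counts it once.
    """

    multi_component_smiles: int = 0
    non_positive_value: int = 0
    n_dropped: int = 0
    n_kept: int = 0
    reasons: list = field(default_factory=list)  # (input index, reason codes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"index": i, "reasons": ";".join(codes)} for i, codes in self.reasons]
        )


# ---------------------------------------------------------------------------
# Reading / preprocessing
# ---------------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    schema: ColumnSchema = ColumnSchema(),
    parameter_kind: str = "kcat",
) -> list[KineticsRecord]:
    """Read a CSV/TSV kinetics table into records.

    The delimiter is taken from the file extension (``.tsv`` → tab, else
    comma). Raw values are parsed as reals; an unparseable value raises an
    error naming the offending row. Log values are not set here — run
    :func:`filter_records` then :func:`log_transform`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    required = [schema.sequence, schema.smiles, schema.value]
    if schema.condition is not None:
        required.append(schema.condition)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    if frame.empty:
        logger.warning("dataset %s contains a header but no rows", path)
        return []

    records = []
    for i, row in frame.iterrows():
        try:
            raw = float(row[schema.value])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"row {i + 2} of {path}: unparseable value {row[schema.value]!r}"
            ) from exc
        condition_kind = condition_value = None
        if schema.condition is not None:
            condition_kind = schema.condition_kind or schema.condition
            try:
                condition_value = float(row[schema.condition])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"row {i + 2} of {path}: unparseable condition "
                    f"{row[schema.condition]!r}"
                ) from exc
        wild_type = None
        if schema.wild_type is not None and schema.wild_type in frame.columns:
            wild_type = str(row[schema.wild_type]).strip().lower() in {"1", "true", "yes"}
        records.append(
            KineticsRecord(
                enzyme_sequence=str(row[schema.sequence]).strip(),
                substrate_smiles=str(row[schema.smiles]).strip(),
                raw_value=raw,
                parameter_kind=parameter_kind,
                condition_kind=condition_kind,
                condition_value=condition_value,
                organism=(
                    str(row[schema.organism])
                    if schema.organism is not None and schema.organism in frame.columns
                    else None
                ),
                wild_type=wild_type,
            )
        )
    return records


def filter_records(
    records: Iterable[KineticsRecord],
) -> tuple[list[KineticsRecord], DropReport]:
    """Drop multi-component SMILES ("." in the string) and non-positive values."""
    kept, report = [], DropReport()
    for i, rec in enumerate(records):
        codes = []
        if "." in rec.substrate_smiles:
            codes.append("multi_component_smiles")
            report.multi_component_smiles += 1
        if rec.raw_value is None or rec.raw_value <= 0:
            codes.append("non_positive_value")
            report.non_positive_value += 1
        if codes:
            report.n_dropped += 1
            report.reasons.append((i, codes))
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def log_transform(records: Iterable[KineticsRecord]) -> list[KineticsRecord]:
    """Set ``log_value = log10(raw_value)`` on every record."""
    out = []
    for i, rec in enumerate(records):
        if rec.raw_value is None or rec.raw_value <= 0:
            raise ValueError(
                f"record {i} has non-positive raw value; run filter_records first"
            )
        out.append(replace(rec, log_value=math.log10(rec.raw_value)))
    return out


# ---------------------------------------------------------------------------
# Split protocols
# ---------------------------------------------------------------------------

def split_holdout(
    n: int, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split with ``ceil(test_fraction·n)`` test samples.

    The ceiling rule reproduces the reference protocol: 16,838 samples at a
    10% test fraction give 1684 test and 15,154 training samples.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_test = math.ceil(test_fraction * n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def split_repeated_holdout(
    n: int, test_fraction: float, repeats: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent random holdout splits (e.g. the 90/10 protocol repeated 5×)."""
    if repeats < 1:
        raise ValueError("repeats must be ≥ 1")
    return [split_holdout(n, test_fraction, seed + r) for r in range(repeats)]


def split_nested_ef(n: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nested split for the two-layer environmental-factor model.

    Returns ``(base_train, meta_train, test)`` index arrays: 20% of the data
    (ceiling) is held out as the test set, and the remaining training portion
    is split 80/20 into the base-model and meta-model training sets — 64/16/20
    of the whole at n=100.
    """
    if n < 5:
        raise ValueError("nested split needs at least 5 samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = math.ceil(0.2 * n)
    test, train = perm[:n_test], perm[n_test:]
    n_meta = math.ceil(0.2 * train.size)
    meta, base = train[:n_meta], train[n_meta:]
    return np.sort(base), np.sort(meta), np.sort(test)


def split_kfold(n: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Shuffled k-fold partition; fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if n < k:
        raise ValueError("need at least k samples")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _normalize_seq(s: str) -> str:
    return s.strip().upper()


def strict_subset(
    test_records: Sequence[KineticsRecord], train_records: Sequence[KineticsRecord]
) -> list[KineticsRecord]:
    """Test records whose enzyme OR substrate never occurs in training.

    Identity is exact string equality (sequences upper-cased, whitespace
    stripped). With an empty training set every test record is retained.
    """
    train_seqs = {_normalize_seq(r.enzyme_sequence) for r in train_records}
    train_smiles = {r.substrate_smiles.strip() for r in train_records}
    return [
        r
        for r in test_records
        if _normalize_seq(r.enzyme_sequence) not in train_seqs
        or r.substrate_smiles.strip() not in train_smiles
    ]


# ---------------------------------------------------------------------------
# Tabular round-trips
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[KineticsRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "enzyme_sequence": r.enzyme_sequence,
                "substrate_smiles": r.substrate_smiles,
                "value": r.raw_value,
                "log_value": r.log_value,
                "parameter_kind": r.parameter_kind,
                "condition_kind": r.condition_kind,
                "condition_value": r.condition_value,
                "organism": r.organism,
            }
        )
    return pd.DataFrame(rows)


def write_split_tsv(path: str | Path, **index_sets: np.ndarray) -> None:
    """Write named index sets (e.g. train/test) as a two-column TSV."""
    rows = [
        {"subset": name, "index": int(i)}
        for name, indices in index_sets.items()
        for i in indices
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
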