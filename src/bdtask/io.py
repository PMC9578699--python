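"""Readers and writers for the trial-table and policy-table CSV schemas.

Trial CSV schema (UTF-8, header mandatory), one row per trial:
``participant_id, design, environment, block, trial, capacity,
allocation, outcomes, chosen_supplier, reward, truth_p`` where
``allocation`` lists 1-based supplier ids separated by ';' in allocation
order, ``outcomes`` the aligned 0/1 sample results, ``chosen_supplier``
is 1-based, and ``truth_p`` (synthetic data only) the ';'-separated
per-supplier success probabilities, empty for real data.  Supplier
indices are 0-based in memory; this module owns the conversion.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import pandas as pd

from .task import DESIGNS, SampleAllocation, TrialRecord
from .ideal import OptimalPolicyEntry

__all__ = [
    "TRIAL_COLUMNS",
    "TrialTableError",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "write_policy",
    "read_policy",
]

TRIAL_COLUMNS = (
    "participant_id",
    "design",
    "environment",
    "block",
    "trial",
    "capacity",
    "allocation",
    "outcomes",
    "chosen_supplier",
    "reward",
    "truth_p",
)


class TrialTableError(ValueError):
    """A malformed trial-table row; the message names row and column."""


def write_trials(records: Sequence[TrialRecord], path: Union[str, Path]) -> None:
    """Write trial records to the CSV schema (1-based supplier ids)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_COLUMNS)
        for t in records:
            writer.writerow(
                [
                    t.participant_id,
                    t.design,
                    t.environment,
                    t.block_index,
                    t.trial_index,
                    t.capacity,
                    ";".join(str(i + 1) for i in t.allocation.sequence),
                    ";".join(str(o) for o in t.outcomes),
                    t.chosen_supplier + 1,
                    t.reward,
                    "" if t.truth_p is None
                    else ";".join(repr(p) for p in t.truth_p),
                ]
            )


def _parse_int(value: str, row: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise TrialTableError(
            f"row {row}: column {column!r}: expected integer, got {value!r}"
        ) from None


def read_trials(path: Union[str, Path]) -> List[TrialRecord]:
    """Read and validate a trial-table CSV; raises on the first bad row."""
    records: List[TrialRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(TRIAL_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise TrialTableError(f"missing columns: {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            design = row["design"]
            try:
                seq = tuple(
                    int(s) - 1 for s in row["allocation"].split(";") if s != ""
                )
            except ValueError:
                raise TrialTableError(
                    f"row {rownum}: column 'allocation': malformed "
                    f"{row['allocation']!r}"
                ) from None
            try:
                outcomes = tuple(
                    int(s) for s in row["outcomes"].split(";") if s != ""
                )
            except ValueError:
                raise TrialTableError(
                    f"row {rownum}: column 'outcomes': malformed "
                    f"{row['outcomes']!r}"
                ) from None
            truth_field = row.get("truth_p", "") or ""
            truth = (
                tuple(float(s) for s in truth_field.split(";"))
                if truth_field
                else None
            )
            if design in DESIGNS:
                n_suppliers = DESIGNS[design].n_suppliers
            elif truth is not None:
                n_suppliers = len(truth)
            else:
                n_suppliers = max(seq) + 1 if seq else 1
            try:
                record = TrialRecord(
                    participant_id=row["participant_id"],
                    design=design,
                    environment=row["environment"],
                    block_index=_parse_int(row["block"], rownum, "block"),
                    trial_index=_parse_int(row["trial"], rownum, "trial"),
                    capacity=_parse_int(row["capacity"], rownum, "capacity"),
                    allocation=SampleAllocation(seq, n_suppliers),
                    outcomes=outcomes,
                    chosen_supplier=_parse_int(
                        row["chosen_supplier"], rownum, "chosen_supplier"
                    )
                    - 1,
                    reward=_parse_int(row["reward"], rownum, "reward"),
                    truth_p=truth,
                )
            except ValueError as exc:
                raise TrialTableError(f"row {rownum}: {exc}") from None
            records.append(record)
    return records


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy per-trial frame with derived columns (m, partition, sd)."""
    import numpy as np

    rows = []
    for t in records:
        rows.append(
            {
                "participant_id": t.participant_id,
                "design": t.design,
                "environment": t.environment,
                "block": t.block_index,
                "trial": t.trial_index,
                "capacity": t.capacity,
                "m": t.allocation.m,
                "partition": ";".join(str(p) for p in t.allocation.partition),
                "chosen_supplier": t.chosen_supplier,
                "reward": t.reward,
            }
        )
    return pd.DataFrame(rows)


def write_policy(
    curves: Mapping[str, Sequence[OptimalPolicyEntry]], path: Union[str, Path]
) -> None:
    """Write optimal-policy curves, one row per environment x capacity."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["environment", "capacity", "m_opt", "partition", "expected_reward"]
        )
        for env_label in curves:
            for e in curves[env_label]:
                writer.writerow(
                    [
                        env_label,
                        e.capacity,
                        e.m_opt,
                        ";".join(str(p) for p in e.best_partition),
                        repr(e.expected_reward),
                    ]
                )


def read_policy(path: Union[str, Path]) -> Dict[str, List[OptimalPolicyEntry]]:
    """Read a policy CSV back into per-environment curves."""
    curves: Dict[str, List[OptimalPolicyEntry]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for rownum, row in enumerate(csv.DictReader(fh), start=2):
            try:
                partition = tuple(int(s) for s in row["partition"].split(";"))
                entry = OptimalPolicyEntry(
                    capacity=int(row["capacity"]),
                    best_partition=partition,
                    m_opt=int(row["m_opt"]),
                    expected_value=float(row["expected_reward"]) / 100.0,
                )
            except (KeyError, ValueError) as exc:
                raise TrialTableError(f"policy row {rownum}: {exc}") from None
            curves.setdefault(row["environment"], []).append(entry)
    return curves
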