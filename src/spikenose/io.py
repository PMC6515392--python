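"""Readers and writers for the package's delimited and JSON formats.

Formats
-------
* feature table (CSV/TSV): ``sample_id, analyte, concentration_ppmv,
  S0..S15`` — one exposure per row, S columns holding the steady-state
  resistance features;
* sparse feature lines: the public gas-sensor-array dialect ``label
  idx:value ...`` with 8 transient/steady features per sensor; a
  configurable feature column selects which of the 8 stands in for the
  steady-state response;
* encoded patterns (CSV or JSON records): ``sample_id, analyte,
  R0..R15`` with R columns holding rank_of_sensor;
* spike streams (CSV): ``frame_id, arrival_order, sensor_index``;
* anomaly logs: JSON lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .encoder import N_SENSORS, RankOrderPattern
from .errors import StructuralError
from .reference import RankScoreMatrix
from .streaming import AnomalyRecord
from .synthetic import TABLE_COLUMNS

RANK_COLUMNS = [f"R{i}" for i in range(N_SENSORS)]


def read_feature_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited feature table, inferring comma/tab when sep is None."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise StructuralError(f"feature table {path} lacks columns {missing}")
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_sparse_features(
    path: str | Path,
    feature_column: int = 0,
    features_per_sensor: int = 8,
) -> pd.DataFrame:
    """Read sparse ``label idx:value`` lines into a standard feature table.

    Each line: a label (``analyte`` or ``analyte;concentration``) followed
    by 1-based ``index:value`` pairs, ``features_per_sensor`` consecutive
    features per sensor.  ``feature_column`` (0-based within a sensor's
    block) picks the steady-state stand-in.  Values are magnitudes of
    resistance change; rows with a non-positive selected feature raise.
    """
    rows = []
    for sample_id, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        label, *pairs = line.split()
        if ";" in label:
            analyte, conc = label.split(";", 1)
            concentration = float(conc)
        else:
            analyte, concentration = label, np.nan
        values: dict[int, float] = {}
        for pair in pairs:
            idx, val = pair.split(":", 1)
            values[int(idx) - 1] = float(val)
        row = {
            "sample_id": sample_id,
            "analyte": analyte,
            "concentration_ppmv": concentration,
        }
        for sensor in range(N_SENSORS):
            flat = sensor * features_per_sensor + feature_column
            if flat not in values:
                raise StructuralError(
                    f"line {sample_id}: missing feature {flat + 1} "
                    f"(sensor {sensor}, column {feature_column})"
                )
            row[f"S{sensor}"] = abs(values[flat])
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def patterns_to_frame(
    patterns: Sequence[RankOrderPattern],
    sample_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Tabulate rank-order signatures (one row per pattern)."""
    if sample_ids is None:
        sample_ids = list(range(len(patterns)))
    rows = []
    for sid, p in zip(sample_ids, patterns):
        row = {"sample_id": sid, "analyte": p.analyte}
        row.update({f"R{i}": int(r) for i, r in enumerate(p.rank_of_sensor)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "analyte", *RANK_COLUMNS])


def frame_to_patterns(df: pd.DataFrame) -> list[RankOrderPattern]:
    missing = [c for c in RANK_COLUMNS if c not in df.columns]
    if missing:
        raise StructuralError(f"pattern table lacks columns {missing}")
    return [
        RankOrderPattern(
            np.array([int(row[c]) for c in RANK_COLUMNS]),
            analyte=None if pd.isna(row.get("analyte")) else str(row["analyte"]),
        )
        for _, row in df.iterrows()
    ]


def write_patterns_csv(
    patterns: Sequence[RankOrderPattern],
    path: str | Path,
    sample_ids: Sequence | None = None,
) -> None:
    patterns_to_frame(patterns, sample_ids).to_csv(path, index=False)


def read_patterns_csv(path: str | Path) -> list[RankOrderPattern]:
    return frame_to_patterns(pd.read_csv(path))


def write_patterns_json(
    patterns: Sequence[RankOrderPattern],
    path: str | Path,
    sample_ids: Sequence | None = None,
) -> None:
    if sample_ids is None:
        sample_ids = list(range(len(patterns)))
    records = [
        {
            "sample_id": sid,
            "analyte": p.analyte,
            "rank_of_sensor": p.rank_of_sensor.tolist(),
        }
        for sid, p in zip(sample_ids, patterns)
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_patterns_json(path: str | Path) -> list[RankOrderPattern]:
    records = json.loads(Path(path).read_text())
    return [
        RankOrderPattern(np.asarray(r["rank_of_sensor"]), analyte=r.get("analyte"))
        for r in records
    ]


def write_rank_score_matrix(matrix: RankScoreMatrix, path: str | Path) -> None:
    """Write P_ij(k) as CSV (rows = sensors, columns = ranks)."""
    pd.DataFrame(
        matrix.probs,
        index=pd.Index([f"S{i}" for i in range(N_SENSORS)], name="sensor"),
        columns=[f"rank{j}" for j in range(N_SENSORS)],
    ).to_csv(path)


def write_spike_stream(
    frames: Sequence[tuple[object, RankOrderPattern]], path: str | Path
) -> None:
    """Serialize frames as a spike-event CSV in firing order."""
    rows = [
        {
            "frame_id": fid,
            "arrival_order": order,
            "sensor_index": int(sensor),
        }
        for fid, pattern in frames
        for order, sensor in enumerate(pattern.firing_order)
    ]
    pd.DataFrame(rows, columns=["frame_id", "arrival_order", "sensor_index"]).to_csv(
        path, index=False
    )


def read_spike_stream(path: str | Path) -> list[tuple[object, int]]:
    """Read a spike-event CSV into (frame_id, sensor_index) pairs, ordered
    within each frame by arrival."""
    df = pd.read_csv(path)
    missing = [
        c for c in ("frame_id", "arrival_order", "sensor_index") if c not in df.columns
    ]
    if missing:
        raise StructuralError(f"spike stream lacks columns {missing}")
    # preserve first-appearance frame order from the file
    order = {fid: i for i, fid in enumerate(dict.fromkeys(df["frame_id"]))}
    df = df.sort_values(
        by=["frame_id", "arrival_order"],
        key=lambda col: col.map(order) if col.name == "frame_id" else col,
        kind="stable",
    )
    return [
        (row.frame_id, int(row.sensor_index)) for row in df.itertuples(index=False)
    ]


def parse_spike_lines(lines: Iterable[str]) -> list[tuple[str, int]]:
    """Parse piped ``frame_id,sensor_index`` lines (one spike per line)."""
    events = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            frame_id, sensor = line.split(",")
            events.append((frame_id.strip(), int(sensor)))
        except ValueError as exc:
            raise StructuralError(f"bad spike line {lineno}: {line!r}") from exc
    return events


def write_anomalies(records: Sequence[AnomalyRecord], path: str | Path) -> None:
    """Append-style anomaly log: one JSON object per line."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "frame_id": rec.frame_id,
                        "category": rec.category,
                        "firing_order": list(rec.firing_order),
                    }
                )
                + "\n"
            )


def read_anomalies(path: str | Path) -> list[AnomalyRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        records.append(
            AnomalyRecord(
                frame_id=obj["frame_id"],
                firing_order=tuple(int(s) for s in obj["firing_order"]),
                category=obj.get("category", "unknown"),
            )
        )
    return records
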