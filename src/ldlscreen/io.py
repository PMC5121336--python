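"""Readers and writers for the package's delimited-text interchange formats.

Dialect: comma-separated, UTF-8, ``.`` decimal, mandatory header; tab is
accepted on read.  Lines starting with ``#`` are metadata comments — every
writer embeds the seed and a hash of the run configuration there, so any
output file names the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParseError
from .screen import PLATE_COLS, PLATE_ROWS, Plate, Well

WELL_COLUMNS = [
    "plate_id", "replicate", "well", "role", "gene_id", "sirna_id",
    "intensity", "cell_count", "dead_fraction",
]

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{2})$")


@dataclass
class RunConfig:
    """All tunable thresholds, with the study's published defaults."""

    z_threshold: float = 2.5  # two-sided robust z hit threshold
    zprime_min: float = 0.2  # plate acceptance, strict inequality
    min_cells: int = 100
    max_dead_fraction: float = 0.20
    dil_threshold: float = 50.0  # % inhibition, both duplicates
    tf_threshold: float = 30.0  # % inhibition, strict, both duplicates
    ldlr_fold: float = 2.0
    fusion_k: float = 2.5  # s.d. units, two consecutive frames
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "extra"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def parse_well_label(label: str) -> tuple[str, int]:
    """Parse an ``"A01"``-style well label into (row letter, 1-based column)."""
    m = _WELL_RE.match(str(label).strip())
    if not m:
        raise ParseError(f"malformed well label {label!r} (expected e.g. 'A01')")
    row, col = m.group(1).upper(), int(m.group(2))
    if row not in PLATE_ROWS or col not in PLATE_COLS:
        raise ParseError(f"well {label!r} outside 384-well geometry (rows A-P, cols 1-24)")
    return row, col


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                sep = "\t" if "\t" in line else ","
                break
        else:
            raise ParseError(f"{path}: empty file")
    return pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")


def read_well_table(path: str | Path) -> list[Plate]:
    """Read a well-level screen table into validated :class:`Plate` objects.

    One row per well; required columns ``plate_id, replicate, well, role,
    gene_id, sirna_id, intensity, cell_count, dead_fraction``.  Parse errors
    name the offending row.
    """
    df = _read_delimited(path)
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    plates: dict[tuple, list[Well]] = {}
    for i, rec in enumerate(df.to_dict("records")):
        try:
            row, col = parse_well_label(rec["well"])
            gene = rec["gene_id"] if pd.notna(rec["gene_id"]) else None
            sirna = rec["sirna_id"] if pd.notna(rec["sirna_id"]) else None
            well = Well(
                plate_id=str(rec["plate_id"]),
                row=row,
                col=col,
                role=str(rec["role"]),
                intensity=float(rec["intensity"]),
                cell_count=int(rec["cell_count"]),
                dead_fraction=float(rec["dead_fraction"]),
                gene_id=gene,
                sirna_id=sirna,
            )
        except (ParseError, ValueError, TypeError) as exc:
            raise ParseError(f"{path} row {i + 2}: {exc}") from exc
        plates.setdefault((str(rec["plate_id"]), int(rec["replicate"])), []).append(well)
    return [
        Plate(plate_id=pid, wells=wells, replicate_id=rep)
        for (pid, rep), wells in sorted(plates.items())
    ]


def write_well_table(plates: list[Plate], path: str | Path, config: RunConfig | None = None):
    rows = [
        (p.plate_id, p.replicate_id, w.label, w.role, w.gene_id or "", w.sirna_id or "",
         w.intensity, w.cell_count, w.dead_fraction)
        for p in plates
        for w in p.wells
    ]
    df = pd.DataFrame(rows, columns=WELL_COLUMNS)
    write_table(df, path, config)


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a frame as CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return _read_delimited(path)


def read_sensorgram(trace_path: str | Path, schedule_path: str | Path | None = None):
    """Read a (time_s, response_RU) trace and optional plain-text schedule.

    Schedule format: one ``concentration,start,stop`` line per injection,
    plus an optional ``dissociation_end,<t>`` line (defaults to the trace
    end).
    """
    from .binding import Injection, InjectionSchedule, Sensorgram

    df = _read_delimited(trace_path)
    if df.shape[1] < 2:
        raise ParseError(f"{trace_path}: expected two columns (time_s, response_RU)")
    time, resp = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    schedule = None
    if schedule_path is not None:
        injections, diss_end = [], None
        for i, line in enumerate(Path(schedule_path).read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in re.split(r"[,\t]", line)]
            if parts[0] == "dissociation_end":
                diss_end = float(parts[1])
            else:
                try:
                    conc, start, stop = (float(p) for p in parts[:3])
                except ValueError as exc:
                    raise ParseError(f"{schedule_path} line {i + 1}: {exc}") from exc
                injections.append(Injection(conc, start, stop))
        schedule = InjectionSchedule(
            injections=injections,
            dissociation_end=diss_end if diss_end is not None else float(time[-1]),
        )
    return Sensorgram(time=time, response=resp, schedule=schedule)


def write_run_summary(summary: dict, path: str | Path, config: RunConfig | None = None) -> None:
    """Machine-readable run summary (stage counts etc.) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(summary)
    if config is not None:
        payload["config_hash"] = config.hash()
        payload["seed"] = config.seed
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n", encoding="utf-8")
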