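"""Readers and writers for the interchange formats.

Tabular interchange is TSV/CSV with a header row; lines starting with
``#`` carry provenance (config hash, seed) and are ignored on read.
Sequences travel as FASTA.  Sensor exports use the canonical columns
``timestamp, temp_c, rh_pct, par_umol`` with ISO-8601 timestamps.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    GRID_MINUTES,
    GriddedDay,
    ProteinRecord,
    SensorSeries,
    Thresholds,
)

logger = logging.getLogger(__name__)

_DEFAULT_COLUMNS = {
    "timestamp": "timestamp",
    "temp_c": "temp_c",
    "rh_pct": "rh_pct",
    "par_umol": "par_umol",
}


def provenance_header(meta: Mapping[str, object]) -> str:
    """Render provenance key/value pairs as '#'-prefixed header lines."""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def config_hash(config: Mapping[str, object]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


# --------------------------------------------------------------------------
# sensor series


def read_sensor_csv(
    path: str | Path,
    site: str = "",
    position: str = "air",
    replicate: str = "",
    column_map: Optional[Mapping[str, str]] = None,
    sep: str = ",",
) -> SensorSeries:
    """Parse a sensor logger export.

    ``column_map`` maps canonical names (timestamp/temp_c/rh_pct/
    par_umol) to the file's column names.  Rows with unparseable
    timestamps are rejected with their line numbers; RH outside
    [0, 100] is clipped with a warning.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path, sep=sep, comment="#")
    if cols["timestamp"] not in raw.columns:
        raise ValueError(f"{path}: no timestamp column {cols['timestamp']!r}")
    ts = pd.to_datetime(raw[cols["timestamp"]], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        logger.warning(
            "%s: dropping %d rows with unparseable timestamps (lines %s)",
            path, bad.size, ", ".join(str(i + 2) for i in bad[:10]),
        )
    keep = ~ts.isna()
    if not keep.any():
        raise ValueError(f"{path}: no parseable rows")
    frame = pd.DataFrame(index=pd.DatetimeIndex(ts[keep]))
    for canon in ("temp_c", "rh_pct", "par_umol"):
        name = cols[canon]
        frame[canon] = (
            pd.to_numeric(raw.loc[keep, name], errors="coerce").to_numpy()
            if name in raw.columns
            else np.nan
        )
    out_of_range = (frame["rh_pct"] < 0) | (frame["rh_pct"] > 100)
    if out_of_range.any():
        logger.warning("%s: clipping %d RH readings into [0, 100]",
                       path, int(out_of_range.sum()))
        frame["rh_pct"] = frame["rh_pct"].clip(0.0, 100.0)
    frame["par_umol"] = frame["par_umol"].clip(lower=0.0)
    return SensorSeries(site=site, position=position, replicate=replicate, data=frame)


def write_sensor_csv(
    series: SensorSeries,
    path: str | Path,
    provenance: Optional[Mapping[str, object]] = None,
) -> None:
    """Write the canonical sensor CSV dialect (ISO-8601 timestamps)."""
    frame = series.data.copy()
    frame.insert(0, "timestamp", [t.isoformat() for t in frame.index])
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance_header(provenance))
        frame.to_csv(fh, index=False, float_format="%.4f", lineterminator="\n")


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, default_weight: float = 1.0) -> list[ProteinRecord]:
    """Read predicted proteins; ids are parsed as ``<contig>_<orf>``."""
    records: list[ProteinRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {i} ({rec.id!r}) has an empty sequence")
        contig = rec.id.rsplit("_", 1)[0] if "_" in rec.id else rec.id
        records.append(
            ProteinRecord(
                id=rec.id, contig=contig, sequence=seq,
                weight=default_weight, description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        [
            SeqRecord(Seq(p.sequence), id=p.id, description=p.description)
            for p in records
        ],
        str(path),
        "fasta",
    )


# --------------------------------------------------------------------------
# tables


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    provenance: Optional[Mapping[str, object]] = None,
    index: bool = True,
) -> None:
    """Write a TSV with an optional provenance comment header."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance_header(provenance))
        frame.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    """Feature x sample table; header row = sample ids, first column = feature ids."""
    frame = read_table(path)
    if frame.shape[1] < 1:
        raise ValueError(f"{path}: abundance table has no sample columns")
    return frame.astype(float)


def read_taxonomy_tsv(path: str | Path) -> pd.DataFrame:
    """Feature -> taxonomy labels (columns: domain, phylum[, genus])."""
    tax = read_table(path)
    if "domain" not in tax.columns:
        raise ValueError(f"{path}: taxonomy table needs a 'domain' column")
    return tax


def read_sites_tsv(path: str | Path) -> dict[str, str]:
    """Sample -> site labels (columns: sample, site)."""
    frame = read_table(path, index_col=None)
    if not {"sample", "site"} <= set(frame.columns):
        raise ValueError(f"{path}: needs 'sample' and 'site' columns")
    return dict(zip(frame["sample"].astype(str), frame["site"].astype(str)))


def read_mag_quality_tsv(path: str | Path):
    """MAG quality table (columns: id, completeness, contamination[, taxonomy])."""
    from .types import MAGRecord

    frame = read_table(path, index_col=None)
    need = {"id", "completeness", "contamination"}
    if not need <= set(frame.columns):
        raise ValueError(f"{path}: needs columns {sorted(need)}")
    return [
        MAGRecord(
            id=str(r["id"]),
            completeness=float(r["completeness"]),
            contamination=float(r["contamination"]),
            taxonomy=str(r["taxonomy"]) if "taxonomy" in frame.columns else None,
        )
        for _, r in frame.iterrows()
    ]


def read_pairwise_tsv(path: str | Path) -> pd.DataFrame:
    """Long-format pairwise table (columns: id1, id2, ani, coverage)."""
    frame = read_table(path, index_col=None)
    need = {"id1", "id2", "ani", "coverage"}
    if not need <= set(frame.columns):
        raise ValueError(f"{path}: needs columns {sorted(need)}")
    return frame


def read_annotations_tsv(path: str | Path) -> dict[str, set[str]]:
    """Feature -> annotation tokens (columns: feature, ko[, gene])."""
    frame = read_table(path, index_col=None)
    if "feature" not in frame.columns:
        raise ValueError(f"{path}: needs a 'feature' column")
    out: dict[str, set[str]] = {}
    for _, row in frame.iterrows():
        toks = out.setdefault(str(row["feature"]), set())
        for col in ("ko", "gene"):
            if col in frame.columns and pd.notna(row[col]):
                toks.add(str(row[col]))
    return out


# --------------------------------------------------------------------------
# gridded-day store


def write_grids(
    grids: Sequence[GriddedDay],
    path: str | Path,
    provenance: Optional[Mapping[str, object]] = None,
) -> None:
    """Long-format grid store: one row per grid point."""
    rows = {
        "date": np.repeat([str(g.date) for g in grids], len(GRID_MINUTES)),
        "site": np.repeat([g.site for g in grids], len(GRID_MINUTES)),
        "position": np.repeat([g.position for g in grids], len(GRID_MINUTES)),
        "replicate": np.repeat([g.replicate for g in grids], len(GRID_MINUTES)),
        "variable": np.repeat([g.variable for g in grids], len(GRID_MINUTES)),
        "minute": np.tile(GRID_MINUTES, len(grids)),
        "value": np.concatenate([g.values for g in grids]) if grids else [],
    }
    write_table(pd.DataFrame(rows), path, provenance, index=False)


def read_grids(path: str | Path) -> list[GriddedDay]:
    frame = read_table(path, index_col=None)
    grids = []
    for (date, site, pos, rep, var), sub in frame.groupby(
        ["date", "site", "position", "replicate", "variable"], sort=True, dropna=False
    ):
        sub = sub.sort_values("minute")
        grids.append(
            GriddedDay(
                date=_dt.date.fromisoformat(str(date)),
                variable=str(var),
                values=sub["value"].to_numpy(),
                site="" if pd.isna(site) else str(site),
                position=str(pos),
                replicate="" if pd.isna(rep) else str(rep),
            )
        )
    return grids


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (see ``halocline report``)."""

    out_dir: Path
    seed: int = 0
    record_days: int = 365
    n_sensor_replicates: int = 3
    thresholds: Thresholds = field(default_factory=Thresholds)
    wet_day_min_hours: float = 1.0
    min_run_days: int = 7
    n_taxa: int = 40
    n_replicates_per_site: int = 4
    dryness_sensitivity: float = 2.0
    n_proteins: int = 200
    acidic_bias_dry: float = 2.0
    n_permutations: int = 999
    pka_set: str = "emboss"
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "thresholds"}
        d["out_dir"] = str(self.out_dir)
        d["thresholds"] = self.thresholds.__dict__.copy()
        return d


def load_config(path: str | Path, **overrides) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    th = Thresholds(**raw.pop("thresholds", {}))
    out_dir = Path(raw.pop("out_dir", "halocline_out"))
    return RunConfig(out_dir=out_dir, thresholds=th, **raw)
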