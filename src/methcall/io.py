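"""Tab-separated table formats shared between pipeline stages.

Every table written here starts with a ``#methcall-schema:<name>/<version>``
comment line followed by a header row; readers reject mismatched schemas.
Feature vectors are comma-joined within a single TSV field.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .features import (
    ALL_SIGNAL_FEATURES,
    CORE_SIGNAL_FEATURES,
    ERROR_FEATURES,
    ErrorRecord,
    RawReadEvents,
    ReadWindow,
)

SCHEMA_VERSIONS = {
    "events": 1,
    "errors": 1,
    "features": 1,
    "read_predictions": 1,
    "position_calls": 1,
}


class SchemaError(ValueError):
    """Raised when a table's schema line is missing or mismatched."""


def _write_schema_line(fh, name: str) -> None:
    fh.write(f"#methcall-schema:{name}/{SCHEMA_VERSIONS[name]}\n")


def _check_schema_line(path: str | Path, name: str) -> None:
    with open(path) as fh:
        first = fh.readline().strip()
    expected = f"#methcall-schema:{name}/{SCHEMA_VERSIONS[name]}"
    if first != expected:
        raise SchemaError(f"{path}: expected schema line {expected!r}, found {first!r}")


def _read_table(path: str | Path, name: str) -> pd.DataFrame:
    _check_schema_line(path, name)
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


# ---------------------------------------------------------------- event table


def write_events(path: str | Path, reads: Iterable[RawReadEvents]) -> None:
    with open(path, "w") as fh:
        _write_schema_line(fh, "events")
        fh.write("read_id\tchrom\tstrand\tposition\tbase\tsamples\n")
        for read in reads:
            for pos, base, samples in zip(read.positions, read.bases, read.samples_per_base):
                joined = ",".join(f"{s:.5g}" for s in np.asarray(samples, float))
                fh.write(f"{read.read_id}\t{read.chrom}\t{read.strand}\t{pos}\t{base}\t{joined}\n")


def read_events(path: str | Path) -> list[RawReadEvents]:
    df = _read_table(path, "events")
    reads = []
    for (read_id, chrom, strand), grp in df.groupby(["read_id", "chrom", "strand"], sort=False):
        grp = grp.sort_values("position")
        reads.append(
            RawReadEvents(
                read_id=str(read_id),
                chrom=str(chrom),
                strand=str(strand),
                positions=[int(p) for p in grp["position"]],
                bases=[str(b) for b in grp["base"]],
                samples_per_base=[
                    np.array([float(v) for v in str(s).split(",")]) for s in grp["samples"]
                ],
            )
        )
    return reads


# ---------------------------------------------------------------- error table


def write_errors(path: str | Path, records: Iterable[ErrorRecord]) -> None:
    with open(path, "w") as fh:
        _write_schema_line(fh, "errors")
        fh.write("read_id\tposition\tstatus\tquality\tbase\n")
        for rec in records:
            fh.write(f"{rec.read_id}\t{rec.position}\t{rec.status}\t{rec.quality:g}\t{rec.base}\n")


def read_errors(path: str | Path) -> list[ErrorRecord]:
    df = _read_table(path, "errors")
    return [
        ErrorRecord(
            read_id=str(r.read_id),
            position=int(r.position),
            status=str(r.status),
            quality=float(r.quality),
            base=str(r.base),
        )
        for r in df.itertuples()
    ]


# -------------------------------------------------------------- feature table


def feature_columns(extended: bool = False) -> list[str]:
    sig = list(ALL_SIGNAL_FEATURES if extended else CORE_SIGNAL_FEATURES)
    return sig + list(ERROR_FEATURES)


def write_features(path: str | Path, windows: Iterable[ReadWindow], extended: bool = False) -> None:
    cols = feature_columns(extended)
    with open(path, "w") as fh:
        _write_schema_line(fh, "features")
        fh.write(
            "read_id\tchrom\tstrand\tcenter_position\tsequence\t"
            + "\t".join(cols)
            + "\tlabel\n"
        )
        for w in windows:
            vecs = "\t".join(",".join(f"{v:.6g}" for v in w.features[c]) for c in cols)
            label = -1 if w.label is None else int(w.label)
            fh.write(
                f"{w.read_id}\t{w.chrom}\t{w.strand}\t{w.center_position}\t{w.sequence}\t"
                f"{vecs}\t{label}\n"
            )


def read_features(path: str | Path) -> list[ReadWindow]:
    df = _read_table(path, "features")
    meta = {"read_id", "chrom", "strand", "center_position", "sequence", "label"}
    cols = [c for c in df.columns if c not in meta]
    windows = []
    for r in df.itertuples():
        feats = {c: np.array([float(v) for v in str(getattr(r, c)).split(",")]) for c in cols}
        label = int(r.label)
        windows.append(
            ReadWindow(
                read_id=str(r.read_id),
                chrom=str(r.chrom),
                strand=str(r.strand),
                center_position=int(r.center_position),
                sequence=str(r.sequence),
                features=feats,
                label=None if label < 0 else label,
            )
        )
    return windows


# --------------------------------------------------------- read predictions


def write_read_predictions(path: str | Path, predictions: pd.DataFrame) -> None:
    """Columns: read_id, chrom, strand, position, score, call[, label]."""
    with open(path, "w") as fh:
        _write_schema_line(fh, "read_predictions")
        predictions.to_csv(fh, sep="\t", index=False)


def read_read_predictions(path: str | Path) -> pd.DataFrame:
    return _read_table(path, "read_predictions")


# ----------------------------------------------------------- position calls


def write_position_calls(path: str | Path, calls: pd.DataFrame) -> None:
    """bedMethyl-flavoured: chrom, start, end, strand, coverage,
    methylated_frequency, state, log_likelihood_ratio."""
    with open(path, "w") as fh:
        _write_schema_line(fh, "position_calls")
        calls.to_csv(fh, sep="\t", index=False)


def read_position_calls(path: str | Path) -> pd.DataFrame:
    return _read_table(path, "position_calls")


def position_calls_to_bed(calls: pd.DataFrame) -> str:
    """Render position calls as BED6+2 text (no schema line; interoperable)."""
    buf = _io.StringIO()
    for r in calls.itertuples():
        name = "m" if r.state == "methylated" else "u"
        score = int(round(min(1.0, max(0.0, r.methylated_frequency)) * 1000))
        buf.write(
            f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t{r.strand}\t"
            f"{r.coverage}\t{r.methylated_frequency:.4f}\n"
        )
    return buf.getvalue()
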