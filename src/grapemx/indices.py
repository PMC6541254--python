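"""Multiplex fluorescence indices.

A Multiplex reading consists of four channels: far-red fluorescence under
red, green and UV excitation (FRF_R, FRF_G, FRF_UV) and red fluorescence
under red excitation (RF_R). Five ripeness indices are derived on decimal-log
scale:

=========  =======================  ==========================================
index      formula                  sensitive to
=========  =======================  ==========================================
ANTH_RG    log10(FRF_R / FRF_G)     anthocyanin absorbance of green light
FERARI     log10(1 / FRF_R)         anthocyanins (single-signal)
FLAV       log10(FRF_R / FRF_UV)    flavonol UV screening
FLAV_UV    log10(1 / FRF_UV)        flavonols (single-signal variant)
SFR_R      FRF_R / RF_R             chlorophyll degradation (sugar proxy)
=========  =======================  ==========================================

By construction FLAV + FERARI = FLAV_UV exactly: the FRF_R terms cancel in
the sum of logs. Raw signals may first be corrected for residual electronic
offsets and normalized to a fluorescence standard; the study-grade indices
are defined on the normalized signals.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import DataError, InvalidSignalError
from .records import CHANNELS, INDEX_NAMES, ClusterSide, FluorescenceRecord, MxIndexSet

READING_COLUMNS = ["cultivar", "doy", "cluster_side", *CHANNELS]

_IDENTITY = {name: 0.0 for name in CHANNELS}
_UNIT = {name: 1.0 for name in CHANNELS}


def normalize_signals(
    raw: FluorescenceRecord,
    offsets: dict[str, float] | None = None,
    standard: dict[str, float] | None = None,
) -> FluorescenceRecord:
    """Correct residual electronic offsets and scale to a fluorescence standard.

    Each channel becomes ``(raw - offset) / standard``. With zero offsets and a
    unit standard (the defaults) the record is returned unchanged. Metadata is
    preserved.
    """
    offsets = {**_IDENTITY, **(offsets or {})}
    standard = {**_UNIT, **(standard or {})}
    corrected = {}
    for name in CHANNELS:
        if not standard[name] > 0:
            raise InvalidSignalError(
                f"standard value for {name!r} must be strictly positive"
            )
        value = (getattr(raw, name) - offsets[name]) / standard[name]
        if not value > 0:
            raise InvalidSignalError(
                f"channel {name!r} non-positive after offset correction "
                f"({getattr(raw, name)!r} - {offsets[name]!r})"
            )
        corrected[name] = value
    return replace(raw, **corrected)


def compute_indices(rec: FluorescenceRecord) -> MxIndexSet:
    """Derive the five Multiplex indices from one (normalized) reading."""
    return MxIndexSet(
        anth_rg=math.log10(rec.frf_r / rec.frf_g),
        ferari=math.log10(1.0 / rec.frf_r),
        flav=math.log10(rec.frf_r / rec.frf_uv),
        flav_uv=math.log10(1.0 / rec.frf_uv),
        sfr_r=rec.frf_r / rec.rf_r,
    )


def compute_indices_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized index computation over a readings table.

    The input must carry the four channel columns; the five index columns are
    appended (existing columns are preserved).
    """
    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise DataError(f"missing channel column(s): {missing}")
    channels = frame[list(CHANNELS)].to_numpy(dtype=float)
    if not (channels > 0).all():
        bad = [CHANNELS[j] for j in np.unique(np.nonzero(~(channels > 0))[1])]
        raise InvalidSignalError(f"non-positive values in channel(s): {bad}")
    out = frame.copy()
    frf_r, frf_g, frf_uv, rf_r = channels.T
    out["anth_rg"] = np.log10(frf_r / frf_g)
    out["ferari"] = np.log10(1.0 / frf_r)
    out["flav"] = np.log10(frf_r / frf_uv)
    out["flav_uv"] = np.log10(1.0 / frf_uv)
    out["sfr_r"] = frf_r / rf_r
    return out


def read_readings_csv(path) -> pd.DataFrame:
    """Read a flat CSV of readings (header required, '.' decimal)."""
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise DataError(f"input file not found: {path}") from exc
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing channel column(s): {missing}")
    return frame


def write_readings_csv(frame: pd.DataFrame, path) -> None:
    """Write a readings (or readings + indices) table; indices to 4 decimals."""
    out = frame.copy()
    for col in (*CHANNELS, *INDEX_NAMES):
        if col in out.columns:
            out[col] = out[col].round(4)
    out.to_csv(path, index=False)


def frame_to_records(frame: pd.DataFrame) -> list[FluorescenceRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            FluorescenceRecord(
                frf_r=float(row.frf_r),
                frf_g=float(row.frf_g),
                frf_uv=float(row.frf_uv),
                rf_r=float(row.rf_r),
                cultivar=str(getattr(row, "cultivar", "")),
                doy=int(getattr(row, "doy", 1)),
                cluster_side=ClusterSide(str(getattr(row, "cluster_side", "unspecified"))),
            )
        )
    return records
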