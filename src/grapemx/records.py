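"""Core data records.

Three flat records travel through the pipeline:

* :class:`FluorescenceRecord` — one Multiplex reading: four fluorescence
  channels (far-red emission under red, green and UV excitation, plus red
  emission under red excitation) together with cultivar / day-of-year /
  cluster-side metadata.
* :class:`MxIndexSet` — the five derived optical indices for one reading.
* :class:`RipeningSample` — one destructive wet-chemistry observation.

Channels are relative (fluorescence-standard) units and must be strictly
positive for any of the log-ratio indices to exist.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum

from .errors import DataError, InvalidSignalError

CHANNELS = ("frf_r", "frf_g", "frf_uv", "rf_r")
INDEX_NAMES = ("anth_rg", "ferari", "flav", "flav_uv", "sfr_r")


class ClusterSide(str, Enum):
    """Which face of the grape cluster the sensor pointed at."""

    SW = "SW"
    NE = "NE"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class FluorescenceRecord:
    frf_r: float
    frf_g: float
    frf_uv: float
    rf_r: float
    cultivar: str = ""
    doy: int = 1
    cluster_side: ClusterSide = ClusterSide.UNSPECIFIED

    def __post_init__(self):
        for name in CHANNELS:
            value = getattr(self, name)
            if not value > 0:
                raise InvalidSignalError(
                    f"channel {name!r} must be strictly positive, got {value!r}"
                )
        if not 1 <= self.doy <= 366:
            raise DataError(f"doy must be in 1..366, got {self.doy!r}")

    def channels(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in CHANNELS}


@dataclass(frozen=True)
class MxIndexSet:
    """The five Multiplex indices for one reading (log indices in decimal-log units)."""

    anth_rg: float
    ferari: float
    flav: float
    flav_uv: float
    sfr_r: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


@dataclass(frozen=True)
class RipeningSample:
    """One destructive wet-chemistry observation of berry ripeness.

    Anthocyanins are carried on both unit bases: per gram of fresh whole-berry
    mass (``anth_berry``) and per gram of fresh skin mass (``anth_skin``); the
    two are linked by the skin-to-berry fresh-mass percentage.
    """

    cultivar: str
    doy: int
    tss: float  # total soluble solids, °Brix
    ta: float  # titratable acidity, g/L tartaric-acid equivalent
    ph: float
    malic: float  # g/L
    anth_berry: float  # mg/g fresh berry mass
    anth_skin: float  # mg/g fresh skin mass
    phenols_berry: float  # mg/g fresh berry mass
    flavonols_skin: float  # mg/g dry skin mass
    berry_mass: float  # g
    skin_to_berry_pct: float  # %

    def __post_init__(self):
        for name in ("tss", "ta", "malic", "anth_berry", "anth_skin",
                     "phenols_berry", "flavonols_skin"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")
        if not self.berry_mass > 0:
            raise DataError("berry_mass must be positive")
        if not 0 < self.skin_to_berry_pct <= 100:
            raise DataError("skin_to_berry_pct must be in (0, 100]")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
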