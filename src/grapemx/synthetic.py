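"""Synthetic seasonal ripening trajectories and fluorescence readings.

The generator produces the two tables the analysis consumes — wet-chemistry
ripening samples and four-channel fluorescence readings — with the
statistical structure the calibration assumes:

* each chemistry variable follows a single logistic seasonal course anchored
  exactly at its cultivar's harvest value (the pre-veraison lag phase is the
  logistic's lower tail);
* fluorescence channels are built by running the published calibration
  curves *backwards*: anthocyanin fixes the FERARI index (inverse of the
  saturating curve), which fixes FRF_R; the ANTH_RG curve fixes FRF_G; the
  TSS→SFR_R line fixes RF_R (above the 10 °Brix threshold; below it SFR_R
  is drawn from the wide uninformative band seen in the field); the
  flavonol curve fixes FRF_UV;
* noise is multiplicative lognormal on channels and additive Gaussian on
  chemistry, and every stochastic path is reproducible from its seed.

Because channels are constructed from model-implied indices, re-deriving
indices from a zero-noise record reproduces those indices exactly, and
refitting the calibration families on generated data recovers the
generating coefficients — the property the test-suite leans on.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, TSS_THRESHOLD, convert_anth_basis
from .errors import ConfigError
from .indices import compute_indices
from .presets import (
    ANTH_RG_BERRY_MODELS,
    FERARI_ANTH_BERRY_MODELS,
    FLAVONOL_MODELS,
    MALVASIA_R,
    PROFILES,
    SFR_PRETHRESHOLD_BAND,
    SIDE_RELATIONS,
    TSS_SFR_MODELS,
    CultivarProfile,
)
from .records import ClusterSide, FluorescenceRecord, RipeningSample

logger = logging.getLogger(__name__)

CHEM_COLUMNS = [
    "cultivar", "doy", "replicate", "tss", "ta", "ph", "malic",
    "anth_berry", "anth_skin", "phenols_berry", "flavonols_skin",
    "berry_mass", "skin_to_berry_pct",
]

#: Fraction of the sigmoid asymptote at which anthocyanin is clipped before
#: inversion (the curve saturates; higher pigment is optically invisible).
SIGMOID_CLIP_FRAC = 0.98

_SKIN_PCT_BOUNDS = (8.0, 13.0)
_SKIN_PCT_SEASON_DRIFT = 2.0  # percentage points above the harvest anchor


def default_dates(profile: CultivarProfile, n_dates: int = 8) -> list[int]:
    """Weekly sampling dates from veraison onset to the harvest day-of-year."""
    return [profile.harvest_doy - 7 * (n_dates - 1 - i) for i in range(n_dates)]


def _anchored_logistic(doy, initial, target, midpoint, rate, harvest_doy):
    """Logistic course rescaled so the harvest date hits ``target`` exactly."""
    doy = np.asarray(doy, dtype=float)
    s = 1.0 / (1.0 + np.exp(-rate * (doy - midpoint)))
    s_h = 1.0 / (1.0 + np.exp(-rate * (harvest_doy - midpoint)))
    return initial + (target - initial) * s / s_h


def simulate_season(
    profile: CultivarProfile,
    dates: list[int] | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    chem_sigma_frac: float | None = None,
) -> pd.DataFrame:
    """Simulate destructive ripening samples for one cultivar over a season.

    Returns one row per date × replicate with the wet-chemistry schema.
    ``chem_sigma_frac`` overrides the profile's relative replicate noise
    (0 gives the exact deterministic trajectories).
    """
    if dates is None:
        dates = default_dates(profile)
    if len(dates) == 0:
        return pd.DataFrame(columns=CHEM_COLUMNS)
    if sorted(dates) != list(dates):
        raise ConfigError("sampling dates must be sorted ascending")
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    sigma = profile.chem_sigma_frac if chem_sigma_frac is None else chem_sigma_frac
    rng = np.random.default_rng(seed)

    doy = np.asarray(dates, dtype=float)
    p = profile
    traj = {
        "tss": _anchored_logistic(doy, p.tss_onset, p.tss_harvest,
                                  p.midpoint_doy, p.rate_per_day, p.harvest_doy),
        "ta": _anchored_logistic(doy, p.ta_initial, p.ta_harvest,
                                 p.midpoint_doy, p.rate_per_day, p.harvest_doy),
        "ph": _anchored_logistic(doy, p.ph_initial, p.ph_harvest,
                                 p.midpoint_doy, p.rate_per_day, p.harvest_doy),
        "malic": _anchored_logistic(doy, p.malic_initial, p.malic_harvest,
                                    p.midpoint_doy, p.rate_per_day, p.harvest_doy),
        "anth_berry": _anchored_logistic(doy, 0.0, p.anth_max_berry,
                                         p.anth_midpoint_doy, p.anth_rate_per_day,
                                         p.harvest_doy),
        "phenols_berry": _anchored_logistic(doy, 0.6 * p.phenols_harvest,
                                            p.phenols_harvest, p.midpoint_doy,
                                            p.rate_per_day, p.harvest_doy),
        "flavonols_skin": _anchored_logistic(doy, p.flavonols_initial,
                                             p.flavonols_harvest, p.midpoint_doy,
                                             p.rate_per_day, p.harvest_doy),
        "berry_mass": _anchored_logistic(doy, 0.5 * p.berry_mass_harvest,
                                         p.berry_mass_harvest, p.midpoint_doy,
                                         p.rate_per_day, p.harvest_doy),
    }
    # relative skin mass drifts down linearly toward its harvest anchor
    span = max(doy[-1] - doy[0], 1.0)
    skin_pct = p.skin_pct_harvest + _SKIN_PCT_SEASON_DRIFT * (doy[-1] - doy) / span
    traj["skin_to_berry_pct"] = np.clip(skin_pct, *_SKIN_PCT_BOUNDS)

    rows = []
    for rep in range(n_replicates):
        row = {"cultivar": p.name, "doy": np.asarray(dates, dtype=int),
               "replicate": rep}
        for name, values in traj.items():
            scale = sigma * abs(values).max()
            noisy = values + rng.normal(0.0, scale, size=len(values)) if scale > 0 \
                else values.copy()
            if name != "ph":
                noisy = np.clip(noisy, 0.0, None)
            if name == "skin_to_berry_pct":
                noisy = np.clip(noisy, *_SKIN_PCT_BOUNDS)
            row[name] = noisy
        rows.append(pd.DataFrame(row))
    frame = pd.concat(rows, ignore_index=True)
    frame["anth_skin"] = frame["anth_berry"] / (frame["skin_to_berry_pct"] / 100.0)
    return frame[CHEM_COLUMNS].sort_values(["doy", "replicate"], ignore_index=True)


def samples_from_frame(frame: pd.DataFrame) -> list[RipeningSample]:
    return [
        RipeningSample(
            cultivar=str(r.cultivar), doy=int(r.doy), tss=float(r.tss),
            ta=float(r.ta), ph=float(r.ph), malic=float(r.malic),
            anth_berry=float(r.anth_berry), anth_skin=float(r.anth_skin),
            phenols_berry=float(r.phenols_berry),
            flavonols_skin=float(r.flavonols_skin),
            berry_mass=float(r.berry_mass),
            skin_to_berry_pct=float(r.skin_to_berry_pct),
        )
        for r in frame.itertuples(index=False)
    ]


def anchor_models(profile: CultivarProfile) -> dict[str, CalibrationModel]:
    """The calibration set used to place fluorescence channels for a profile.

    Cultivars without their own anthocyanin calibration (the whites) borrow
    the low-pigment Malvasia R. linear relations, which at zero anthocyanin
    yield a small positive FERARI baseline.
    """
    name = profile.name
    return {
        "ferari_anth": FERARI_ANTH_BERRY_MODELS.get(
            name, FERARI_ANTH_BERRY_MODELS[MALVASIA_R]),
        "anth_rg": ANTH_RG_BERRY_MODELS.get(name, ANTH_RG_BERRY_MODELS[MALVASIA_R]),
        "tss_sfr": TSS_SFR_MODELS.get(name, TSS_SFR_MODELS[MALVASIA_R]),
        "flav_uv": FLAVONOL_MODELS.get(name, FLAVONOL_MODELS["pooled"]),
    }


def _ferari_from_anth(model: CalibrationModel, anth: float) -> float:
    if model.family == "sigmoid":
        a = model.coefficients[0]
        lo = model.predict(0.0)  # index floor: curve value at index 0
        hi = SIGMOID_CLIP_FRAC * a
        if anth > hi:
            logger.warning(
                "anthocyanin %.3f mg/g above the %.2f saturation of the "
                "FERARI curve; clipping", anth, a)
        y = min(max(anth, lo), hi)
        return float(model.invert(y))
    return float(model.invert(anth))


def synthesize_fluorescence(
    sample: RipeningSample,
    profile: CultivarProfile,
    models: dict[str, CalibrationModel] | None = None,
    rng: np.random.Generator | int | None = None,
    channel_sigma: float | None = None,
    tss_threshold: float = TSS_THRESHOLD,
) -> FluorescenceRecord:
    """Build a four-channel reading consistent with one ripening sample."""
    models = models or anchor_models(profile)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng or 0)
    sigma = profile.channel_sigma if channel_sigma is None else channel_sigma

    ferari = _ferari_from_anth(models["ferari_anth"], sample.anth_berry)
    anth_rg = float(models["anth_rg"].predict(sample.anth_berry))
    flav_uv = float(models["flav_uv"].predict(sample.flavonols_skin))
    if sample.tss >= tss_threshold:
        # floor guards degenerate TSS lines whose prediction crosses zero
        sfr = max(float(models["tss_sfr"].predict(sample.tss)), 0.02)
    else:
        sfr = float(rng.uniform(*SFR_PRETHRESHOLD_BAND))

    frf_r = 10.0 ** (-ferari)
    frf_g = frf_r * 10.0 ** (-anth_rg)
    frf_uv = 10.0 ** (-flav_uv)
    rf_r = frf_r / sfr
    channels = np.array([frf_r, frf_g, frf_uv, rf_r])
    if sigma > 0:
        channels = channels * rng.lognormal(0.0, sigma, size=4)
    return FluorescenceRecord(
        frf_r=float(channels[0]), frf_g=float(channels[1]),
        frf_uv=float(channels[2]), rf_r=float(channels[3]),
        cultivar=sample.cultivar, doy=sample.doy,
    )


def synthesize_fluorescence_frame(
    chem: pd.DataFrame,
    profile: CultivarProfile,
    models: dict[str, CalibrationModel] | None = None,
    seed: int = 0,
    channel_sigma: float | None = None,
) -> pd.DataFrame:
    """Chemistry table → chemistry + channel columns (one reading per row)."""
    rng = np.random.default_rng(seed)
    records = [
        synthesize_fluorescence(s, profile, models=models, rng=rng,
                                channel_sigma=channel_sigma)
        for s in samples_from_frame(chem)
    ]
    out = chem.copy().reset_index(drop=True)
    for name in ("frf_r", "frf_g", "frf_uv", "rf_r"):
        out[name] = [getattr(r, name) for r in records]
    out["cluster_side"] = ClusterSide.UNSPECIFIED.value
    return out


def simulate_cluster_sides(
    records: list[FluorescenceRecord],
    side_relations: dict[str, CalibrationModel] | None = None,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> list[tuple[FluorescenceRecord, FluorescenceRecord]]:
    """Pair each reading (taken as the NE face) with a simulated SW face.

    The SW-face indices are the NE indices mapped through the per-index
    linear side relations (plus optional Gaussian noise on the index scale);
    channels are then rebuilt from the mapped indices.
    """
    relations = side_relations or SIDE_RELATIONS
    required = ("anth_rg", "ferari", "flav_uv", "sfr_r")
    missing = [k for k in required if k not in relations]
    if missing:
        raise ConfigError(f"missing side relation(s) for: {missing}")
    for key in required:
        if relations[key].coefficients[0] <= 0:
            raise ConfigError(f"side relation slope for {key!r} must be positive")
    rng = np.random.default_rng(seed)
    pairs = []
    for rec in records:
        ne = replace(rec, cluster_side=ClusterSide.NE)
        idx = compute_indices(rec)
        mapped = {
            key: float(relations[key].predict(getattr(idx, key)))
            + (rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0)
            for key in required
        }
        frf_r = 10.0 ** (-mapped["ferari"])
        sw = FluorescenceRecord(
            frf_r=frf_r,
            frf_g=frf_r * 10.0 ** (-mapped["anth_rg"]),
            frf_uv=10.0 ** (-mapped["flav_uv"]),
            rf_r=frf_r / mapped["sfr_r"],
            cultivar=rec.cultivar, doy=rec.doy, cluster_side=ClusterSide.SW,
        )
        pairs.append((sw, ne))
    return pairs
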