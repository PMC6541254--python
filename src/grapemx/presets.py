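"""Published field-calibration constants and cultivar presets.

The single-season Colli Piacentini field calibrations for five cultivars —
two whites (Ortrugo, Malvasia di Candia aromatica), one pink (Malvasia
Rosa) and two reds (Barbera, Ervi) — are encoded here as
:class:`~grapemx.calibration.CalibrationModel` records. They anchor the
synthetic generator and serve as ground truth for parameter-recovery tests.

Orientation conventions (they differ between relationships, reflecting how
the curves are used):

* FERARI → anthocyanin models map the index (x) to the chemistry (y); the
  generator *inverts* them to place an index on a simulated berry.
* ANTH_RG ← anthocyanin models map the chemistry (x) to the index (y): the
  bi-phasic quartic (index peaks near full coloring, then declines) is only
  single-valued in that direction.
* TSS → SFR_R and flavonols → FLAV_UV models map chemistry (x) to index (y),
  the direction the generator evaluates them in.
* Cluster-side relations map the north-east-facing reading (x) to the
  south-west-facing reading (y) of the same cluster, per index.

The berry-basis anthocyanin models are expressed in mg/g fresh whole-berry
mass; the skin-basis variants in mg/g fresh skin mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calibration import CalibrationModel, TSS_THRESHOLD

ORTRUGO = "Ortrugo"
MALVASIA_CA = "Malvasia C.a."
MALVASIA_R = "Malvasia R."
BARBERA = "Barbera"
ERVI = "Ervi"

CULTIVARS = (ORTRUGO, MALVASIA_CA, MALVASIA_R, BARBERA, ERVI)

#: n of the per-cultivar seasonal calibration fits.
CALIBRATION_N = 27


def _lin(m, q, x_name, y_name, domain=None, r2=None, n=None):
    return CalibrationModel("linear", (m, q), x_name=x_name, y_name=y_name,
                            domain=domain, r2=r2, n=n)


def _sig(a, b, c, x_name, y_name, r2=None, n=None):
    return CalibrationModel("sigmoid", (a, b, c), x_name=x_name, y_name=y_name,
                            r2=r2, n=n)


def _quartic(coeffs, x_name, y_name, r2=None, n=None):
    return CalibrationModel("polynomial", tuple(coeffs), degree=4,
                            x_name=x_name, y_name=y_name, r2=r2, n=n)


# -- SFR_R as a function of TSS (°Brix), valid for TSS >= 10 ----------------
TSS_SFR_MODELS = {
    ORTRUGO: _lin(-0.0205, 0.8906, "tss", "sfr_r", domain=(TSS_THRESHOLD, None),
                  r2=0.71, n=12),
    MALVASIA_CA: _lin(-0.0096, 0.7476, "tss", "sfr_r", domain=(TSS_THRESHOLD, None),
                      r2=0.50, n=12),
    MALVASIA_R: _lin(-0.0144, 0.8405, "tss", "sfr_r", domain=(TSS_THRESHOLD, None),
                     r2=0.68, n=21),
    BARBERA: _lin(-0.063, 0.7375, "tss", "sfr_r", domain=(TSS_THRESHOLD, None),
                  r2=0.04, n=21),
    ERVI: _lin(-0.0112, 0.8398, "tss", "sfr_r", domain=(TSS_THRESHOLD, None),
               r2=0.37, n=21),
}

#: SFR_R is uninformative below the TSS threshold; field readings there fall
#: in a wide band of Mx units.
SFR_PRETHRESHOLD_BAND = (0.5, 1.1)

# -- FLAV_UV as a function of total flavonols (mg/g dry skin) ---------------
FLAVONOL_MODELS = {
    "pooled": CalibrationModel("polynomial", (-0.1105, 0.7613, 0.628), degree=2,
                               x_name="flavonols_skin", y_name="flav_uv",
                               r2=0.35, n=41),
    BARBERA: CalibrationModel("polynomial", (-0.1331, 0.5898, 1.589), degree=2,
                              x_name="flavonols_skin", y_name="flav_uv",
                              r2=0.66, n=9),
    ERVI: CalibrationModel("polynomial", (-0.0886, 0.2592, 2.5412), degree=2,
                           x_name="flavonols_skin", y_name="flav_uv",
                           r2=0.64, n=9),
}

# -- anthocyanins (berry basis) as a function of FERARI ---------------------
FERARI_ANTH_BERRY_MODELS = {
    MALVASIA_R: _lin(3.7167, -0.1982, "ferari", "anth_berry", r2=0.84,
                     n=CALIBRATION_N),
    BARBERA: _sig(1.55, 4.005, 5.261, "ferari", "anth_berry", r2=0.99,
                  n=CALIBRATION_N),
    ERVI: _sig(1.47, 4.132, 5.906, "ferari", "anth_berry", r2=0.97,
               n=CALIBRATION_N),
}

# -- anthocyanins (skin basis) and FERARI -----------------------------------
# For Malvasia R. the line maps index -> chemistry; for the reds the printed
# sigmoids are only dimensionally consistent mapping skin-basis anthocyanin
# (x, up to ~20 mg/g) to the index (y), so they are stored in that
# orientation.
FERARI_ANTH_SKIN_MODELS = {
    MALVASIA_R: _lin(0.313, -0.1403, "ferari", "anth_skin", r2=0.64,
                     n=CALIBRATION_N),
    BARBERA: _sig(1.533, 4.690, 0.635, "anth_skin", "ferari", r2=0.99,
                  n=CALIBRATION_N),
    ERVI: _sig(1.471, 11.064, 1.088, "anth_skin", "ferari", r2=0.98,
               n=CALIBRATION_N),
}

# -- ANTH_RG as a function of anthocyanins (berry basis) --------------------
# Bi-phasic for the strong accumulators: the green-excited channel decays
# faster than the red-excited one, so the log-ratio peaks near full coloring
# and then declines. The Barbera x^1 coefficient is taken positive; the
# negative sign renders the curve monotone negative, contradicting its
# described peak-then-decline shape.
ANTH_RG_BERRY_MODELS = {
    MALVASIA_R: _lin(2.6675, -0.0891, "anth_berry", "anth_rg", r2=0.82,
                     n=CALIBRATION_N),
    BARBERA: _quartic((-0.102, 0.7315, -1.6365, 1.2373, -0.102),
                      "anth_berry", "anth_rg", r2=0.85, n=CALIBRATION_N),
    ERVI: _quartic((-0.0081, 0.2422, -0.8925, 0.9441, -0.1142),
                   "anth_berry", "anth_rg", r2=0.91, n=CALIBRATION_N),
}

# -- ANTH_RG and anthocyanins (skin basis) ----------------------------------
ANTH_RG_SKIN_MODELS = {
    MALVASIA_R: _lin(0.2527, -0.0893, "anth_skin", "anth_rg", r2=0.79,
                     n=CALIBRATION_N),
    BARBERA: _quartic((-3e-05, 0.0018, -0.0319, 0.1946, -0.1191),
                      "anth_skin", "anth_rg", r2=0.94, n=CALIBRATION_N),
    ERVI: _quartic((-4e-06, 0.0004, -0.0106, 0.1057, -0.1238),
                   "anth_skin", "anth_rg", r2=0.91, n=CALIBRATION_N),
}

# -- cluster-side concordance (NE reading -> SW reading, per index) ---------
SIDE_RELATIONS = {
    "anth_rg": _lin(0.8537, 0.0014, "NE", "SW", r2=0.94, n=27),
    "ferari": _lin(0.9131, 0.0026, "NE", "SW", r2=0.97, n=27),
    "flav_uv": _lin(0.951, 0.0433, "NE", "SW", r2=0.95, n=41),
    "sfr_r": _lin(0.7180, 0.1372, "NE", "SW", r2=0.75, n=41),
}


# ---------------------------------------------------------------------------
# cultivar profiles for the synthetic generator


@dataclass(frozen=True)
class CultivarProfile:
    """Seasonal ripening anchors and trajectory shape for one cultivar.

    Harvest anchors are the observed single-season values; trajectory
    midpoints/rates describe single-logistic seasonal courses from the
    veraison-onset plateau to the harvest value. ``side_bias`` is the extra
    SFR_R offset of the sun-exposed (SW) side early in the season;
    ``channel_sigma`` is the multiplicative lognormal noise of each
    fluorescence channel and ``chem_sigma_frac`` the relative replicate
    noise of the wet-chemistry variables.
    """

    name: str
    tss_harvest: float  # °Brix
    tss_onset: float = 5.0  # °Brix at veraison onset
    ta_initial: float = 25.0  # g/L at lag phase
    ta_harvest: float = 6.0
    malic_initial: float = 15.0  # g/L
    malic_harvest: float = 0.5
    ph_initial: float = 2.75
    ph_harvest: float = 3.1
    anth_max_berry: float = 0.0  # mg/g fresh berry (0 for whites)
    phenols_harvest: float = 2.0  # mg/g fresh berry
    flavonols_harvest: float = 1.0  # mg/g dry skin
    flavonols_initial: float = 0.5
    skin_pct_harvest: float = 9.0  # %
    berry_mass_harvest: float = 1.7  # g
    harvest_doy: int = 249
    midpoint_doy: float = 215.0  # logistic midpoint, day of year
    rate_per_day: float = 0.12  # logistic steepness
    anth_midpoint_doy: float = 222.0
    anth_rate_per_day: float = 0.15
    side_bias: float = 0.05  # early-season SW-NE SFR_R offset (Mx units)
    channel_sigma: float = 0.03  # lognormal sigma per channel
    chem_sigma_frac: float = 0.03  # relative additive noise on chemistry


PROFILES = {
    ORTRUGO: CultivarProfile(
        name=ORTRUGO, tss_harvest=22.3, ta_harvest=4.96, malic_harvest=0.23,
        ph_harvest=3.14, anth_max_berry=0.0, phenols_harvest=1.93,
        flavonols_harvest=1.35, skin_pct_harvest=8.96,
        berry_mass_harvest=1.81, harvest_doy=233, midpoint_doy=208.0,
    ),
    MALVASIA_CA: CultivarProfile(
        name=MALVASIA_CA, tss_harvest=19.9, ta_harvest=6.38, malic_harvest=0.57,
        ph_harvest=2.95, anth_max_berry=0.0, phenols_harvest=2.50,
        flavonols_harvest=1.19, skin_pct_harvest=8.70,
        berry_mass_harvest=1.69, harvest_doy=233, midpoint_doy=208.0,
    ),
    MALVASIA_R: CultivarProfile(
        name=MALVASIA_R, tss_harvest=22.9, ta_harvest=6.04, malic_harvest=0.86,
        ph_harvest=3.17, anth_max_berry=0.20, phenols_harvest=2.23,
        flavonols_harvest=0.68, flavonols_initial=0.4, skin_pct_harvest=9.08,
        berry_mass_harvest=1.95, harvest_doy=249,
    ),
    BARBERA: CultivarProfile(
        name=BARBERA, tss_harvest=27.2, ta_harvest=9.21, malic_harvest=0.88,
        ph_harvest=3.07, anth_max_berry=1.68, phenols_harvest=2.89,
        flavonols_harvest=2.11, flavonols_initial=1.2, skin_pct_harvest=9.82,
        berry_mass_harvest=1.62, harvest_doy=249,
    ),
    ERVI: CultivarProfile(
        name=ERVI, tss_harvest=26.7, ta_harvest=6.67, malic_harvest=1.11,
        ph_harvest=3.19, anth_max_berry=1.91, phenols_harvest=3.78,
        flavonols_harvest=2.84, flavonols_initial=1.6, skin_pct_harvest=9.35,
        berry_mass_harvest=1.47, harvest_doy=249,
    ),
}

#: Suffix-tolerant profile lookup ("Barbera-like" -> Barbera preset).
def get_profile(name: str) -> CultivarProfile:
    key = name.removesuffix("-like").strip()
    for cultivar in PROFILES:
        if cultivar.lower() == key.lower():
            return PROFILES[cultivar]
    raise KeyError(
        f"unknown cultivar profile {name!r}; known: {', '.join(PROFILES)}"
    )
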