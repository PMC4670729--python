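"""Simulator configuration and per-medium calibrations.

The mechanistic model is a calibration device, not a mechanistic claim: it is
the minimal ODE system that reproduces the phenomenology of an E. coli strain
whose rpoBC operon (RNA polymerase beta/beta' subunits) is under IPTG control —
preculture carry-over of polymerase that dilutes out, an ultrasensitive (Hill)
dependence of growth rate on the beta' pool, an mCherry maturation lag, and
glucose-to-glycerol conversion whose instantaneous yield roughly doubles on
growth arrest.

Units: time in minutes throughout; beta' pool and reporter in arbitrary
concentration units (a.u.) normalized so that the growth threshold ``hill_K``
is 1; biomass in background-corrected absorbance units at 600 nm; substrate
and product in g/L; IPTG in uM.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field


#: OD600 = ABS_TO_OD * absorbance for the microplates emulated here.
ABS_TO_OD = 2.34

#: g dry weight per liter per OD600 unit, used to convert the biomass yield
#: Y_biomass (g biomass per g substrate) into absorbance units per g/L.
GDW_PER_OD = 0.4


@dataclass
class SimConfig:
    """Parameters of the growth-switch simulator.

    The defaults are the reference "M9-glc" calibration (M9 minimal medium
    with 0.2% glucose). Use :func:`medium_config` for the other media and
    :func:`production_config` for shake-flask glycerol production runs.
    """

    medium: str = "M9-glc"
    #: maximal growth rate supported by the medium (1/min)
    mu_max: float = 0.012
    #: Hill exponent of the growth rate vs beta' concentration
    hill_n: float = 10.0
    #: beta' concentration at half-maximal growth (a.u.)
    hill_K: float = 1.0
    #: maximal rpoBC promoter activity (a.u./min)
    k_tx_max: float = 0.030
    #: IPTG level of half-maximal induction (uM)
    K_iptg: float = 36.0
    #: effective cooperativity of induction (h=1 is Michaelis-Menten)
    iptg_hill: float = 5.0
    #: first-order depletion rate of the beta' (and fused reporter) pool
    #: (1/min); slow proteolysis/leakage on top of growth dilution
    deg_rate: float = 0.002
    #: mCherry maturation rate (1/min), ~25 min half-time
    k_mat: float = 0.028
    #: beta' carried over from the overnight preculture (a.u.); the default is
    #: the stationary-phase fixed point k_tx_max/deg_rate, where synthesis
    #: continues but growth dilution has stopped
    c0: float = 15.0
    #: initial biomass above background (absorbance units; OD600 0.01)
    A0: float = 0.0043
    #: background absorbance of medium + plate
    A_bg: float = 0.04
    #: initial substrate (g/L)
    glc0: float = 2.0
    #: biomass yield on substrate (g biomass per g substrate; effective value,
    #: medium-dependent because rich media feed biomass from amino acids)
    Y_biomass: float = 0.45
    #: maximal specific substrate uptake, g substrate per (absorbance unit * L * min)
    q_max: float = 0.05
    #: Monod constant for substrate uptake (g/L; PTS-level affinity)
    K_glc: float = 0.01
    #: maintenance-only specific uptake, g substrate per (absorbance unit * L * min);
    #: the residual uptake of non-producing strains when growth stops
    q_maint: float = 0.002
    #: fraction of non-biomass substrate carbon routed to glycerol (gly strains)
    f_branch: float = 0.0
    #: fluorescence gain: RFU per (a.u. reporter * absorbance unit)
    phi: float = 1.0
    #: autofluorescence coefficient: RFU per observed absorbance unit
    autofluo: float = 2.5
    #: relative (multiplicative lognormal) absorbance noise SD
    noise_abs: float = 0.01
    #: additive Gaussian fluorescence noise SD (RFU)
    noise_fluo: float = 0.01
    #: minutes between samples
    dt_sample: float = 2.0
    #: RNG seed
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = (
            "mu_max", "hill_K", "k_tx_max", "K_iptg", "deg_rate", "k_mat",
            "c0", "A0", "A_bg", "glc0", "Y_biomass", "q_max", "K_glc",
            "phi", "autofluo", "noise_abs", "noise_fluo",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.iptg_hill < 1:
            raise ValueError("iptg_hill must be >= 1")
        if not 0.0 <= self.f_branch <= 1.0:
            raise ValueError("f_branch must lie in [0, 1]")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")

    @property
    def Y_biomass_abs(self) -> float:
        """Biomass yield in absorbance units per (g/L) of substrate."""
        return self.Y_biomass / (ABS_TO_OD * GDW_PER_OD)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


#: medium calibrations: maximal growth rate (1/min) and effective biomass yield.
#: k_tx_max is scaled with mu_max so that the fully induced steady-state beta'
#: pool sits ~2x above the growth threshold in every medium.
MEDIA: dict[str, dict[str, float]] = {
    "M9-glc": {"mu_max": 0.012, "Y_biomass": 0.45},
    "M9-glc-CAA": {"mu_max": 0.016, "Y_biomass": 0.75},
    "LB-glc": {"mu_max": 0.027, "Y_biomass": 1.8},
    "M9-succ": {"mu_max": 0.009, "Y_biomass": 0.40},
}

#: ratio of fully induced promoter activity to mu_max * hill_K
KTX_OVER_MU = 2.5


def medium_config(medium: str = "M9-glc", **overrides) -> SimConfig:
    """Reference calibration for one of the four characterized media."""
    if medium not in MEDIA:
        raise KeyError(
            f"unknown medium {medium!r}; expected one of {sorted(MEDIA)}"
        )
    cal = MEDIA[medium]
    params: dict = {
        "medium": medium,
        "mu_max": cal["mu_max"],
        "Y_biomass": cal["Y_biomass"],
        "k_tx_max": KTX_OVER_MU * cal["mu_max"],
    }
    params.update(overrides)
    return SimConfig(**params)


def production_config(**overrides) -> SimConfig:
    """Shake-flask glycerol-production calibration (M9 + 2 g/L glucose).

    Lower inoculum than the microplate default so that the wild-type strain
    exhausts glucose around 500 min, and the glycerol branch open.
    """
    params: dict = {"A0": 0.0015, "glc0": 2.0, "f_branch": 0.6,
                    "dt_sample": 30.0, "noise_abs": 0.0, "noise_fluo": 0.0}
    params.update(overrides)
    return medium_config("M9-glc", **params)


def write_config(config: SimConfig, path) -> None:
    """Write a config as sectioned key=value text."""
    parser = configparser.ConfigParser()
    parser.optionxform = str          # keys are case-sensitive (hill_K, A0)
    parser["simulation"] = {
        f.name: repr(getattr(config, f.name)) for f in dataclasses.fields(config)
    }
    parser["calibrations"] = {
        m: f"mu_max={c['mu_max']}, Y_biomass={c['Y_biomass']}"
        for m, c in MEDIA.items()
    }
    with open(path, "w") as fh:
        parser.write(fh)


def read_config(path) -> SimConfig:
    """Read a config written by :func:`write_config`."""
    parser = configparser.ConfigParser()
    parser.optionxform = str
    with open(path) as fh:
        parser.read_file(fh)
    fields = {f.name: f.type for f in dataclasses.fields(SimConfig)}
    kwargs = {}
    for key, raw in parser["simulation"].items():
        if key not in fields:
            raise KeyError(f"unknown config key {key!r}")
        val = raw.strip().strip("'\"")
        kwargs[key] = val if key == "medium" else (
            int(val) if key == "seed" else float(val)
        )
    return SimConfig(**kwargs)
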