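"""Rate constants, tissue geometry, unit conversions and validated presets.

The simulator tracks beta-amyloid (Aβ) in a well-mixed 1 mm³ volume of
hippocampal CA1 tissue.  Internally every Aβ pool is a molecule count per
model volume, because generation and microglial uptake rates are given in
molecules per cell per day.  Initial interstitial-fluid concentrations are
quoted in pg/mL and converted once at load time using the Aβ40/Aβ42
monomer masses.

Two conventions matter throughout:

* rates quoted per year (cell-loss rates ``d``, ``k1``, ``k2``, ``k10``)
  compound geometrically to a per-day rate, so that 365 daily steps
  reproduce the annual fraction exactly;
* the baseline interstitial-fluid velocity ``v0`` and the perivascular
  exit rate ``k_exit`` are free flow parameters, fitted by the engine's
  calibration routines against the endpoint anchors in
  :data:`CALIBRATION_ANCHORS`.  The defaults below are the calibrated
  values.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterator, Mapping

from .errors import ParameterError

AVOGADRO = 6.02214076e23
DAYS_PER_YEAR = 365.0

#: Monomer molar masses (Da) of the 40- and 42-residue Aβ peptides.
MW_AB40 = 4330.0
MW_AB42 = 4514.0

#: Literature range for bulk interstitial-fluid velocity, mm/day
#: (0.1–0.3 μm/min).  The calibrated v0 must land inside this window.
V0_BOUNDS = (0.144, 0.43)

#: Endpoint anchors for the two free flow parameters: the 50-year
#: normal-aging parenchymal Aβ40 deposit (molecules) pins v0, and the
#: ApoE4-to-baseline vessel Aβ40 deposit ratio pins k_exit.
CALIBRATION_ANCHORS = {
    "parenchymal_ab40_deposit": 5.929e9,
    "apoe4_vessel_ab40_ratio": 1.96,
}

#: Alternative endothelial senescence rates (fraction/year): the low
#: "unstressed" estimate and the high "stressed" estimate.  The model
#: default is 1 %/yr, which reproduces the observed ~40 % loss of
#: endothelial cells and LRP-1 receptors over a 50-year adult lifespan.
K2_NO_STIM = 0.001
K2_STIM = 0.017


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def pgml_to_molecules(conc: float, molar_mass: float, volume: float = 1.0) -> float:
    """Convert a concentration in pg/mL to a molecule count per model volume.

    Parameters
    ----------
    conc : float
        Concentration in pg/mL.  1 pg/mL = 1e-3 pg/mm³.
    molar_mass : float
        Molar mass of the species in Da (g/mol).
    volume : float
        Model volume in mm³ (default 1).
    """
    if conc < 0:
        raise ParameterError(f"concentration must be >= 0, got {conc}")
    if molar_mass <= 0:
        raise ParameterError(f"molar mass must be > 0, got {molar_mass}")
    if volume <= 0:
        raise ParameterError(f"volume must be > 0, got {volume}")
    grams = conc * 1e-3 * volume * 1e-12  # pg/mL -> pg/mm³ -> pg -> g
    return grams / molar_mass * AVOGADRO


def annual_to_daily(rate: float) -> float:
    """Convert an annual loss fraction to the equivalent daily fraction.

    Uses geometric compounding, ``1 - (1 - rate)**(1/365)``, so that 365
    consecutive daily survival factors reproduce the annual fraction
    exactly (e.g. a 1 %/yr neuron loss halves the pool in 69 years).
    """
    if not 0.0 <= rate < 1.0:
        raise ParameterError(f"annual rate must be in [0, 1), got {rate}")
    return 1.0 - (1.0 - rate) ** (1.0 / DAYS_PER_YEAR)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GeometryConstants:
    """Capillary-array geometry of the 1 mm³ model volume.

    Capillaries run in parallel 1 mm segments; a single polygonal
    endothelial cell wraps the full circumference, so cells stack along
    the vessel axis at one per ``ec_width_um``.
    """

    model_volume_mm3: float = 1.0
    capillary_diameter_um: float = 8.0
    capillary_separation_um: float = 40.0
    segment_length_mm: float = 1.0
    ec_width_um: float = 20.0
    ec_circumference_um: float = 25.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ParameterError(f"{f.name} must be > 0")
        if self.capillary_separation_um <= self.capillary_diameter_um:
            raise ParameterError("capillary separation must exceed diameter")


DEFAULT_GEOMETRY = GeometryConstants()


def ec_per_capillary_length(diameter: float, ec_width: float, length: float) -> int:
    """Endothelial cells along ``length`` μm of capillary (one cell wraps
    the circumference, so the count is length / cell width)."""
    if diameter <= 0 or ec_width <= 0 or length <= 0:
        raise ParameterError("geometry arguments must be > 0")
    return _round_half_away(length / ec_width)


def capillaries_per_edge(edge: float, diameter: float, separation: float) -> int:
    """Capillaries fitting along one edge of the model volume at the given
    centre-to-centre pitch (diameter + separation)."""
    if edge <= 0 or diameter <= 0 or separation <= 0:
        raise ParameterError("geometry arguments must be > 0")
    return _round_half_away(edge / (diameter + separation))


def default_ec0(geometry: GeometryConstants = DEFAULT_GEOMETRY) -> int:
    """Endothelial cells in the model volume: a square capillary array,
    each vessel one segment long."""
    per_edge = capillaries_per_edge(
        1000.0 * geometry.segment_length_mm,
        geometry.capillary_diameter_um,
        geometry.capillary_separation_um,
    )
    per_capillary = ec_per_capillary_length(
        geometry.capillary_diameter_um,
        geometry.ec_width_um,
        1000.0 * geometry.segment_length_mm,
    )
    return per_edge * per_edge * per_capillary


# ---------------------------------------------------------------------------
# Hippocampal volume records
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class VolumeRecord:
    """MRI-derived hippocampal volume and annual loss for one cohort."""

    cohort: str
    baseline_volume: float  # mm³
    loss_rate: float  # mm³/year, negative = shrinkage

    def __post_init__(self) -> None:
        if self.baseline_volume <= 0:
            raise ParameterError("baseline_volume must be > 0")


#: MRI hippocampal volumes: healthy aging, mild cognitive impairment, AD.
HIPPOCAMPAL_VOLUMES: dict[str, VolumeRecord] = {
    "healthy": VolumeRecord("healthy", 2133.0, -17.3),
    "MCI": VolumeRecord("MCI", 1846.0, -47.5),
    "AD": VolumeRecord("AD", 1631.0, -72.0),
}


def percent_loss_per_year(record: VolumeRecord) -> float:
    """Signed annual volume change as a percentage of baseline."""
    if record.baseline_volume <= 0:
        raise ParameterError("baseline_volume must be > 0")
    return 100.0 * record.loss_rate / record.baseline_volume


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------

_APOE_K6 = {"E2": 0.4, "E3": 0.4, "E4": 0.12}

#: Calibrated defaults for the two free flow parameters (see module
#: docstring); values produced by engine.calibrate_v0 / calibrate_k_exit
#: against CALIBRATION_ANCHORS.
V0_DEFAULT = 0.2945627
K_EXIT_DEFAULT = 0.1304205


@dataclass(frozen=True, slots=True)
class ModelParams:
    """Every rate constant and initial condition of the model.

    Units: cell-loss rates ``d``, ``k1``, ``k2``, ``k10`` are fractions
    per *year*; all Aβ rates are per *day*; ``k3``/``k8`` are
    molecules/neuron/day, ``k5``/``k11`` molecules/microglia/day;
    ``C1_0``/``C4_0`` are pg/mL; ``v0`` is mm/day.
    """

    d: float = 0.01            # natural neuron loss, fraction/yr
    k1: float = 0.034          # additional Aβ-stimulated neuron loss, fraction/yr
    k2: float = 0.01           # endothelial senescence, fraction/yr
    k3: float = 16000.0        # Aβ40 generation, molecules/neuron/day
    k8: float = 3000.0         # Aβ42 generation, molecules/neuron/day
    k4: float = 1.5            # stimulated-generation multiplier
    k5: float = 1400.0         # microglial Aβ40 uptake, molecules/microglia/day
    k11: float = 200.0         # microglial Aβ42 uptake, molecules/microglia/day
    k6: float = 0.4            # LRP-1 transport, fraction/day (0.12 for ApoE4)
    k7: float = 0.004          # Aβ40 vessel-wall deposition, fraction/day
    k9a: float = 0.002         # Aβ42 vessel-wall deposition, fraction/day
    k7a: float = 0.001         # Aβ40 parenchymal deposition, fraction/day
    k9: float = 0.001          # Aβ42 parenchymal deposition, fraction/day
    k10: float | None = None   # LRP-1 loss, fraction/yr; None -> equal to k2
    k12: float = 7.3e-5        # microglial dystrophy conversion, fraction/day
    N0: float = 5275.0         # neurons per mm³
    M0: float = 4500.0         # microglia per mm³
    EC0: float = float(default_ec0())  # endothelial cells per mm³
    LRP0: float = 9.3e11       # LRP-1 receptors per mm³
    C1_0: float = 450.0        # initial ISF Aβ40, pg/mL
    C4_0: float = 70.0         # initial ISF Aβ42, pg/mL
    pvs_init_fraction: float = 0.10  # initial PVS Aβ as fraction of ISF Aβ
    v0: float = V0_DEFAULT     # baseline ISF bulk velocity, mm/day
    k_exit: float = K_EXIT_DEFAULT  # PVS glymphatic exit to cervical lymph, fraction/day
    theta_k1: float = 20.0     # neuron-loss trigger threshold, multiples of initial C1
    mw40: float = MW_AB40      # Aβ40 monomer mass, Da
    mw42: float = MW_AB42      # Aβ42 monomer mass, Da

    def __post_init__(self) -> None:
        if self.k10 is None:
            object.__setattr__(self, "k10", self.k2)
        self.validate()

    def validate(self) -> None:
        rate_fields = (
            "d k1 k2 k3 k8 k4 k5 k11 k6 k7 k9a k7a k9 k10 k12".split()
        )
        for name in rate_fields:
            if getattr(self, name) < 0:
                raise ParameterError(f"rate {name} must be >= 0")
        for name in ("N0", "M0", "EC0", "LRP0", "mw40", "mw42", "theta_k1"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("C1_0", "C4_0", "k_exit"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("d", "k1", "k2", "k10"):
            if getattr(self, name) >= 1.0:
                raise ParameterError(f"annual rate {name} must be < 1")
        if not 0.0 < self.pvs_init_fraction <= 1.0:
            raise ParameterError("pvs_init_fraction must be in (0, 1]")
        lo, hi = V0_BOUNDS
        if not lo <= self.v0 <= hi:
            raise ParameterError(
                f"v0={self.v0} outside the literature range [{lo}, {hi}] mm/day"
            )

    # -- convenience -------------------------------------------------------
    def with_overrides(self, **kwargs: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)

    def c1_init_molecules(self, volume: float = 1.0) -> float:
        """Initial parenchymal Aβ40 pool in molecules per model volume."""
        return pgml_to_molecules(self.C1_0, self.mw40, volume)

    def c4_init_molecules(self, volume: float = 1.0) -> float:
        """Initial parenchymal Aβ42 pool in molecules per model volume."""
        return pgml_to_molecules(self.C4_0, self.mw42, volume)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())


def default_params(apoe: str = "E3") -> ModelParams:
    """Validated parameter preset for the given ApoE allele.

    ApoE2 and ApoE3 share the normal LRP-1 transport rate; ApoE4 slows
    effective LRP-1-mediated clearance ~2.5-fold (k6 = 0.12/day).
    """
    allele = str(apoe).upper().removeprefix("APOE")
    if allele in {"2", "3", "4"}:
        allele = "E" + allele
    if allele not in _APOE_K6:
        raise ParameterError(
            f"unknown ApoE allele {apoe!r}; expected one of E2, E3, E4"
        )
    return ModelParams(k6=_APOE_K6[allele])


# ---------------------------------------------------------------------------
# TOML presets
# ---------------------------------------------------------------------------

def params_to_toml(params: ModelParams) -> str:
    """Serialize a parameter set as a flat TOML document (keys are the
    ModelParams field names)."""
    lines = ["# glymphsim parameter preset (flat keys = ModelParams fields)"]
    for name, value in params:
        lines.append(f"{name} = {value!r}")
    return "\n".join(lines) + "\n"


def params_from_mapping(data: Mapping[str, float]) -> ModelParams:
    """Build a validated ModelParams from a flat mapping (fail-closed:
    unknown keys are an error)."""
    known = {f.name for f in fields(ModelParams)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(f"unknown parameter key(s): {sorted(unknown)}")
    return ModelParams(**{k: float(v) for k, v in data.items()})


def params_from_toml(text: str) -> ModelParams:
    return params_from_mapping(tomllib.loads(text))


def load_preset(name: str) -> ModelParams:
    """Load a packaged TOML preset, e.g. ``"apoe3"`` or ``"apoe4"``."""
    ref = resources.files("glymphsim.presets").joinpath(f"{name}.toml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ParameterError(f"no packaged preset named {name!r}") from None
    return params_from_toml(text)
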