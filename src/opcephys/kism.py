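"""K⁺-selective microelectrode (K⁺-ISM) calibration and junction potentials.

A K⁺-ISM reports extracellular potassium through a log-linear (Nernstian)
voltage response, V = slope·log10([K⁺]) + intercept, with the theoretical
slope ln(10)·RT/F (59.2 mV/decade at 25 °C). Electrodes are calibrated
against known KCl standards and accepted when the fitted slope exceeds
50 mV/decade. Because the ISM also picks up the local field potential, a
co-located reference electrode is recorded and subtracted before the
voltage is inverted to a concentration.

The module also computes liquid junction potentials between pipette and
bath solutions with the Henderson equation, using a built-in table of
limiting equivalent conductivities. Whole-cell potentials in this package
are junction-corrected using this value (or the recorded offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import thermal_voltage_mv

__all__ = [
    "IonSpecies",
    "SolutionComposition",
    "KismCalibration",
    "MOBILITY_TABLE",
    "fit_calibration",
    "theoretical_nernst_slope",
    "voltage_to_concentration",
    "junction_potential",
    "standard_internal_solution",
    "hepes_acsf",
]

#: Fitted slope above which an electrode is considered Nernstian (mV/decade).
NERNSTIAN_SLOPE_MV = 50.0


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species in a solution.

    Parameters
    ----------
    name :
        Species label (for error messages and overrides).
    charge :
        Signed valence; must be nonzero.
    conductivity :
        Limiting equivalent conductivity λ⁰ in S·cm²·eq⁻¹ (25 °C scale).
        Mobility enters the Henderson equation as λ⁰/|z|.
    """

    name: str
    charge: int
    conductivity: float

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"{self.name}: ion charge must be nonzero")
        if self.conductivity <= 0:
            raise ValueError(f"{self.name}: conductivity must be positive")


# Limiting equivalent conductivities, S cm^2 eq^-1 at 25 C. Monatomic values
# are standard table entries; organic anions (gluconate, HEPES, nucleotides,
# BAPTA, Lucifer yellow) use the conventional junction-calculator values,
# expressed here as lambda = relative_mobility * |z| * lambda_K.
MOBILITY_TABLE: dict[str, IonSpecies] = {
    s.name: s
    for s in [
        IonSpecies("H", 1, 349.8),
        IonSpecies("K", 1, 73.5),
        IonSpecies("Na", 1, 50.1),
        IonSpecies("Li", 1, 38.7),
        IonSpecies("Cs", 1, 77.3),
        IonSpecies("NH4", 1, 73.6),
        IonSpecies("TEA", 1, 32.7),
        IonSpecies("Ca", 2, 59.5),
        IonSpecies("Mg", 2, 53.1),
        IonSpecies("Ba", 2, 63.6),
        IonSpecies("Cl", -1, 76.3),
        IonSpecies("Br", -1, 78.1),
        IonSpecies("F", -1, 55.4),
        IonSpecies("OH", -1, 198.0),
        IonSpecies("NO3", -1, 71.5),
        IonSpecies("HCO3", -1, 44.5),
        IonSpecies("H2PO4", -1, 36.0),
        IonSpecies("acetate", -1, 40.9),
        IonSpecies("gluconate", -1, 24.3),  # 0.33 relative to K+
        IonSpecies("HEPES", -1, 22.0),  # 0.30 relative to K+
        IonSpecies("MES", -1, 26.8),
        IonSpecies("SO4", -2, 80.0),
        IonSpecies("ATP", -2, 47.0),  # gluconate-like nucleotide mobility
        IonSpecies("GTP", -2, 47.0),
        IonSpecies("BAPTA", -4, 84.0),  # tetra-anion, slow organic chelator
        IonSpecies("LuciferYellow", -2, 45.0),
    ]
}


@dataclass
class SolutionComposition:
    """An electrolyte solution as a list of (species, concentration) pairs.

    ``ions`` maps a species name from :data:`MOBILITY_TABLE` (or from
    ``extra_species``) to its free-ion concentration in mM. Neutral
    components (glucose, free HEPES acid) are simply omitted.
    """

    name: str
    ions: dict[str, float]
    extra_species: dict[str, IonSpecies] = field(default_factory=dict)

    def species(self, label: str) -> IonSpecies:
        if label in self.extra_species:
            return self.extra_species[label]
        if label in MOBILITY_TABLE:
            return MOBILITY_TABLE[label]
        raise KeyError(
            f"no limiting conductivity tabulated for species {label!r}; "
            "provide it via extra_species"
        )

    def __post_init__(self) -> None:
        if not self.ions:
            raise ValueError(f"solution {self.name!r} has no ions")
        for label, conc in self.ions.items():
            self.species(label)  # raises on unknown species
            if conc < 0:
                raise ValueError(f"{self.name}: negative concentration for {label}")

    def net_charge(self) -> float:
        """Net charge concentration in mEq/L (0 for an electroneutral solution)."""
        return sum(self.species(s).charge * c for s, c in self.ions.items())

    def balanced(self, titrant: str) -> "SolutionComposition":
        """Return a copy with residual charge neutralized by ``titrant``.

        Models pH titration (e.g. KOH or NaOH added to the nominal recipe):
        the counter-ion concentration is adjusted so the solution is
        electroneutral. Raises if the titrant has the wrong sign.
        """
        q = self.net_charge()
        ions = dict(self.ions)
        if abs(q) > 1e-9:
            z = self.species(titrant).charge
            delta = -q / z
            if delta < 0:
                raise ValueError(
                    f"{self.name}: titrant {titrant} cannot neutralize charge {q:+.2f} mEq/L"
                )
            ions[titrant] = ions.get(titrant, 0.0) + delta
        return SolutionComposition(self.name, ions, dict(self.extra_species))


def standard_internal_solution() -> SolutionComposition:
    """The K-gluconate whole-cell pipette solution used for OPC recordings.

    Nominal recipe (mM): 130 K-gluconate, 4 NaCl, 0.5 CaCl2, 10 HEPES,
    10 BAPTA, 4 MgATP, 0.5 Na2GTP, 2 K-Lucifer yellow, pH 7.3 with KOH.

    Ionization conventions: HEPES is taken as 50% anionic near its pKa;
    BAPTA as the fully ionized tetra-anion; MgATP as free Mg²⁺ plus ATP²⁻;
    GTP as its di-anion. The K⁺ added by KOH titration is recovered by
    charge balance.
    """
    nominal = SolutionComposition(
        "K-gluconate internal",
        {
            "K": 130.0 + 2 * 2.0,  # K-gluconate + K2-Lucifer-yellow
            "gluconate": 130.0,
            "Na": 4.0 + 2 * 0.5,  # NaCl + Na2GTP
            "Cl": 4.0 + 2 * 0.5,  # NaCl + CaCl2
            "Ca": 0.5,
            "HEPES": 5.0,  # 10 mM total, ~50% anionic at pH 7.3
            "BAPTA": 10.0,
            "Mg": 4.0,
            "ATP": 4.0,
            "GTP": 0.5,
            "LuciferYellow": 2.0,
        },
    )
    return nominal.balanced("K")


def hepes_acsf() -> SolutionComposition:
    """HEPES-buffered aCSF bath (mM): 144 NaCl, 2.5 KCl, 10 HEPES,
    1 NaH2PO4, 2.5 CaCl2, 10 glucose, pH 7.35 with NaOH (Mg²⁺-free).

    Glucose is neutral and omitted; HEPES is 50% anionic; the NaOH
    titration is recovered by charge balance.
    """
    nominal = SolutionComposition(
        "HEPES-aCSF",
        {
            "Na": 144.0 + 1.0,  # NaCl + NaH2PO4
            "Cl": 144.0 + 2 * 2.5,  # NaCl + CaCl2
            "K": 2.5,
            "HEPES": 5.0,
            "H2PO4": 1.0,
            "Ca": 2.5,
        },
    )
    return nominal.balanced("Na")


@dataclass
class KismCalibration:
    """Log-linear electrode calibration V = slope·log10(c) + intercept.

    slope is in mV per decade of [K⁺], intercept in mV at 1 mM.
    ``is_nernstian`` applies the >50 mV/decade acceptance rule.
    """

    slope: float
    intercept: float
    concentrations_mm: np.ndarray
    voltages_mv: np.ndarray
    residual_sd: float

    @property
    def is_nernstian(self) -> bool:
        return self.slope > NERNSTIAN_SLOPE_MV

    def forward(self, concentration_mm):
        """Electrode voltage (mV) for a concentration (mM); the forward map
        inverted by :func:`voltage_to_concentration`."""
        c = np.asarray(concentration_mm, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        return self.slope * np.log10(c) + self.intercept


def fit_calibration(points) -> KismCalibration:
    """Least-squares log-linear fit to calibration points.

    Parameters
    ----------
    points :
        Sequence of (concentration mM, voltage mV) pairs; at least two
        distinct concentrations.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (concentration, voltage) pairs")
    c, v = pts[:, 0], pts[:, 1]
    if np.any(c <= 0):
        raise ValueError("calibration concentrations must be positive")
    logc = np.log10(c)
    if np.ptp(logc) == 0:
        raise ValueError("calibration requires at least two distinct concentrations")
    coeffs, residuals, *_ = np.polynomial.polynomial.polyfit(logc, v, 1, full=True)
    intercept, slope = coeffs
    fitted = intercept + slope * logc
    dof = max(len(c) - 2, 1)
    residual_sd = float(np.sqrt(np.sum((v - fitted) ** 2) / dof))
    return KismCalibration(float(slope), float(intercept), c, v, residual_sd)


def theoretical_nernst_slope(temperature_k: float) -> float:
    """Ideal electrode slope ln(10)·RT/F in mV per decade (59.16 at 298.15 K)."""
    return np.log(10.0) * thermal_voltage_mv(temperature_k)


def voltage_to_concentration(
    ism_trace_mv,
    reference_trace_mv,
    cal: KismCalibration,
    *,
    warn_non_nernstian: bool = True,
) -> np.ndarray:
    """Convert an ISM voltage trace to [K⁺]ₑ (mM).

    The reference (field-potential) trace is subtracted sample-by-sample to
    remove the common-mode signal, then the calibration is inverted:
    c(t) = 10^((V_ism − V_ref − intercept)/slope). Output is strictly
    positive by construction.
    """
    ism = np.asarray(ism_trace_mv, dtype=float)
    ref = np.asarray(reference_trace_mv, dtype=float)
    if ism.shape != ref.shape:
        raise ValueError("ISM and reference traces must be aligned and equal length")
    if abs(cal.slope) < 1.0:
        raise ValueError(f"calibration slope {cal.slope:.3g} mV/decade is too small to invert")
    if warn_non_nernstian and not cal.is_nernstian:
        import warnings

        warnings.warn(
            f"electrode slope {cal.slope:.1f} mV/decade is sub-Nernstian "
            f"(<= {NERNSTIAN_SLOPE_MV} mV); converted concentrations may be biased",
            stacklevel=2,
        )
    return 10.0 ** ((ism - ref - cal.intercept) / cal.slope)


def junction_potential(
    internal: SolutionComposition,
    external: SolutionComposition,
    temperature_k: float,
) -> float:
    """Henderson liquid junction potential, pipette relative to bath, in mV.

    Sign convention: a K-gluconate pipette against a NaCl-rich bath gives a
    negative value (fast K⁺ out-diffuses slow gluconate⁻, leaving the
    pipette side negative), matching the usual whole-cell correction.
    """
    rtf = thermal_voltage_mv(temperature_k)
    labels = sorted(set(internal.ions) | set(external.ions))
    num = den = 0.0
    sigma_p = sigma_s = 0.0
    for label in labels:
        sp = internal.species(label) if label in internal.ions else external.species(label)
        z = sp.charge
        u = sp.conductivity / abs(z)  # mobility scale
        c_p = internal.ions.get(label, 0.0)
        c_s = external.ions.get(label, 0.0)
        num += z * u * (c_s - c_p)
        den += z * z * u * (c_s - c_p)
        sigma_p += z * z * u * c_p
        sigma_s += z * z * u * c_s
    if sigma_p <= 0 or sigma_s <= 0:
        raise ValueError("both solutions must contain ions")
    if den == 0.0:
        return 0.0
    return float(-rtf * (num / den) * np.log(sigma_p / sigma_s))
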