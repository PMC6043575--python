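"""Domain types and synthetic generator for 1D proton NMR spectra.

The quantification arm of the package works on processed 1D spectra:
a chemical-shift axis in ppm, an intensity trace, and the spectrometer
frequency (400 MHz in all default work).  Real spectra enter through
:func:`read_spectrum`; synthetic ones with known ground truth come from
:func:`simulate_spectrum`, which renders each analyte's multiplets as
Lorentzian lines whose total area is proportional to
``(mass / molecular_weight) * n_protons`` — the proportionality that makes
internal-standard qNMR work.

Scalar coupling is rendered to first order: a doublet is two equal-area
lines split by ``J`` Hz, i.e. ``J / frequency_mhz`` ppm, about the multiplet
centre.  No roofing or second-order effects are modelled; at 400 MHz the
shift separations of the signals of interest are large against ``J``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, InvalidParameterError, RangeError

__all__ = [
    "Spectrum",
    "PeakComponent",
    "AnalyteSignature",
    "InternalReference",
    "SignatureLibrary",
    "SpectrumSimConfig",
    "lorentzian_profile",
    "build_signature_library",
    "simulate_spectrum",
    "read_spectrum",
    "write_spectrum",
    "signatures_to_yaml",
    "signatures_from_yaml",
    "DEFAULT_FWHM_HZ",
]

#: Default full width at half maximum of a solution-state line, Hz.
DEFAULT_FWHM_HZ = 1.0


@dataclass
class Spectrum:
    """A processed 1D spectrum on a uniform, strictly monotone ppm grid."""

    ppm: np.ndarray
    intensity: np.ndarray
    frequency_mhz: float = 400.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.size < 2:
            raise InvalidParameterError("ppm axis must be 1-D with >= 2 points")
        if self.ppm.shape != self.intensity.shape:
            raise InvalidParameterError("ppm and intensity must have equal length")
        diffs = np.diff(self.ppm)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise InvalidParameterError("ppm axis must be strictly monotone")
        if not self.frequency_mhz > 0:
            raise InvalidParameterError("frequency_mhz must be positive")

    def ascending(self) -> "Spectrum":
        """Return the spectrum with the ppm axis in ascending order."""
        if self.ppm[1] > self.ppm[0]:
            return self
        return Spectrum(self.ppm[::-1].copy(), self.intensity[::-1].copy(),
                        self.frequency_mhz, dict(self.meta))

    @property
    def ppm_range(self) -> tuple[float, float]:
        return float(self.ppm.min()), float(self.ppm.max())


@dataclass(frozen=True)
class PeakComponent:
    """One multiplet of an analyte: a singlet or a first-order doublet."""

    center_ppm: float
    multiplicity: str  # "singlet" | "doublet"
    j_hz: float
    n_protons: int
    fwhm_hz: float = DEFAULT_FWHM_HZ

    def __post_init__(self) -> None:
        if self.multiplicity not in ("singlet", "doublet"):
            raise InvalidParameterError(
                f"multiplicity must be 'singlet' or 'doublet', got {self.multiplicity!r}")
        if self.n_protons < 1:
            raise InvalidParameterError("n_protons must be >= 1")
        if not self.fwhm_hz > 0:
            raise InvalidParameterError("fwhm_hz must be positive")
        if self.j_hz < 0:
            raise InvalidParameterError("j_hz must be >= 0")
        if self.multiplicity == "doublet" and not self.j_hz > 0:
            raise InvalidParameterError("a doublet requires j_hz > 0")

    def line_positions(self, frequency_mhz: float) -> list[tuple[float, float]]:
        """(ppm, area-fraction) for each Lorentzian line of the multiplet."""
        if self.multiplicity == "singlet":
            return [(self.center_ppm, 1.0)]
        half = 0.5 * self.j_hz / frequency_mhz
        return [(self.center_ppm - half, 0.5), (self.center_ppm + half, 0.5)]


@dataclass(frozen=True)
class AnalyteSignature:
    """An analyte's multiplets plus the window used for quantification.

    ``quant_n_protons`` is the number of protons resonating inside
    ``quant_window``; for both hydroxycitric acid and its lactone a single
    CH proton of one doublet is integrated.
    """

    name: str
    mw: float
    peaks: tuple[PeakComponent, ...]
    quant_window: tuple[float, float]
    quant_n_protons: int

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise InvalidParameterError("molecular weight must be positive")
        lo, hi = self.quant_window
        if not lo < hi:
            raise InvalidParameterError("quant_window must satisfy lo < hi")
        if self.quant_n_protons < 1:
            raise InvalidParameterError("quant_n_protons must be >= 1")

    @property
    def total_protons(self) -> int:
        return sum(p.n_protons for p in self.peaks)


@dataclass(frozen=True)
class InternalReference:
    """The internal standard added at known mass and purity (maleic acid)."""

    name: str = "maleic acid"
    mw: float = 116.07
    purity: float = 0.9994
    mass_mg: float = 1.0
    quant_window: tuple[float, float] = (6.33, 6.41)
    n_protons: int = 2
    center_ppm: float = 6.37
    fwhm_hz: float = DEFAULT_FWHM_HZ

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise InvalidParameterError("purity must be in (0, 1]")
        if not self.mass_mg > 0:
            raise InvalidParameterError("mass_mg must be positive")
        if not self.mw > 0:
            raise InvalidParameterError("mw must be positive")

    def as_signature(self) -> AnalyteSignature:
        return AnalyteSignature(
            name=self.name,
            mw=self.mw,
            peaks=(PeakComponent(self.center_ppm, "singlet", 0.0,
                                 self.n_protons, self.fwhm_hz),),
            quant_window=self.quant_window,
            quant_n_protons=self.n_protons,
        )


@dataclass
class SignatureLibrary:
    """The analyte signatures plus the internal reference, keyed by name."""

    analytes: dict[str, AnalyteSignature]
    internal_reference: InternalReference

    def __getitem__(self, name: str) -> AnalyteSignature:
        if name == self.internal_reference.name:
            return self.internal_reference.as_signature()
        return self.analytes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.analytes or name == self.internal_reference.name

    def names(self) -> list[str]:
        return [*self.analytes, self.internal_reference.name]


def build_signature_library(fwhm_hz: float = DEFAULT_FWHM_HZ) -> SignatureLibrary:
    """Signatures of the compounds seen in Garcinia extract proton spectra.

    Hydroxycitric acid (HCA): the CH2 protons give two doublets at
    delta 3.07 and 3.16 (J = 16.6 Hz) and the CHOH proton a singlet at 4.45;
    quantified on the 3.16-centred doublet (1H).  The lactone: doublets at
    2.92 and 3.29 (J = 18.0 Hz) and a singlet at 5.00; quantified at 3.29
    (1H).  Maleic acid (internal standard): 2H singlet at 6.37.  TSP: 9H
    reference singlet at 0.0.  The garcinol marker signature (benzophenone
    aromatics at 6.7/7.0/7.2 plus olefinic methyls 1.5-1.7) flags methanol
    extracts of genuine fruit-rind material.
    """

    def d(center, j, n=1):
        return PeakComponent(center, "doublet", j, n, fwhm_hz)

    def s(center, n=1):
        return PeakComponent(center, "singlet", 0.0, n, fwhm_hz)

    hca = AnalyteSignature(
        name="hca",
        mw=208.12,
        peaks=(d(3.07, 16.6), d(3.16, 16.6), s(4.45)),
        quant_window=(3.12, 3.20),
        quant_n_protons=1,
    )
    lactone = AnalyteSignature(
        name="hca_lactone",
        mw=190.11,
        peaks=(d(2.92, 18.0), d(3.29, 18.0), s(5.00)),
        quant_window=(3.25, 3.33),
        quant_n_protons=1,
    )
    # TSP-d4 sodium salt; the trimethylsilyl 9H singlet defines delta 0.0.
    tsp = AnalyteSignature(
        name="tsp",
        mw=172.26,
        peaks=(s(0.0, 9),),
        quant_window=(-0.04, 0.04),
        quant_n_protons=9,
    )
    garcinol = AnalyteSignature(
        name="garcinol",
        mw=602.8,
        peaks=(s(6.7), s(7.0), s(7.2),
               s(1.52, 3), s(1.58, 3), s(1.64, 3), s(1.70, 3)),
        quant_window=(6.95, 7.05),
        quant_n_protons=1,
    )
    return SignatureLibrary(
        analytes={a.name: a for a in (hca, lactone, tsp, garcinol)},
        internal_reference=InternalReference(fwhm_hz=fwhm_hz),
    )


def lorentzian_profile(center_ppm: float, fwhm_ppm: float, area: float,
                       ppm_axis: np.ndarray) -> np.ndarray:
    """Lorentzian line evaluated on a ppm grid.

    ``L(x) = (area / pi) * (w/2) / ((x - c)^2 + (w/2)^2)`` with ``w`` the
    full width at half maximum; the peak maximum is ``2 * area / (pi * w)``
    and the profile integrates to ``area`` over the whole real line.
    """
    if not fwhm_ppm > 0:
        raise InvalidParameterError("fwhm_ppm must be positive")
    x = np.asarray(ppm_axis, dtype=float)
    hw = 0.5 * fwhm_ppm
    return (area / np.pi) * hw / ((x - center_ppm) ** 2 + hw ** 2)


# Broad stand-in humps for the sugar-dominated 3.2-4.2 ppm region of crude
# fruit-rind water extracts: three 40-Hz Lorentzians, not assigned to any
# specific sugar.
SUGAR_HUMPS_PPM = (3.4, 3.7, 4.0)
SUGAR_HUMP_FWHM_HZ = 40.0


@dataclass
class SpectrumSimConfig:
    """Configuration of one simulated sample spectrum.

    ``concentrations`` maps analyte names (signature-library keys) to the
    mass of that compound, in mg, present in the measured aliquot.  The
    internal reference is always rendered at its own ``mass_mg`` unless a
    mass is given for it explicitly.
    """

    concentrations: Mapping[str, float] = field(default_factory=dict)
    aliquot_mass_mg: float = 10.0
    noise_sd: float = 0.0
    baseline: Sequence[float] = (0.0,)
    sugar_background: bool = True
    sugar_area: float = 0.05
    seed: int | None = None
    n_points: int = 2 ** 16
    ppm_range: tuple[float, float] = (-0.5, 10.5)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.concentrations.values()):
            raise ConfigurationError("concentrations must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_points < 2:
            raise ConfigurationError("n_points must be >= 2")
        if not self.aliquot_mass_mg > 0:
            raise ConfigurationError("aliquot_mass_mg must be positive")
        lo, hi = self.ppm_range
        if not lo < hi:
            raise ConfigurationError("ppm_range must satisfy lo < hi")


def simulate_spectrum(config: SpectrumSimConfig,
                      signatures: SignatureLibrary | None = None) -> Spectrum:
    """Render a synthetic 400-MHz proton spectrum with known ground truth.

    Each analyte contributes a total area of ``(mass_mg / mw) * total_protons``
    — areas are in arbitrary units proportional to moles of contributing
    protons; the absolute unit cancels in internal-standard quantification.
    The area is distributed over the analyte's multiplets by proton count.
    Ground-truth per-analyte areas, masses and the seed are recorded in
    ``meta`` for downstream recovery tests.
    """
    if signatures is None:
        signatures = build_signature_library()
    frequency_mhz = 400.0
    lo, hi = config.ppm_range
    ppm = np.linspace(lo, hi, config.n_points)
    intensity = np.polynomial.polynomial.polyval(ppm, np.asarray(config.baseline, float))
    intensity = np.broadcast_to(intensity, ppm.shape).astype(float).copy()

    masses = dict(config.concentrations)
    ir = signatures.internal_reference
    masses.setdefault(ir.name, ir.mass_mg)

    true_areas: dict[str, float] = {}
    for name, mass_mg in masses.items():
        if name not in signatures:
            raise ConfigurationError(f"unknown analyte in config: {name!r}")
        sig = signatures[name]
        total_area = (mass_mg / sig.mw) * sig.total_protons
        true_areas[name] = total_area
        if mass_mg == 0:
            continue
        per_proton = mass_mg / sig.mw  # area per contributing proton
        for peak in sig.peaks:
            peak_area = per_proton * peak.n_protons
            fwhm_ppm = peak.fwhm_hz / frequency_mhz
            for pos, frac in peak.line_positions(frequency_mhz):
                intensity += lorentzian_profile(pos, fwhm_ppm, peak_area * frac, ppm)

    if config.sugar_background and config.sugar_area > 0:
        hump_area = config.sugar_area / len(SUGAR_HUMPS_PPM)
        for center in SUGAR_HUMPS_PPM:
            intensity += lorentzian_profile(
                center, SUGAR_HUMP_FWHM_HZ / frequency_mhz, hump_area, ppm)

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=ppm.shape)

    meta = {
        "sample_id": "simulated",
        "aliquot_mass_mg": config.aliquot_mass_mg,
        "true_masses_mg": masses,
        "true_areas": true_areas,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return Spectrum(ppm, intensity, frequency_mhz, meta)


# ---------------------------------------------------------------------------
# Spectrum text I/O: two columns (ppm, intensity) after one header line with
# key=value pairs; tolerant of ascending or descending axes.

def write_spectrum(path, spectrum: Spectrum) -> None:
    simple_meta = {k: v for k, v in spectrum.meta.items()
                   if isinstance(v, (str, int, float))}
    header_items = [f"frequency_mhz={spectrum.frequency_mhz}"]
    header_items += [f"{k}={v}" for k, v in simple_meta.items()]
    with open(path, "w") as fh:
        fh.write("# " + " ".join(header_items) + "\n")
        for p, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{p:.8f}\t{y:.10g}\n")


def read_spectrum(path) -> Spectrum:
    """Read the two-column dialect; canonicalizes the axis to ascending."""
    meta: dict = {}
    frequency_mhz = 400.0
    ppm: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for item in line.lstrip("#").split():
                    if "=" not in item:
                        continue
                    key, _, val = item.partition("=")
                    try:
                        parsed: object = float(val)
                    except ValueError:
                        parsed = val
                    if key == "frequency_mhz":
                        frequency_mhz = float(val)
                    else:
                        meta[key] = parsed
                continue
            cols = line.replace(",", " ").split()
            if len(cols) < 2:
                raise RangeError(f"malformed spectrum line: {line!r}")
            ppm.append(float(cols[0]))
            intensity.append(float(cols[1]))
    return Spectrum(np.array(ppm), np.array(intensity),
                    frequency_mhz, meta).ascending()


# ---------------------------------------------------------------------------
# Signature library import/export so users can register their own analytes.

def signatures_to_yaml(library: SignatureLibrary, path) -> None:
    doc = {
        "internal_reference": {
            "name": library.internal_reference.name,
            "mw": library.internal_reference.mw,
            "purity": library.internal_reference.purity,
            "mass_mg": library.internal_reference.mass_mg,
            "quant_window": list(library.internal_reference.quant_window),
            "n_protons": library.internal_reference.n_protons,
            "center_ppm": library.internal_reference.center_ppm,
            "fwhm_hz": library.internal_reference.fwhm_hz,
        },
        "analytes": {
            name: {
                "mw": sig.mw,
                "quant_window": list(sig.quant_window),
                "quant_n_protons": sig.quant_n_protons,
                "peaks": [
                    {"center_ppm": p.center_ppm, "multiplicity": p.multiplicity,
                     "j_hz": p.j_hz, "n_protons": p.n_protons, "fwhm_hz": p.fwhm_hz}
                    for p in sig.peaks
                ],
            }
            for name, sig in library.analytes.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def signatures_from_yaml(path) -> SignatureLibrary:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    ir_doc = doc["internal_reference"]
    ir = InternalReference(
        name=ir_doc["name"], mw=ir_doc["mw"], purity=ir_doc["purity"],
        mass_mg=ir_doc["mass_mg"], quant_window=tuple(ir_doc["quant_window"]),
        n_protons=ir_doc["n_protons"], center_ppm=ir_doc["center_ppm"],
        fwhm_hz=ir_doc["fwhm_hz"])
    analytes = {}
    for name, sdoc in doc["analytes"].items():
        peaks = tuple(PeakComponent(p["center_ppm"], p["multiplicity"],
                                    p["j_hz"], p["n_protons"], p["fwhm_hz"])
                      for p in sdoc["peaks"])
        analytes[name] = AnalyteSignature(
            name=name, mw=sdoc["mw"], peaks=peaks,
            quant_window=tuple(sdoc["quant_window"]),
            quant_n_protons=sdoc["quant_n_protons"])
    return SignatureLibrary(analytes=analytes, internal_reference=ir)
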