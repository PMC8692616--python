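"""Synthetic multimodal dataset generator with known ground truth.

No public hair dataset exists for this kind of multi-technique study, so the
pipeline is exercised on simulated data: latent compositional variables per
sample pool (alpha-helix keratin fraction, lipid content, bound water,
thermal resistance, fiber cross-section) drive parametric line-shape
templates for six modalities plus tensile-property replicates.  The latent ->
spectrum maps are sums of Voigt/Gaussian bands, Abragam/exponential decays
and skewed-Gaussian mass-loss events — line-shape realism only, no spin
dynamics or pyrolysis kinetics.

Species structure: alpha-helix fraction, lipid content and cross-section
area have species-level means (cat/cow/human/pig) plus donor- and pool-level
jitter; bound water and thermal resistance vary only at the donor level.
Breaking force is driven by cross-section area and the species-structured
latents, so its planted signal lives in exactly the spectral regions those
latents control (20 bin descriptors under the default descriptor config).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import voigt_profile as _voigt
from scipy.stats import norm

from .spectra import Spectrum, read_spectra_csv, write_spectra_csv

SPECIES = ("cat", "cow", "human", "pig")

#: Default species mix: 9 cat / 12 cow / 21 human / 21 pig pools.
DEFAULT_SPECIES_MIX = (9 / 63, 12 / 63, 21 / 63, 21 / 63)

#: Species-level latent means; cross-section areas in mm^2.
SPECIES_MEANS = {
    "cat": {"alpha_helix_fraction": 0.45, "lipid_content": 0.70,
            "cross_section_area": 0.0060},
    "cow": {"alpha_helix_fraction": 0.60, "lipid_content": 0.35,
            "cross_section_area": 0.0100},
    "human": {"alpha_helix_fraction": 0.72, "lipid_content": 0.45,
              "cross_section_area": 0.0075},
    "pig": {"alpha_helix_fraction": 0.88, "lipid_content": 0.10,
            "cross_section_area": 0.0130},
}

#: Donor-level / pool-level jitter SDs for the fractional latents.
LATENT_JITTER = {
    "alpha_helix_fraction": (0.10, 0.02),
    "lipid_content": (0.10, 0.03),
    "bound_water": (0.10, 0.04),
    "thermal_resistance": (0.10, 0.04),
}

#: Replicates per modality: TD-NMR decays 5x per pool, >=3 FT-IR spectra,
#: tensile tests 10 fibers per pool.
REPLICATES = {"h1_wideline": 2, "h1_mas": 2, "c13_cpmas": 2,
              "tdnmr": 5, "ftir": 3, "dtg": 1}
N_PROPERTY_REPLICATES = 10

PROPERTY_COLUMNS = ("breaking_force_N", "elastic_modulus_GPa",
                    "extension_pct", "yield_strength_MPa")

# -- measurement axes ------------------------------------------------------
WL_AXIS = np.arange(-120.0, 120.0 + 0.125, 0.25)        # ppm
MAS_AXIS = np.arange(-10.0, 16.0 + 0.01, 0.02)          # ppm
CPMAS_AXIS = np.arange(0.0, 200.0 + 0.1, 0.2)           # ppm
#: Solid-echo decays use a quasi-logarithmic acquisition grid up to 1.0 ms.
TD_AXIS = np.concatenate([[0.0], np.geomspace(1e-6, 1e-3, 250)])  # s
FTIR_AXIS = np.arange(650.0, 4000.0 + 1.0, 2.0)         # cm-1
DTG_AXIS = np.arange(40.0, 500.0 + 0.25, 0.5)           # degC

#: Relative point-noise level: peak template amplitude / noise SD.
#: Scan-averaged NMR/FT-IR/DTG profiles resolve their peaks at SNR of
#: several hundred; the instrument-level figure for a single solid-echo
#: decay is nearer 200 (used where single acquisitions are emulated).
DEFAULT_SNR = 500.0
#: SD of the multiplicative per-replicate intensity drift.
REPLICATE_SCALE_SD = 0.02


@dataclass(frozen=True)
class LatentComposition:
    """Ground-truth compositional state of one hair sample pool."""

    sample_id: str
    species: str
    donor: str
    alpha_helix_fraction: float
    lipid_content: float
    bound_water: float
    thermal_resistance: float
    cross_section_area: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        for name in ("alpha_helix_fraction", "lipid_content", "bound_water",
                     "thermal_resistance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cross_section_area <= 0:
            raise ValueError("cross_section_area must be positive")


@dataclass(frozen=True)
class InformativeRegion:
    """An axis region whose intensity responds to one latent variable."""

    modality: str
    lo: float
    hi: float
    latent: str
    derivatives: tuple[int, ...] = (0, 2)


#: Informative spectral features: distinct compositional bands whose
#: amounts equal their family latent (lipid content or alpha-helix
#: fraction) plus an independent per-sample deviation, with the tensile
#: stress depending on every band amount individually.  Each band is
#: centered in its own descriptor bin, so the bin descriptors are the
#: cleanest reads of the planted signal.  mas lipid positions sit in the
#: 0.8-2.3 ppm lipid window, alpha positions across the H-alpha band, the
#: aliphatic region and the 176 ppm carbonyl region.
FEATURE_BINS = (
    # lipid sub-bands across the 0.8-2.3 ppm MAS window
    ("h1_mas", "lipid_content", 0.85),
    ("h1_mas", "lipid_content", 1.15),
    ("h1_mas", "lipid_content", 1.45),
    ("h1_mas", "lipid_content", 1.75),
    ("h1_mas", "lipid_content", 2.05),
    ("h1_mas", "lipid_content", 2.35),
    # alpha-helix sub-bands across the 2.8-7.0 ppm H-alpha region
    ("h1_mas", "alpha_helix_fraction", 2.95),
    ("h1_mas", "alpha_helix_fraction", 3.25),
    ("h1_mas", "alpha_helix_fraction", 3.55),
    ("h1_mas", "alpha_helix_fraction", 3.85),
    ("h1_mas", "alpha_helix_fraction", 4.15),
    ("h1_mas", "alpha_helix_fraction", 4.45),
    ("h1_mas", "alpha_helix_fraction", 4.75),
    ("h1_mas", "alpha_helix_fraction", 5.05),
    ("h1_mas", "alpha_helix_fraction", 5.35),
    ("h1_mas", "alpha_helix_fraction", 5.65),
    ("h1_mas", "alpha_helix_fraction", 5.95),
    ("h1_mas", "alpha_helix_fraction", 6.25),
    ("h1_mas", "alpha_helix_fraction", 6.55),
    ("h1_mas", "alpha_helix_fraction", 6.85),
)

#: (sigma, height) per modality.  Each band sits at the center of its
#: descriptor bin and is narrow enough that even after Savitzky-Golay
#: smoothing its entire second-derivative pattern stays inside that bin —
#: where it averages to ~zero, because the SG second-derivative kernel's
#: coefficients sum to zero.  The nonderivative bin is therefore the only
#: clean read of each band (no derivative shadows, no neighbor bleed).
#: Band heights are small: the bin mean still reads them at high SNR
#: (point noise shrinks with points-per-bin and replicates), while their
#: share of profile-space variance stays below the donor nuisance, so PCA
#: scores do not act as aggregated band reads.
FEATURE_SHAPES = {"h1_mas": (0.02, 0.15)}

#: SD of one band's deviation around its family latent.  Deliberately
#: large relative to the between-species latent differences: no single
#: band (and no latent-scaled template band — those carry deviations too)
#: is a clean read of a latent, so recovering the composition, and hence
#: the properties, requires averaging over many informative bins.
FEATURE_DEV_SD = 0.22

#: Number of per-sample band deviations drawn: the 20 feature bands plus
#: the latent-scaled carbonyl and aliphatic template bands.
N_BAND_DEVIATIONS = len(FEATURE_BINS) + 2

#: Axis regions carrying planted signal, tagged by their driving latent.
#: Feature-band regions are declared for the nonderivative profiles only:
#: with the Savitzky-Golay window matched to the band widths, second
#: differentiation attenuates the bands, so the nonderivative bin is the
#: read of record for each feature.
INFORMATIVE_REGIONS = tuple(
    [InformativeRegion(mod, center - 0.1 * (1 if mod == "h1_mas" else 5),
                       center + 0.1 * (1 if mod == "h1_mas" else 5), fam,
                       derivatives=(0,))
     for mod, fam, center in FEATURE_BINS]
    + [
        # narrow mobile-proton peak of the wide-line spectrum
        InformativeRegion("h1_wideline", -3.0, 3.0, "bound_water"),
        # TD-NMR mobile tail
        InformativeRegion("tdnmr", 5e-5, 1e-3, "bound_water"),
        # DTG cuticle decomposition events
        InformativeRegion("dtg", 258.0, 278.0, "thermal_resistance"),
        InformativeRegion("dtg", 342.0, 384.0, "thermal_resistance"),
    ])

#: Property models: intercept + weights on the fractional latents.
#: Breaking force is a tensile stress (MPa) multiplied by the cross-section
#: area (mm^2), giving newtons.  For latents expressed as band features
#: (alpha-helix, lipid) the stress uses the mean band amount of the family
#: plus, with weight ``band_contrast`` (MPa per contrast unit), the
#: FEATURE_CONTRAST combination of the individual band amounts.
DEFAULT_PROPERTY_WEIGHTS = {
    "breaking_force_N": {"intercept": 90.0, "alpha_helix_fraction": 110.0,
                         "lipid_content": 60.0, "area_scaled": 1.0},
    "elastic_modulus_GPa": {"intercept": 1.5, "alpha_helix_fraction": 2.0,
                            "thermal_resistance": 3.0},
    "extension_pct": {"intercept": 25.0, "bound_water": 60.0},
    "yield_strength_MPa": {"intercept": 55.0, "alpha_helix_fraction": 65.0,
                           "thermal_resistance": 120.0},
}

DEFAULT_NOISE_SD = {"breaking_force_N": 0.12, "elastic_modulus_GPa": 0.9,
                    "extension_pct": 12.0, "yield_strength_MPa": 35.0}


@dataclass(frozen=True)
class GroundTruth:
    """Planted links between latents, descriptors and properties."""

    informative_descriptor_ids: frozenset
    property_weights: dict
    noise_sd: dict
    regions: tuple = INFORMATIVE_REGIONS

    def __post_init__(self) -> None:
        if not self.informative_descriptor_ids:
            raise ValueError("informative descriptor set must be non-empty")
        for prop, weights in self.property_weights.items():
            if not all(math.isfinite(v) for v in weights.values()):
                raise ValueError(f"non-finite weight for {prop}")

    def latents_for_property(self, prop: str) -> set[str]:
        return {k for k, v in self.property_weights[prop].items()
                if k in LATENT_JITTER and v != 0.0}

    def regions_for_property(self, prop: str) -> tuple[InformativeRegion, ...]:
        wanted = self.latents_for_property(prop)
        return tuple(r for r in self.regions if r.latent in wanted)


@dataclass
class SyntheticDataset:
    latents: list[LatentComposition]
    spectra: list[Spectrum]
    properties: pd.DataFrame
    truth: GroundTruth
    seed: int

    def property_means(self) -> pd.DataFrame:
        """Per-sample replicate means, one row per pool (modeling target)."""
        return (self.properties.groupby("sample_id", sort=True)
                [list(PROPERTY_COLUMNS)].mean())


# ---------------------------------------------------------------------------
# latent sampling
# ---------------------------------------------------------------------------

def _species_counts(n_samples: int, mix) -> dict[str, int]:
    """Largest-remainder apportionment of pools to species."""
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (4,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("species_mix must be 4 proportions summing to 1")
    raw = mix * n_samples
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n_samples - counts.sum()]:
        counts[i] += 1
    return dict(zip(SPECIES, counts.tolist()))


def sample_latents(n_samples: int = 63, species_mix=DEFAULT_SPECIES_MIX,
                   seed: int = 0) -> list[LatentComposition]:
    """Draw species/donor-structured latent compositions for sample pools.

    Donors number roughly half the pools of each species (each donor
    contributes ~2 pools collected on different days); donor effects and
    pool-level jitter are Gaussian on the latent scale, clipped to [0.02,
    0.98].  One shared donor factor drives both the alpha-helix fraction
    and the fiber cross-section: donors growing thicker fibers also grow
    more cortex keratin, so within-species thickness (and with it breaking
    force) is predictable from composition.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 sample pools")
    rng = np.random.default_rng(seed)
    counts = _species_counts(n_samples, species_mix)
    latents = []
    idx = 0
    for species in SPECIES:
        n_sp = counts[species]
        if n_sp == 0:
            continue
        n_donors = max(1, round(n_sp / 2))
        donor_fx = {
            name: rng.normal(0.0, LATENT_JITTER[name][0], size=n_donors)
            for name in LATENT_JITTER
        }
        shared = rng.normal(0.0, 1.0, size=n_donors)
        donor_fx["alpha_helix_fraction"] =             LATENT_JITTER["alpha_helix_fraction"][0] * shared
        donor_area = 0.09 * shared
        donor_of = rng.integers(0, n_donors, size=n_sp)
        for j in range(n_sp):
            d = int(donor_of[j])
            values = {}
            for name, (_, pool_sd) in LATENT_JITTER.items():
                mean = SPECIES_MEANS[species].get(name, 0.5)
                v = mean + donor_fx[name][d] + rng.normal(0.0, pool_sd)
                values[name] = float(np.clip(v, 0.02, 0.98))
            area = (SPECIES_MEANS[species]["cross_section_area"]
                    * math.exp(donor_area[d] + rng.normal(0.0, 0.02)))
            idx += 1
            latents.append(LatentComposition(
                sample_id=f"S{idx:03d}", species=species,
                donor=f"{species}_d{d + 1}",
                cross_section_area=area, **values))
    return latents


# ---------------------------------------------------------------------------
# spectrum templates
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


#: SD (ppm) of the per-sample chemical-shift jitter of each feature band.
#: Within one descriptor bin the bin mean is shift-invariant, but the
#: sampled band shape — especially after second differentiation — is not,
#: so profile-space methods cannot aggregate the bands coherently.  Real
#: spectra show comparable referencing/susceptibility shifts (the reason
#: axes are spline-aligned during pre-treatment).
FEATURE_SHIFT_SD = 0.03


def feature_deviations(sample_id: str, seed: int) -> np.ndarray:
    """Per-sample band-amount deviations, one per feature band.

    Derived deterministically from (seed, sample_id) so the spectrum
    renderer and the property renderer see the same compositional state.
    """
    tag = zlib.crc32(sample_id.encode())
    rng = np.random.default_rng(np.random.SeedSequence([seed, tag, 0xFEA7]))
    return rng.normal(0.0, FEATURE_DEV_SD, size=N_BAND_DEVIATIONS)


def feature_shifts(sample_id: str, seed: int) -> np.ndarray:
    """Per-sample chemical-shift jitter of the feature bands (ppm)."""
    tag = zlib.crc32(sample_id.encode())
    rng = np.random.default_rng(np.random.SeedSequence([seed, tag, 0x5F1F]))
    return np.clip(rng.normal(0.0, FEATURE_SHIFT_SD, size=len(FEATURE_BINS)),
                   -0.06, 0.06)


def band_amounts(latent: LatentComposition,
                 deviations: np.ndarray | None = None) -> np.ndarray:
    """Band amounts per feature: family latent + deviation, floored at 0.02
    (a band cannot have negative area)."""
    if deviations is None:
        deviations = np.zeros(N_BAND_DEVIATIONS)
    amounts = np.empty(len(FEATURE_BINS))
    for j, (_, family, _) in enumerate(FEATURE_BINS):
        amounts[j] = max(getattr(latent, family) + deviations[j], 0.02)
    return amounts


def _feature_peaks(modality: str, x: np.ndarray, amounts: np.ndarray,
                   shifts: np.ndarray | None = None) -> np.ndarray:
    sigma, height = FEATURE_SHAPES[modality]
    if shifts is None:
        shifts = np.zeros(len(FEATURE_BINS))
    y = np.zeros_like(x)
    for j, (mod, _, center) in enumerate(FEATURE_BINS):
        if mod == modality:
            y += height * amounts[j] * _gauss(x, center + shifts[j], sigma)
    return y


def _skew_event(x: np.ndarray, center: float, sigma: float,
                skew: float) -> np.ndarray:
    """Skewed-Gaussian mass-loss event, peak-normalized to ~1."""
    z = (x - center) / sigma
    shape = np.exp(-0.5 * z * z) * norm.cdf(skew * z) * 2.0
    return shape / shape.max()


def wideline_template(latent: LatentComposition) -> np.ndarray:
    """Broad + intermediate + narrow Voigt mixture (unit total area).

    The narrow mobile-proton share grows with bound water.
    """
    bw = latent.bound_water
    p_narrow = 0.06 + 0.10 * bw
    p_mid = 0.22
    p_broad = 1.0 - p_mid - p_narrow
    x = WL_AXIS
    return (p_broad * _voigt(x - 0.0, 22.0, 0.0)
            + p_mid * _voigt(x - 0.4, 7.0, 0.0)
            + p_narrow * _voigt(x - 0.05, 0.7, 0.5))


def mas_template(latent: LatentComposition,
                 deviations: np.ndarray | None = None,
                 shifts: np.ndarray | None = None) -> np.ndarray:
    """Isotropic 1H profile: H-alpha envelope, rigid base, narrow lipid
    bands across the 0.8-2.3 ppm window and H-alpha sub-bands, plus fixed
    distractor bands."""
    x = MAS_AXIS
    amounts = band_amounts(latent, deviations)
    y = (0.45 * _gauss(x, 4.3, 1.3)           # H-alpha envelope
         + 0.30 * _gauss(x, 4.0, 5.0)         # rigid anisotropic base
         + 0.18 * _gauss(x, 3.0, 9.0)         # very broad rigid background
         + _feature_peaks("h1_mas", x, amounts, shifts)
         + 0.06 * _gauss(x, 8.1, 0.60)        # fixed distractor bands
         + 0.04 * _gauss(x, -2.5, 0.80))
    return y


def cpmas_template(latent: LatentComposition,
                   deviations: np.ndarray | None = None) -> np.ndarray:
    if deviations is None:
        deviations = np.zeros(N_BAND_DEVIATIONS)
    # broad envelope bands overlap many constituents, so their link to the
    # latents is twice as noisy as the resolved feature bands'
    al = max(latent.alpha_helix_fraction + 2.0 * deviations[-2], 0.02)
    x = CPMAS_AXIS
    return (0.15 * _gauss(x, 100.0, 85.0)     # very broad rigid background
            + 0.50 * _gauss(x, 17.0, 4.0)     # side-chain aliphatics
            + 0.52 * _gauss(x, 30.0, 5.0)
            + 0.45 * _gauss(x, 54.0, 4.0)     # C-alpha methine
            + 0.22 * _gauss(x, 130.0, 8.0)    # aromatics
            + 0.30 * _gauss(x, 171.5, 4.0)    # carbonyl envelope
            + (0.12 + 0.15 * al) * _gauss(x, 176.0, 1.2))


def td_components(latent: LatentComposition):
    """(proportions, relaxation times [s], abragam b [rad/s]) of the decay."""
    bw = latent.bound_water
    props = np.array([0.80 - 0.14 * bw, 0.12, 0.08 + 0.14 * bw])
    times = np.array([11e-6 * (1.0 + 0.10 * (bw - 0.5)),
                      60e-6 * (1.0 + 0.40 * (bw - 0.5)),
                      300e-6 * (1.0 + 0.50 * (bw - 0.5))])
    return props, times, 1.1e5


def td_template(latent: LatentComposition) -> np.ndarray:
    props, times, b = td_components(latent)
    t = TD_AXIS
    rigid = np.exp(-0.5 * (t / times[0]) ** 2) * np.sinc(b * t / np.pi)
    y = (props[0] * rigid + props[1] * np.exp(-t / times[1])
         + props[2] * np.exp(-t / times[2]))
    return 100.0 * y


def ftir_template(latent: LatentComposition) -> np.ndarray:
    x = FTIR_AXIS
    return (0.45 * _gauss(x, 3277.0, 60.0)    # amide A
            + 0.90 * _gauss(x, 1634.0, 16.0)  # amide I
            + 0.18 * _gauss(x, 1652.0, 9.0)
            + 0.62 * _gauss(x, 1516.0, 14.0)  # amide II
            + 0.33 * _gauss(x, 1234.0, 12.0)  # amide III
            + 0.28 * _gauss(x, 2850.0, 9.0)   # CH2 / CH3 stretches
            + 0.22 * _gauss(x, 2958.0, 11.0)
            + 0.20 * _gauss(x, 1050.0, 15.0)
            + 0.26 * _gauss(x, 1390.0, 12.0)
            + 0.12 * _gauss(x, 3060.0, 20.0))


def dtg_template(latent: LatentComposition, weight_mg: float) -> np.ndarray:
    """Mass-loss rate in g/min; event amplitudes scale with sample mass."""
    tr = latent.thermal_resistance
    bw = latent.bound_water
    x = DTG_AXIS
    frac_per_min = (0.003 * (0.7 + 0.3 * bw) * _skew_event(x, 80.0, 25.0, 3.0)
                    + 0.014 * _skew_event(x, 240.0, 15.0, 1.5)
                    + (0.003 + 0.004 * tr) * _skew_event(x, 268.0, 9.0, 0.0)
                    + (0.0025 + 0.0035 * tr) * _skew_event(x, 360.0, 18.0, 0.0)
                    + 0.002 * _skew_event(x, 440.0, 45.0, -2.0))
    return frac_per_min * (weight_mg / 1000.0)


_TEMPLATES = {
    "h1_wideline": (WL_AXIS, wideline_template),
    "h1_mas": (MAS_AXIS, mas_template),
    "c13_cpmas": (CPMAS_AXIS, cpmas_template),
    "tdnmr": (TD_AXIS, td_template),
    "ftir": (FTIR_AXIS, ftir_template),
}

#: Relative amplitude of the smooth per-sample nuisance variation.  Sized
#: so that between-donor profile variation unrelated to the mechanics
#: dominates each profile block's covariance: PCA scores (variance-greedy)
#: then capture nuisance rather than acting as aggregates of the much
#: smaller planted bands.
NUISANCE_AMP = 0.08

#: Per-modality nuisance modes as (center fraction of axis span, width
#: fraction, relative amplitude).  Three broad modes (baseline-like drift)
#: and three narrow ones (band-amplitude variation, wide enough to survive
#: second differentiation); positions avoid the planted feature regions.
#: Each mode is a difference of two equal-width Gaussian lobes (positive
#: at the first fraction, negative at the partner fraction): donor
#: variation redistributes intensity locally without changing the total
#: area, so area normalization is unperturbed.  Lobe positions avoid every
#: planted informative region.
_NUISANCE_SHAPES = {
    # every lobe lies >= 3 sigma inside the truncation window (area
    # neutrality must survive truncation) and >= 3 sigma from every
    # planted feature bin
    "h1_mas": ((0.192, 0.0385, 1.0, 0.804), (0.250, 0.0269, 1.0, 0.827),
               (0.215, 0.0462, 1.0, 0.792), (0.096, 0.006, 1.0, 0.119),
               (0.720, 0.005, 1.0, 0.744), (0.840, 0.008, 1.0, 0.865)),
    "c13_cpmas": ((0.550, 0.08, 1.0, 0.610), (0.475, 0.05, 1.0, 0.675),
                  (0.500, 0.06, 1.0, 0.650), (0.360, 0.006, 1.0, 0.385),
                  (0.550, 0.005, 1.0, 0.575), (0.660, 0.008, 1.0, 0.700)),
    "h1_wideline": ((0.36, 0.08, 1.0, 0.64), (0.30, 0.05, 1.0, 0.70),
                    (0.40, 0.06, 1.0, 0.60), (0.20, 0.006, 1.0, 0.23),
                    (0.72, 0.005, 1.0, 0.75), (0.80, 0.008, 1.0, 0.83)),
    "ftir": ((0.10, 0.030, 1.0, 0.20), (0.13, 0.025, 1.0, 0.22),
             (0.70, 0.028, 1.0, 0.73), (0.05, 0.006, 1.0, 0.08),
             (0.25, 0.005, 1.0, 0.28), (0.65, 0.008, 1.0, 0.68)),
    "default": ((0.25, 0.08, 1.0, 0.31), (0.55, 0.05, 1.0, 0.61),
                (0.80, 0.10, 1.0, 0.87), (0.12, 0.006, 1.0, 0.095),
                (0.64, 0.005, 1.0, 0.615), (0.78, 0.008, 1.0, 0.82)),
}


def _nuisance_modes(modality: str, axis: np.ndarray) -> np.ndarray:
    """Fixed smooth modes of property-unrelated sample variation.

    Real pools differ in many bands beyond the planted latent effects
    (pigmentation, history, surface state); emulating that as a low-rank
    smooth component keeps distractor descriptors varying between samples
    and gives each profile block the structured covariance a >1%-variance
    PCA retention rule expects.
    """
    if modality == "tdnmr":
        return np.stack([np.exp(-axis / tau) for tau in (3e-5, 1e-4, 4e-4)])
    span = axis[-1] - axis[0]
    lo = axis[0]
    shapes = _NUISANCE_SHAPES.get(modality, _NUISANCE_SHAPES["default"])
    modes = [a * (_gauss(axis, lo + f * span, w * span)
                  - _gauss(axis, lo + pf * span, w * span))
             for f, w, a, pf in shapes]
    modes += [a * _gauss(axis, c, s)
              for c, s, a in _INTERFERENCE.get(modality, ())]
    return np.stack(modes)


#: Interfering bands overlapping some informative regions (absolute axis
#: units: center, sigma, relative amplitude).  Their per-sample loads are
#: independent of the latents, so those regions are not clean single-band
#: reads — as with real crowded spectra.  The h1_mas/c13_cpmas informative
#: regions get their overlap structure from the broad+narrow feature pairs
#: instead.
_INTERFERENCE = {
    "dtg": ((272.0, 8.0, 1.2), (352.0, 14.0, 1.0)),
}


def render_spectra(latents: list[LatentComposition], seed: int = 0,
                   snr: float = DEFAULT_SNR,
                   modalities=tuple(REPLICATES),
                   nuisance: bool = True) -> list[Spectrum]:
    """Render replicate curves for every modality from the latents.

    Noise model: additive Gaussian per axis point (template peak / ``snr``),
    a multiplicative per-replicate intensity drift (SD 2%) emulating
    normalization-relevant instrument scale variation, and (unless
    ``nuisance=False``) smooth low-rank per-sample variation unrelated to
    the properties.
    """
    if not latents:
        raise ValueError("no latents supplied")
    for m in modalities:
        if m not in REPLICATES:
            raise ValueError(f"unknown modality {m!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))
    spectra: list[Spectrum] = []
    # noise and nuisance amplitudes are anchored to a fixed reference
    # template (sample-independent), as an instrument's noise floor is
    reference = LatentComposition(
        sample_id="REF", species="human", donor="ref",
        alpha_helix_fraction=0.675, lipid_content=0.4, bound_water=0.5,
        thermal_resistance=0.5, cross_section_area=0.006)
    ref_scale = {m: float(np.abs(_TEMPLATES[m][1](reference)).max())
                 for m in modalities if m != "dtg"}
    for latent in latents:
        deviations = feature_deviations(latent.sample_id, seed)
        shifts = feature_shifts(latent.sample_id, seed)
        for modality in modalities:
            if modality == "dtg":
                weight = float(rng.uniform(10.0, 25.0))
                axis, clean = DTG_AXIS, dtg_template(latent, weight)
                scale_ref = float(
                    np.abs(dtg_template(reference, weight)).max())
            elif modality == "h1_mas":
                weight = None
                axis, clean = MAS_AXIS, mas_template(latent, deviations,
                                                     shifts)
                scale_ref = ref_scale[modality]
            elif modality == "c13_cpmas":
                weight = None
                axis, clean = CPMAS_AXIS, cpmas_template(latent, deviations)
                scale_ref = ref_scale[modality]
            else:
                weight = None
                axis_fn = _TEMPLATES[modality]
                axis, clean = axis_fn[0], axis_fn[1](latent)
                scale_ref = ref_scale[modality]
            if nuisance:
                modes = _nuisance_modes(modality, axis)
                loads = rng.normal(0.0, 1.0, modes.shape[0])
                clean = clean + (NUISANCE_AMP * scale_ref * loads @ modes)
            noise_sd = scale_ref / snr if snr else 0.0
            for rep in range(1, REPLICATES[modality] + 1):
                scale = 1.0 + rng.normal(0.0, REPLICATE_SCALE_SD)
                y = clean * scale + rng.normal(0.0, noise_sd, axis.size)
                spectra.append(Spectrum(
                    modality=modality, axis=axis.copy(), intensity=y,
                    sample_id=latent.sample_id, replicate=rep,
                    sample_weight=weight,
                    lineage=("synthetic",)))
    return spectra


# ---------------------------------------------------------------------------
# tensile properties
# ---------------------------------------------------------------------------

def property_mean(latent: LatentComposition, weights: dict) -> float:
    """Noise-free property value of one sample.

    Properties depend on the latents; the spectra expose the latents only
    through band amounts carrying per-band deviations, so predicting a
    property well requires pooling many informative bins.
    """
    value = weights.get("intercept", 0.0)
    for name in LATENT_JITTER:
        value += weights.get(name, 0.0) * getattr(latent, name)
    if weights.get("area_scaled"):
        value *= latent.cross_section_area
    return value


def render_properties(latents: list[LatentComposition], truth: GroundTruth,
                      seed: int = 0,
                      n_replicates: int = N_PROPERTY_REPLICATES
                      ) -> pd.DataFrame:
    """Tensile-test replicate table: 10 fibers per pool, Gaussian replicate
    noise with the per-property SDs recorded in the ground truth."""
    for prop in PROPERTY_COLUMNS:
        if prop not in truth.property_weights:
            raise ValueError(f"missing weights for {prop}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1BE7]))
    rows = []
    for latent in latents:
        means = {p: property_mean(latent, truth.property_weights[p])
                 for p in PROPERTY_COLUMNS}
        for rep in range(1, n_replicates + 1):
            row = {"sample_id": latent.sample_id, "replicate": rep}
            for p in PROPERTY_COLUMNS:
                row[p] = means[p] + rng.normal(0.0, truth.noise_sd[p])
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# informative descriptor ids and dataset assembly
# ---------------------------------------------------------------------------

def informative_bin_ids(config, regions=INFORMATIVE_REGIONS,
                        latents_subset: set[str] | None = None) -> frozenset:
    """Bin-descriptor ids overlapping the planted informative regions.

    ``config`` is a :class:`keraspec.descriptors.DescriptorConfig`; only bin
    blocks are mapped (the planted signal is localized on the measurement
    axes).
    """
    ids = set()
    for block in config.bin_blocks:
        for region in regions:
            if region.modality != block.modality:
                continue
            if block.derivative not in region.derivatives:
                continue
            if latents_subset is not None and region.latent not in latents_subset:
                continue
            index = 0
            for lo, hi, n_bins in block.regions:
                edges = np.linspace(lo, hi, n_bins + 1)
                eps = 1e-6 * (hi - lo) / n_bins
                for k in range(n_bins):
                    index += 1
                    overlap = (min(edges[k + 1], region.hi)
                               - max(edges[k], region.lo))
                    if overlap > eps:
                        ids.add(f"{block.name}.{index}")
    return frozenset(ids)


def default_truth(config=None) -> GroundTruth:
    """Ground truth under the default descriptor config.

    ``informative_descriptor_ids`` is the planted breaking-force signal: the
    bin descriptors controlled by the latents that carry nonzero
    breaking-force weight (20 ids under the default config).
    """
    if config is None:
        from .descriptors import default_config
        config = default_config()
    bf_latents = {k for k, v in
                  DEFAULT_PROPERTY_WEIGHTS["breaking_force_N"].items()
                  if k in LATENT_JITTER and v != 0.0}
    ids = informative_bin_ids(config, latents_subset=bf_latents)
    return GroundTruth(informative_descriptor_ids=ids,
                       property_weights=DEFAULT_PROPERTY_WEIGHTS,
                       noise_sd=DEFAULT_NOISE_SD)


def generate_dataset(n_samples: int = 63, seed: int = 0,
                     species_mix=DEFAULT_SPECIES_MIX,
                     snr: float = DEFAULT_SNR,
                     truth: GroundTruth | None = None) -> SyntheticDataset:
    """Full synthetic dataset: latents, all-modality spectra, properties."""
    if truth is None:
        truth = default_truth()
    latents = sample_latents(n_samples, species_mix, seed)
    spectra = render_spectra(latents, seed=seed, snr=snr)
    properties = render_properties(latents, truth, seed=seed)
    return SyntheticDataset(latents=latents, spectra=spectra,
                            properties=properties, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def _truth_to_json(truth: GroundTruth, latents) -> dict:
    return {
        "informative_descriptor_ids":
            sorted(truth.informative_descriptor_ids),
        "property_weights": truth.property_weights,
        "noise_sd": truth.noise_sd,
        "regions": [asdict(r) for r in truth.regions],
        "latents": [asdict(lat) for lat in latents],
    }


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_dataset(dataset: SyntheticDataset, directory,
                  overwrite: bool = False) -> dict:
    """Write spectra/properties CSV + truth and manifest JSON; returns the
    manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists (use overwrite=True)")
    write_spectra_csv(dataset.spectra, directory / "spectra.csv")
    dataset.properties.to_csv(directory / "properties.csv", index=False)
    truth_payload = _truth_to_json(dataset.truth, dataset.latents)
    (directory / "truth.json").write_text(
        json.dumps(truth_payload, indent=1, sort_keys=True))
    manifest = {
        "seed": dataset.seed,
        "n_samples": len(dataset.latents),
        "n_spectra": len(dataset.spectra),
        "n_property_rows": int(len(dataset.properties)),
        "config_hash": _config_hash(truth_payload),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_dataset(directory) -> SyntheticDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    truth_payload = json.loads((directory / "truth.json").read_text())
    latents = [LatentComposition(**d) for d in truth_payload["latents"]]
    truth = GroundTruth(
        informative_descriptor_ids=frozenset(
            truth_payload["informative_descriptor_ids"]),
        property_weights=truth_payload["property_weights"],
        noise_sd=truth_payload["noise_sd"],
        regions=tuple(
            InformativeRegion(r["modality"], r["lo"], r["hi"], r["latent"],
                              tuple(r["derivatives"]))
            for r in truth_payload["regions"]))
    spectra = read_spectra_csv(directory / "spectra.csv")
    properties = pd.read_csv(directory / "properties.csv")
    return SyntheticDataset(latents=latents, spectra=spectra,
                            properties=properties, truth=truth,
                            seed=int(manifest["seed"]))
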