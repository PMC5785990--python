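"""Synthetic OCT B-scan phantoms and simulated acquisition studies.

This module emulates the data a Spectralis-style macular raster protocol
produces when vitreous haze is quantified by the vitreous/RPE intensity
ratio (VRI):

* a *phantom* B-scan: a bright horizontal retina band with a brighter RPE
  sub-band at its outer edge and a central foveal dip, over a dark vitreous,
  with frame-averaging-dependent Gaussian noise, focus-dependent blur and
  vitreous gain, and an intensity roll-off near the bottom image edge;
* the canonical acquisition *protocol*: 10 settings (5 ART frame-averaging
  levels in focus, 5 focus offsets at ART 100, plus one bottom-positioned
  acquisition), each repeated 3 times, 7 sections per raster scan;
* a *study simulator* that draws VRI values from a three-level nested
  random-effects model (subject / scan-within-subject / section) around
  per-setting means, optionally rendering each slot as a phantom image.

Images are 8-bit grayscale on disk and floats in ``[0, 1]`` in memory;
row 0 is the top of the frame (the vitreous side).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "AcquisitionSetting",
    "PhantomGeometry",
    "PhantomOptics",
    "PhantomTruth",
    "BScan",
    "ScanSlot",
    "VarianceComponents",
    "PROTOCOL",
    "DEFAULT_SETTING_MEANS",
    "DEFAULT_VARIANCE_COMPONENTS",
    "RPE_REFERENCE_INTENSITY",
    "art_arm",
    "focus_arm",
    "enumerate_protocol",
    "make_phantom",
    "generate_study",
    "inject_failures",
]


# ---------------------------------------------------------------------------
# Acquisition protocol
# ---------------------------------------------------------------------------

ART_LEVELS = (100, 50, 25, 12, 6)
FOCUS_OFFSETS = (5, 10, -5, -10)


@dataclass(frozen=True, order=True)
class AcquisitionSetting:
    """One acquisition condition: vertical position, ART level, focus offset.

    ``position`` is ``"middle"`` or ``"bottom"`` (vertical placement of the
    retina in the frame), ``art`` the number of frames averaged per section,
    ``focus`` the focus offset in dioptres relative to the retinal focus on
    the IR fundus image.
    """

    position: str = "middle"
    art: int = 100
    focus: int = 0

    def __post_init__(self) -> None:
        if self.position not in ("middle", "bottom"):
            raise ValueError(f"position must be 'middle' or 'bottom', got {self.position!r}")
        if self.art < 1:
            raise ValueError(f"art level must be >= 1, got {self.art}")

    @property
    def label(self) -> str:
        focus = f"{self.focus:+d}D" if self.focus else "0D"
        return f"{self.position}/ART{self.art}/{focus}"


def _protocol() -> tuple[AcquisitionSetting, ...]:
    rows = [AcquisitionSetting("middle", art, 0) for art in ART_LEVELS]
    rows += [AcquisitionSetting("middle", 100, f) for f in FOCUS_OFFSETS]
    rows.append(AcquisitionSetting("bottom", 100, 0))
    return tuple(rows)


#: The 10 canonical acquisition settings.
PROTOCOL: tuple[AcquisitionSetting, ...] = _protocol()

_SETTING_INDEX = {s: i for i, s in enumerate(PROTOCOL)}


@dataclass(frozen=True, order=True)
class ScanSlot:
    """One theoretical measurement: subject x setting x repetition x section."""

    subject: int
    setting: AcquisitionSetting
    repetition: int
    section: int

    @property
    def key(self) -> tuple:
        s = self.setting
        return (self.subject, s.position, s.art, s.focus, self.repetition, self.section)


def enumerate_protocol(
    n_subjects: int, repetitions: int = 3, sections: int = 7
) -> list[ScanSlot]:
    """Full factorial of subjects x the 10 protocol settings x reps x sections.

    Subjects, repetitions and sections are numbered from 1.  With the
    canonical design (15 subjects, 3 repetitions, 7 sections) each of the
    two five-setting arms contains 15 x 5 x 3 x 7 = 1575 theoretical
    measurements and each subject contributes 30 raster scans.
    """
    if n_subjects < 1 or repetitions < 1 or sections < 1:
        raise ValueError("n_subjects, repetitions and sections must all be >= 1")
    return [
        ScanSlot(sub, setting, rep, sec)
        for sub, setting, rep, sec in itertools.product(
            range(1, n_subjects + 1),
            PROTOCOL,
            range(1, repetitions + 1),
            range(1, sections + 1),
        )
    ]


def art_arm(slots: Iterable[ScanSlot]) -> list[ScanSlot]:
    """Slots of the ART arm: middle position, in focus, any ART level."""
    return [s for s in slots if s.setting.position == "middle" and s.setting.focus == 0]


def focus_arm(slots: Iterable[ScanSlot]) -> list[ScanSlot]:
    """Slots of the focus arm: middle position, ART 100, any focus offset."""
    return [s for s in slots if s.setting.position == "middle" and s.setting.art == 100]


# ---------------------------------------------------------------------------
# Phantom geometry and optics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomGeometry:
    """Pixel layout of the phantom B-scan.

    The retina band occupies rows ``[retina_top_row, retina_top_row +
    retina_thickness)``; its lowest ``rpe_thickness`` rows are the RPE.
    ``fovea_depth`` is the central downward excursion of the inner retinal
    boundary (the foveal pit).  ``lateral_crop_fraction`` is the central
    fraction of columns regarded as the reliable capture area.
    """

    height: int = 496
    width: int = 512
    retina_top_row: int = 200
    retina_thickness: int = 90
    rpe_thickness: int = 6
    fovea_depth: int = 40
    lateral_crop_fraction: float = 0.6

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.retina_thickness, self.rpe_thickness) <= 0:
            raise ValueError("all pixel dimensions must be positive")
        if self.retina_top_row < 0 or self.fovea_depth < 0:
            raise ValueError("retina_top_row and fovea_depth must be non-negative")
        if self.rpe_thickness > self.retina_thickness:
            raise ValueError("rpe_thickness cannot exceed retina_thickness")
        if self.retina_top_row + self.retina_thickness + self.rpe_thickness > self.height:
            raise ValueError("retina band does not fit inside the image")
        if not 0 < self.lateral_crop_fraction <= 1:
            raise ValueError("lateral_crop_fraction must be in (0, 1]")


# Focus maps: vitreous gain follows the observed ordering of mean VRI across
# focus offsets (in-focus smallest, positive offsets largest); blur grows
# with the magnitude of the offset.  Values are calibration choices: no
# optical model is implied.
_DEFAULT_FOCUS_GAIN = {0: 1.0, -5: 1.8, -10: 3.4, 5: 4.0, 10: 4.2}
_DEFAULT_FOCUS_BLUR = {0: 0.0, -5: 1.0, -10: 2.0, 5: 1.0, 10: 2.0}


@dataclass(frozen=True)
class PhantomOptics:
    """Region intensities and degradation model of the phantom.

    Intensities are in ``[0, 1]``.  ``base_noise_sd`` is the additive
    Gaussian noise standard deviation at ART 1; averaging ``N`` frames
    scales it by ``1/sqrt(N)``.  ``focus_gain_map`` multiplies the vitreous
    intensity per focus offset, ``focus_blur_map`` gives the Gaussian PSF
    sigma in pixels, and ``bottom_fade_depth`` is the extent (in rows) of
    the intensity roll-off at the lower edge of the acquisition window.
    """

    vitreous_mean: float = 0.041
    retina_mean: float = 0.55
    rpe_mean: float = 0.85
    background_mean: float = 0.01
    base_noise_sd: float = 0.08
    focus_gain_map: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_FOCUS_GAIN)
    )
    focus_blur_map: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_FOCUS_BLUR)
    )
    bottom_fade_depth: int = 80
    bottom_fade_floor: float = 0.35

    def __post_init__(self) -> None:
        if not 0 <= self.background_mean <= self.vitreous_mean:
            raise ValueError("need 0 <= background_mean <= vitreous_mean")
        if not self.vitreous_mean < self.rpe_mean <= 1:
            raise ValueError("need vitreous_mean < rpe_mean <= 1")
        if self.base_noise_sd < 0:
            raise ValueError("base_noise_sd must be >= 0")
        if self.focus_gain_map.get(0, 1.0) != 1.0:
            raise ValueError("focus_gain_map must map the in-focus offset to 1")
        if self.focus_blur_map.get(0, 0.0) != 0.0:
            raise ValueError("focus_blur_map must map the in-focus offset to 0")

    def gain(self, focus: int) -> float:
        return float(self.focus_gain_map.get(focus, 1.0))

    def blur(self, focus: int) -> float:
        return float(self.focus_blur_map.get(focus, 0.0))


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth attached to a rendered phantom.

    Masks are boolean arrays congruent with the image; the region means are
    taken over the noise-free rendering, so ``vri`` is the exact value a
    perfect segmentation would measure in the absence of noise.
    """

    tissue_mask: np.ndarray
    rpe_mask: np.ndarray
    vitreous_mask: np.ndarray
    vitreous_mean: float
    rpe_mean: float

    @property
    def vri(self) -> float:
        return self.vitreous_mean / self.rpe_mean


@dataclass
class BScan:
    """A single OCT section: float image in [0, 1] plus acquisition metadata."""

    pixels: np.ndarray
    setting: AcquisitionSetting = AcquisitionSetting()
    subject: int = 0
    repetition: int = 1
    section: int = 1
    truth: PhantomTruth | None = None


def _fovea_profile(geometry: PhantomGeometry) -> np.ndarray:
    """Per-column downward excursion of the inner retinal boundary (pixels)."""
    cols = np.arange(geometry.width)
    centre = (geometry.width - 1) / 2.0
    sigma = geometry.width / 10.0
    dip = geometry.fovea_depth * np.exp(-0.5 * ((cols - centre) / sigma) ** 2)
    return np.round(dip).astype(int)


def make_phantom(
    geometry: PhantomGeometry,
    optics: PhantomOptics,
    setting: AcquisitionSetting,
    seed: int | np.random.SeedSequence | None = 0,
    vitreous_value: float | None = None,
) -> BScan:
    """Render one phantom B-scan under an acquisition setting.

    The vitreous fills everything above the inner retinal boundary at
    ``optics.vitreous_mean * gain(focus)`` (or at ``vitreous_value`` when
    given, which overrides the gain model — used to render targeted VRI
    levels).  Additive Gaussian noise with sd ``base_noise_sd /
    sqrt(art)`` is applied after focus blur; bottom positioning translates
    the band down and applies the edge fade.  Ground-truth masks and
    noise-free region means are recorded on the returned scan.
    """
    g, o = geometry, optics
    dip = _fovea_profile(g)
    inner = g.retina_top_row + dip  # per-column anterior boundary row
    band_bottom = g.retina_top_row + g.retina_thickness

    shift = 0
    if setting.position == "bottom":
        # park the band just above the lower frame edge, inside the fade zone
        shift = g.height - 10 - band_bottom
        if shift < 0:
            raise ValueError("bottom positioning would push the retina band out of frame")
    inner = inner + shift
    band_bottom += shift
    if inner.max() + g.rpe_thickness >= band_bottom:
        raise ValueError("foveal dip reaches the RPE band; invalid phantom geometry")

    rows = np.arange(g.height)[:, None]
    vit_value = o.vitreous_mean * o.gain(setting.focus) if vitreous_value is None else vitreous_value

    vitreous_mask = rows < inner[None, :]
    tissue_mask = (rows >= inner[None, :]) & (rows < band_bottom)
    rpe_mask = tissue_mask & (rows >= band_bottom - g.rpe_thickness)

    clean = np.full((g.height, g.width), o.background_mean, dtype=float)
    clean[vitreous_mask] = vit_value
    clean[tissue_mask] = o.retina_mean
    clean[rpe_mask] = o.rpe_mean

    sigma = o.blur(setting.focus)
    if sigma > 0:
        clean = gaussian_filter(clean, sigma)

    if setting.position == "bottom" and o.bottom_fade_depth > 0:
        depth_below = g.height - 1 - np.arange(g.height)
        ramp = np.clip(depth_below / o.bottom_fade_depth, 0.0, 1.0)
        fade = o.bottom_fade_floor + (1.0 - o.bottom_fade_floor) * ramp
        clean = clean * fade[:, None]

    truth = PhantomTruth(
        tissue_mask=tissue_mask,
        rpe_mask=rpe_mask,
        vitreous_mask=vitreous_mask,
        vitreous_mean=float(clean[vitreous_mask].mean()) if vitreous_mask.any() else float("nan"),
        rpe_mean=float(clean[rpe_mask].mean()),
    )

    noise_sd = o.base_noise_sd / np.sqrt(setting.art)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    else:
        image = clean.copy()
    np.clip(image, 0.0, 1.0, out=image)

    return BScan(pixels=image, setting=setting, truth=truth)


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceComponents:
    """Standard deviations of the nested random effects, in VRI units."""

    sigma_subject: float = 0.012
    sigma_scan: float = 0.007
    sigma_section: float = 0.010

    def __post_init__(self) -> None:
        if min(self.sigma_subject, self.sigma_scan, self.sigma_section) < 0:
            raise ValueError("variance components must be >= 0")


#: Simulation ground truth for the nested variability structure.
DEFAULT_VARIANCE_COMPONENTS = VarianceComponents()

#: Per-setting mean VRI used as the simulator's study conditions.
DEFAULT_SETTING_MEANS: dict[AcquisitionSetting, float] = {
    AcquisitionSetting("middle", 6, 0): 0.043,
    AcquisitionSetting("middle", 12, 0): 0.043,
    AcquisitionSetting("middle", 25, 0): 0.043,
    AcquisitionSetting("middle", 50, 0): 0.039,
    AcquisitionSetting("middle", 100, 0): 0.048,
    AcquisitionSetting("middle", 100, -5): 0.088,
    AcquisitionSetting("middle", 100, -10): 0.162,
    AcquisitionSetting("middle", 100, 5): 0.192,
    AcquisitionSetting("middle", 100, 10): 0.200,
    AcquisitionSetting("bottom", 100, 0): 0.162,
}

#: Nominal RPE intensity used to back out component intensities from a VRI.
RPE_REFERENCE_INTENSITY = 0.85

TABLE_COLUMNS = [
    "subject",
    "position",
    "art",
    "focus",
    "repetition",
    "section",
    "vri",
    "vitreous_mean",
    "rpe_mean",
    "failed",
]


def _setting_entropy(setting: AcquisitionSetting) -> tuple[int, int, int]:
    return (0 if setting.position == "middle" else 1, setting.art, setting.focus + 100)


def _draw(seed: int, tag: int, *key: int) -> float:
    """One standard-normal draw from a stream keyed by (seed, tag, key).

    Streams are derived by seeding on the slot key itself, so subsetting a
    design never changes the values drawn for other slots.
    """
    ss = np.random.SeedSequence([int(seed), tag, *key])
    return float(np.random.default_rng(ss).standard_normal())


def generate_study(
    slots: Sequence[ScanSlot],
    mu_by_setting: Mapping[AcquisitionSetting, float] | None = None,
    vc: VarianceComponents = DEFAULT_VARIANCE_COMPONENTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate VRI measurements for every slot of a design.

    The value for subject ``i``, repetition ``j``, section ``k`` under a
    setting with mean ``mu`` is ``mu + b_i + c_ij + e_ijk`` with independent
    zero-mean Gaussian effects of sd ``sigma_subject``, ``sigma_scan`` and
    ``sigma_section``.  The subject effect is shared across settings; the
    scan effect is specific to one raster scan (setting x repetition).
    Returns a long-format table with one row per slot.
    """
    mu_by_setting = DEFAULT_SETTING_MEANS if mu_by_setting is None else mu_by_setting
    for setting in {s.setting for s in slots}:
        if setting not in mu_by_setting:
            raise KeyError(f"no mean VRI provided for setting {setting.label}")

    records = []
    for slot in slots:
        s = slot.setting
        ent = _setting_entropy(s)
        mu = mu_by_setting[s]
        b = vc.sigma_subject * _draw(seed, 1, slot.subject)
        c = vc.sigma_scan * _draw(seed, 2, slot.subject, *ent, slot.repetition)
        e = vc.sigma_section * _draw(seed, 3, slot.subject, *ent, slot.repetition, slot.section)
        vri = mu + b + c + e
        records.append(
            (
                slot.subject,
                s.position,
                s.art,
                s.focus,
                slot.repetition,
                slot.section,
                vri,
                vri * RPE_REFERENCE_INTENSITY,
                RPE_REFERENCE_INTENSITY,
                False,
            )
        )
    return pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)


def inject_failures(
    table: pd.DataFrame,
    failure_prob_by_setting: Mapping[AcquisitionSetting, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Mark rows as failed measurements, independently per slot.

    Failed rows keep their key but lose the measured quantities (NaN) and
    get ``failed=True``.  Settings absent from the mapping never fail.
    """
    for p in failure_prob_by_setting.values():
        if not 0 <= p <= 1:
            raise ValueError("failure probabilities must lie in [0, 1]")
    out = table.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    u = rng.random(len(out))
    probs = np.array(
        [
            failure_prob_by_setting.get(
                AcquisitionSetting(row.position, int(row.art), int(row.focus)), 0.0
            )
            for row in out.itertuples()
        ]
    )
    fail = u < probs
    out.loc[fail, ["vri", "vitreous_mean", "rpe_mean"]] = np.nan
    out.loc[fail, "failed"] = True
    return out


def render_slot(
    slot: ScanSlot,
    target_vri: float,
    geometry: PhantomGeometry = PhantomGeometry(),
    optics: PhantomOptics = PhantomOptics(),
    seed: int = 0,
) -> BScan:
    """Render a phantom whose true (noise-free) VRI equals ``target_vri``.

    The vitreous intensity is set to ``target_vri * optics.rpe_mean``,
    overriding the focus gain model, so the measured VRI tracks the target
    monotonically while noise, blur and positioning still follow the slot's
    acquisition setting.
    """
    ss = np.random.SeedSequence([int(seed), 5, slot.subject, *_setting_entropy(slot.setting),
                                 slot.repetition, slot.section])
    scan = make_phantom(
        geometry,
        optics,
        slot.setting,
        seed=ss,
        vitreous_value=target_vri * optics.rpe_mean,
    )
    scan.subject = slot.subject
    scan.repetition = slot.repetition
    scan.section = slot.section
    return scan
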