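"""Synthetic multichannel EEG cohorts with dementia-like group structure.

Clinical resting-state EEG in Alzheimer's disease shows "slowing":
power shifts from the alpha rhythm toward delta/theta, signal
complexity drops, and the changes are most pronounced over posterior
regions. This module generates 19-channel cohorts carrying exactly
those contrasts — enough statistical structure for the band-power and
entropy features downstream to discriminate the groups — without any
claim to biophysical realism.

Generative model per channel: a sum of five band-limited Gaussian
noise components (one per rhythm, white noise shaped by the equiripple
band filters) with variances set by a group- and region-specific
band-power profile, plus a 1/f^a pink background. A complexity factor
in (0, 1] applies AR(1) smoothing inside each band component
(variance-renormalized), narrowing its effective bandwidth and
lowering entropy without changing band power. Channels within an
anatomical region share a common component; channels in different
regions are independent. An ``effect_size`` knob interpolates every
group's parameters between the control values (0 = all groups
identically distributed) and the specified profile (1).

Artifacts are emulated as Poisson-count 1 s masked intervals — they
exist to exercise the exclusion logic, not to model EMG morphology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .filters import band_taps, zero_phase_fir
from .montage import BAND_NAMES, CHANNELS_1020, REGION_OF_CHANNEL, REGIONS
from .preprocess import Recording, write_recording_csv

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "generate_channel",
    "generate_cohort",
    "inject_artifacts",
    "save_cohort",
    "default_band_profile",
    "strong_slowing_profile",
    "posterior_effect_profile",
]

GROUPS = ("CN", "mild", "moderate")

#: Age IQR (years) per group, used as uniform sampling ranges.
AGE_RANGE = {"CN": (62.25, 72.0), "mild": (68.5, 77.25), "moderate": (61.25, 68.25)}

#: MMSE integer ranges per group (30 = cognitively intact).
MMSE_RANGE = {"CN": (30, 30), "mild": (19, 23), "moderate": (10, 18)}

#: Recording duration ranges (s): controls 20-23 min, patients 11-17 min.
DURATION_RANGE = {
    "CN": (1200.0, 1380.0),
    "mild": (660.0, 1020.0),
    "moderate": (660.0, 1020.0),
}

def _profile(delta, theta, alpha, beta, gamma):
    w = np.array([delta, theta, alpha, beta, gamma], dtype=float)
    return w / w.sum()


def default_band_profile() -> Dict[str, Dict[str, np.ndarray]]:
    """Moderate AD-slowing profiles: posterior alpha dominance in
    controls, diffuse delta/theta elevation growing with severity."""
    return {
        "CN": {
            "anterior": _profile(0.20, 0.20, 0.25, 0.25, 0.10),
            "central": _profile(0.15, 0.15, 0.35, 0.25, 0.10),
            "temporal_left": _profile(0.18, 0.17, 0.30, 0.25, 0.10),
            "temporal_right": _profile(0.18, 0.17, 0.30, 0.25, 0.10),
            "posterior": _profile(0.12, 0.13, 0.45, 0.20, 0.10),
        },
        "mild": {
            "anterior": _profile(0.25, 0.24, 0.18, 0.23, 0.10),
            "central": _profile(0.22, 0.21, 0.25, 0.22, 0.10),
            "temporal_left": _profile(0.23, 0.22, 0.22, 0.23, 0.10),
            "temporal_right": _profile(0.23, 0.22, 0.22, 0.23, 0.10),
            "posterior": _profile(0.20, 0.20, 0.30, 0.20, 0.10),
        },
        "moderate": {
            "anterior": _profile(0.30, 0.27, 0.15, 0.18, 0.10),
            "central": _profile(0.28, 0.26, 0.18, 0.18, 0.10),
            "temporal_left": _profile(0.28, 0.26, 0.18, 0.18, 0.10),
            "temporal_right": _profile(0.28, 0.26, 0.18, 0.18, 0.10),
            "posterior": _profile(0.28, 0.27, 0.18, 0.17, 0.10),
        },
    }


def strong_slowing_profile() -> Dict[str, Dict[str, np.ndarray]]:
    """Strong, spatially uniform slowing: delta+theta weight 0.7 in
    moderate AD versus 0.3 in controls (mild halfway)."""
    cn = _profile(0.15, 0.15, 0.40, 0.20, 0.10)          # delta+theta 0.3
    mild = _profile(0.25, 0.25, 0.25, 0.15, 0.10)        # delta+theta 0.5
    moderate = _profile(0.35, 0.35, 0.12, 0.10, 0.08)    # delta+theta 0.7
    return {
        "CN": {r: cn for r in REGIONS},
        "mild": {r: mild for r in REGIONS},
        "moderate": {r: moderate for r in REGIONS},
    }


def posterior_effect_profile() -> Dict[str, Dict[str, np.ndarray]]:
    """Group differences confined to posterior/central regions; the
    anterior and temporal profiles are identical across groups."""
    flat = _profile(0.20, 0.20, 0.25, 0.25, 0.10)
    cn_post = _profile(0.12, 0.13, 0.45, 0.20, 0.10)
    ad_post = _profile(0.32, 0.30, 0.13, 0.15, 0.10)
    cn_cent = _profile(0.17, 0.17, 0.33, 0.23, 0.10)
    ad_cent = _profile(0.26, 0.25, 0.19, 0.20, 0.10)
    out = {}
    for g, post, cent in (("CN", cn_post, cn_cent),
                          ("mild", ad_post, ad_cent),
                          ("moderate", ad_post, ad_cent)):
        out[g] = {
            "anterior": flat, "temporal_left": flat, "temporal_right": flat,
            "central": cent, "posterior": post,
        }
    return out


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate a typical clinical dementia-EEG cohort: 10
    controls, 8 mild and 6 moderate AD subjects, 19 channels at
    500 Hz, controls recorded for 20–23 min and patients for
    11–17 min.
    """

    n_controls: int = 10
    n_mild: int = 8
    n_moderate: int = 6
    fs: float = 500.0
    duration_range_per_group: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DURATION_RANGE))
    montage: Tuple[str, ...] = CHANNELS_1020
    band_profile: Dict[str, Dict[str, np.ndarray]] = field(
        default_factory=default_band_profile)
    pink_exponent: Dict[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in GROUPS})
    #: pink-background variance as a fraction of the rhythm variance
    pink_fraction: float = 0.1
    complexity_factor: Dict[str, float] = field(
        default_factory=lambda: {"CN": 1.0, "mild": 0.85, "moderate": 0.7})
    #: variance fraction of the within-region shared component
    region_coupling: float = 0.3
    artifact_rate: float = 0.5  # events per minute
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_controls, self.n_mild, self.n_moderate) <= 0:
            raise ValueError("every group size must be positive")
        if len(self.montage) != 19 or len(set(self.montage)) != 19:
            raise ValueError("montage must list 19 distinct channel labels")
        if self.fs <= 130:
            raise ValueError("fs must exceed 130 Hz for the 0.5-60 Hz bands")
        for g in GROUPS:
            lo, hi = self.duration_range_per_group[g]
            if not 0 < lo <= hi:
                raise ValueError(f"invalid duration range for {g}: ({lo}, {hi})")
            cf = self.complexity_factor[g]
            if not 0 < cf <= 1:
                raise ValueError(f"complexity_factor[{g}]={cf} outside (0, 1]")
            for region in REGIONS:
                w = np.asarray(self.band_profile[g][region], dtype=float)
                if w.shape != (5,) or (w < 0).any() or w.sum() <= 0:
                    raise ValueError(
                        f"band profile for {g}/{region} must be 5 nonnegative "
                        "weights with positive sum")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if not 0 <= self.pink_fraction < 1:
            raise ValueError("pink_fraction must be in [0, 1)")
        if not 0 <= self.region_coupling < 1:
            raise ValueError("region_coupling must be in [0, 1)")

    def effective(self, group: str, region: str):
        """Group parameters after effect-size interpolation toward CN."""
        es = self.effect_size
        w_cn = np.asarray(self.band_profile["CN"][region], dtype=float)
        w_cn = w_cn / w_cn.sum()
        w_g = np.asarray(self.band_profile[group][region], dtype=float)
        w_g = w_g / w_g.sum()
        w = w_cn + es * (w_g - w_cn)
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        cf_cn = self.complexity_factor["CN"]
        cf = cf_cn + es * (self.complexity_factor[group] - cf_cn)
        pe_cn = self.pink_exponent["CN"]
        pe = pe_cn + es * (self.pink_exponent[group] - pe_cn)
        return w, float(cf), float(pe)


@dataclass
class SubjectRecord:
    """One synthetic subject: metadata plus the raw recording."""

    subject_id: str
    group: str
    age: float
    mmse: int
    recording: Recording


def _pink_noise(n: int, exponent: float, rng: np.random.Generator,
                fs: float) -> np.ndarray:
    """Unit-variance 1/f^exponent Gaussian noise, band-limited to >=0.5 Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs >= 0.5  # avoid the 1/f singularity below the analysis band
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    phases = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    x = np.fft.irfft(amp * phases, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_channel(profile: Sequence[float], duration: float, fs: float,
                     complexity_factor: float = 1.0, pink_exponent: float = 1.0,
                     pink_fraction: float = 0.1, amplitude: float = 10.0,
                     rng=None, seed: int | None = None) -> np.ndarray:
    """Generate one channel of band-structured noise.

    ``profile`` gives the five relative band powers (delta..gamma); the
    output is zero-mean with RMS ≈ ``amplitude`` µV and relative band
    powers approximating the profile. ``complexity_factor`` < 1 smooths
    each band component with an AR(1) filter (variance-renormalized),
    reducing entropy at constant band power.
    """
    w = np.asarray(profile, dtype=float)
    if w.shape != (5,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("profile must be 5 nonnegative weights, not all zero")
    w = w / w.sum()
    n = int(round(duration * fs))
    if n < 2 * fs:
        raise ValueError("duration must cover at least 2 s of samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    phi = 0.95 * (1.0 - complexity_factor)  # AR(1) pole; 0 at factor 1
    # synthesize with a one-filter-length margin on each side and trim:
    # zero-phase filtering of a finite signal leaves edge transients that
    # would otherwise leak broadband power into the stopbands.
    margin = max(len(band_taps(fs, name)) for name in BAND_NAMES)
    n_full = n + 2 * margin
    x = np.zeros(n)
    for b, name in enumerate(BAND_NAMES):
        if w[b] == 0:
            continue
        comp = zero_phase_fir(rng.normal(size=n_full), band_taps(fs, name))
        if phi > 0:
            comp = sps.lfilter([1.0], [1.0, -phi], comp)
        comp = comp[margin:margin + n]
        sd = comp.std()
        if sd > 0:
            comp *= np.sqrt(w[b]) / sd
        x += comp
    if pink_fraction > 0:
        pink = _pink_noise(n, pink_exponent, rng, fs)
        x = np.sqrt(1 - pink_fraction) * x + np.sqrt(pink_fraction) * pink
    x -= x.mean()
    return amplitude * x


def inject_artifacts(recording: Recording, rate: float,
                     seed: int | None = None, rng=None) -> Recording:
    """Mark Poisson-count artifact intervals of fixed 1 s length.

    ``rate`` is in events per minute; intervals are clamped inside the
    recording. Returns a copy with the mask set; rate 0 gives an empty
    mask.
    """
    if rate < 0:
        raise ValueError("artifact rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    dur = recording.duration
    mask: List[Tuple[float, float]] = []
    if rate > 0 and dur > 1.0:
        n_events = rng.poisson(rate * dur / 60.0)
        starts = np.sort(rng.uniform(0.0, dur - 1.0, size=n_events))
        mask = [(float(s), float(s + 1.0)) for s in starts]
    return replace(recording, artifact_mask=mask)


def generate_cohort(spec: CohortSpec) -> List[SubjectRecord]:
    """Generate the full cohort described by ``spec``.

    Deterministic in ``spec.seed``: per-subject random streams are
    spawned from a single seed sequence, so identical specs produce
    bit-identical cohorts.
    """
    ss = np.random.SeedSequence(spec.seed)
    subjects: List[SubjectRecord] = []
    sizes = {"CN": spec.n_controls, "mild": spec.n_mild, "moderate": spec.n_moderate}
    counter = 0
    for group in GROUPS:
        for k in range(sizes[group]):
            rng = np.random.default_rng(ss.spawn(1)[0])
            counter += 1
            sid = f"S{counter:03d}"
            lo, hi = spec.duration_range_per_group[group]
            duration = float(rng.uniform(lo, hi))
            age = float(rng.uniform(*AGE_RANGE[group]))
            m_lo, m_hi = MMSE_RANGE[group]
            mmse = int(rng.integers(m_lo, m_hi + 1))
            n = int(round(duration * spec.fs))
            data = np.empty((19, n))
            # shared within-region components
            shared: Dict[str, Dict] = {}
            for region in REGIONS:
                w, cf, pe = spec.effective(group, region)
                shared[region] = generate_channel(
                    w, duration, spec.fs, complexity_factor=cf,
                    pink_exponent=pe, pink_fraction=spec.pink_fraction,
                    amplitude=1.0, rng=rng)
            for ci, ch in enumerate(spec.montage):
                region = REGION_OF_CHANNEL[ch]
                w, cf, pe = spec.effective(group, region)
                own = generate_channel(
                    w, duration, spec.fs, complexity_factor=cf,
                    pink_exponent=pe, pink_fraction=spec.pink_fraction,
                    amplitude=1.0, rng=rng)
                rho = spec.region_coupling
                data[ci] = 10.0 * (np.sqrt(1 - rho) * own
                                   + np.sqrt(rho) * shared[region])
            rec = Recording(
                data=data, fs=spec.fs, labels=spec.montage,
                meta={"subject_id": sid, "group": group, "age": age,
                      "mmse": mmse},
            )
            rec = inject_artifacts(rec, spec.artifact_rate, rng=rng)
            subjects.append(SubjectRecord(sid, group, age, mmse, rec))
    logger.info("generated cohort: %d subjects", len(subjects))
    return subjects


def save_cohort(subjects: List[SubjectRecord], out_dir) -> Path:
    """Write one CSV signal matrix per subject plus a metadata table.

    Returns the path of the metadata CSV (`cohort.csv`: subject_id,
    group, age, mmse, duration_s).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        write_recording_csv(s.recording, out / f"{s.subject_id}.csv")
        rows.append(
            f"{s.subject_id},{s.group},{s.age:.2f},{s.mmse},"
            f"{s.recording.duration:.2f}"
        )
    meta_path = out / "cohort.csv"
    meta_path.write_text(
        "subject_id,group,age,mmse,duration_s\n" + "\n".join(rows) + "\n"
    )
    return meta_path
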