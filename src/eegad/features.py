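"""The 38-feature-per-channel bank.

Per channel: 8 full-band time-domain features (mean, variance, SD,
skewness, kurtosis, IQR, Shannon entropy, multiscale entropy) plus 6
spectral features (band energy, relative band power, approximate /
permutation / Tsallis / sample entropy) for each of the five rhythms
obtained with the equiripple FIR filter bank — 38 per channel, 722
for the 19-channel montage, plus the class label.

Per-band features are computed on the band-filtered *time series*,
not on spectral coefficients. Conventions (documented because the
quantities are otherwise ambiguous):

- variance/SD use the population (1/n) normalization;
- skewness is the population third standardized moment, kurtosis the
  non-excess fourth (Gaussian -> 3); both defined as 0 for a
  zero-variance segment;
- IQR uses the linear-interpolation quantile rule;
- histogram entropies use equal-width bins spanning the segment's
  min–max range.

Epochs for which any feature is not estimable (e.g. sample entropy
with zero template matches, relative power of an all-zero segment)
are dropped from the assembled table and counted in the log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import entropy as ent
from .filters import band_taps, zero_phase_fir
from .montage import BAND_NAMES, BANDS
from .preprocess import Epoch

logger = logging.getLogger(__name__)

__all__ = [
    "EstimatorParams",
    "band_decompose",
    "band_energy",
    "relative_band_power",
    "time_domain_features",
    "extract_feature_vector",
    "extract_features",
    "feature_columns",
    "TIME_FEATURES",
    "BAND_FEATURES",
]

TIME_FEATURES: Tuple[str, ...] = (
    "mean", "variance", "std", "skewness", "kurtosis", "iqr", "shanen", "mse",
)
BAND_FEATURES: Tuple[str, ...] = (
    "energy", "rbp", "apen", "permen", "tsalen", "sampen",
)


@dataclass
class EstimatorParams:
    """Entropy-estimator parameters (field-standard defaults).

    m / r_factor: ApEn and SampEn embedding dimension and Chebyshev
    tolerance as a fraction of the analyzed segment's SD; perm_order /
    perm_delay: ordinal pattern length and lag; tsallis_q: Tsallis
    order; mse_scales: coarse-graining scales averaged into the MSE
    summary; hist_bins: equal-width amplitude histogram bins for
    Shannon/Tsallis entropy.
    """

    m: int = 2
    r_factor: float = 0.2
    perm_order: int = 3
    perm_delay: int = 1
    tsallis_q: float = 2.0
    mse_scales: Tuple[int, ...] = (1, 2, 3, 4, 5)
    hist_bins: int = 100

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if self.perm_order < 2:
            raise ValueError("perm_order must be >= 2")
        if min(self.mse_scales) < 1:
            raise ValueError("all MSE scales must be >= 1")


def band_decompose(x: np.ndarray, band: str, fs: float) -> np.ndarray:
    """Band-limit one channel to a named rhythm (zero-phase equiripple FIR)."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}")
    return zero_phase_fir(np.asarray(x, dtype=np.float64), band_taps(fs, band))


def band_energy(band_signal: np.ndarray) -> float:
    """Signal energy, sum of squared samples (µV²·samples)."""
    x = np.asarray(band_signal, dtype=np.float64)
    return float((x * x).sum())


def relative_band_power(x: np.ndarray, fs: float) -> Dict[str, float]:
    """Relative band power over the five rhythms; fractions sum to 1.

    Returns ``nan`` for every band when the epoch carries no energy in
    the analysis range (the quantity is undefined there).
    """
    energies = {b: band_energy(band_decompose(x, b, fs)) for b in BAND_NAMES}
    total = sum(energies.values())
    if total <= 0:
        return {b: math.nan for b in BAND_NAMES}
    return {b: e / total for b, e in energies.items()}


def time_domain_features(x: np.ndarray, params: EstimatorParams | None = None
                         ) -> Dict[str, float]:
    """The 8 full-band statistics of one channel segment."""
    params = params or EstimatorParams()
    x = np.asarray(x, dtype=np.float64)
    if x.size < 100:
        raise ValueError("segment too short (need >= 100 samples)")
    var = float(x.var())
    if x.max() == x.min():  # constant segment: moments/entropies degenerate
        var = 0.0
        skew, kurt, shanen, mse = 0.0, 0.0, 0.0, 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        shanen = ent.shannon_entropy(x, params.hist_bins)
        mse = ent.multiscale_entropy(x, params.m, params.r_factor,
                                     params.mse_scales)
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "mean": float(x.mean()),
        "variance": var,
        "std": math.sqrt(var),
        "skewness": skew,
        "kurtosis": kurt,
        "iqr": float(q3 - q1),
        "shanen": shanen,
        "mse": mse,
    }


def _channel_features(x: np.ndarray, fs: float, params: EstimatorParams
                      ) -> List[float]:
    """The 38 features of one channel, in documented column order."""
    td = time_domain_features(x, params)
    values = [td[name] for name in TIME_FEATURES]
    band_sigs = {b: band_decompose(x, b, fs) for b in BAND_NAMES}
    energies = {b: band_energy(s) for b, s in band_sigs.items()}
    total = sum(energies.values())
    for b in BAND_NAMES:
        s = band_sigs[b]
        sd = float(s.std())
        if sd == 0.0:
            apen, sampen = 0.0, 0.0
        else:
            apen, sampen = ent.apen_sampen(s, params.m, params.r_factor * sd)
        values.extend([
            energies[b],
            energies[b] / total if total > 0 else math.nan,
            apen,
            ent.permutation_entropy(s, params.perm_order, params.perm_delay),
            ent.tsallis_entropy(s, params.tsallis_q, params.hist_bins)
            if sd > 0 else 0.0,
            sampen,
        ])
    return values


def feature_columns(labels: Sequence[str]) -> List[str]:
    """Column names ``{channel}_{feature}[_{band}]`` in extraction order."""
    cols = []
    for ch in labels:
        cols.extend(f"{ch}_{f}" for f in TIME_FEATURES)
        for b in BAND_NAMES:
            cols.extend(f"{ch}_{f}_{b}" for f in BAND_FEATURES)
    return cols


def extract_feature_vector(epoch: Epoch, params: EstimatorParams | None = None
                           ) -> pd.Series:
    """All 722 features of one 19-channel epoch plus its label.

    The returned Series carries ``subject_id``, ``window_s`` and
    ``label`` ahead of the feature columns. Values may contain ``nan``
    sentinels; :func:`extract_features` drops such epochs.
    """
    params = params or EstimatorParams()
    if epoch.data.shape[0] != 19:
        raise ValueError(f"expected 19 channels, got {epoch.data.shape[0]}")
    values: List[float] = []
    for ci in range(19):
        values.extend(_channel_features(epoch.data[ci], epoch.fs, params))
    index = feature_columns(epoch.labels)
    head = pd.Series(
        {"subject_id": epoch.subject_id, "window_s": epoch.window_s,
         "label": epoch.group})
    return pd.concat([head, pd.Series(values, index=index, dtype=float)])


def extract_features(epochs: Sequence[Epoch],
                     params: EstimatorParams | None = None) -> pd.DataFrame:
    """Feature table, one row per epoch; sentinel-bearing rows dropped."""
    params = params or EstimatorParams()
    rows = [extract_feature_vector(e, params) for e in epochs]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows).reset_index(drop=True)
    feat_cols = df.columns[3:]
    keep = df[feat_cols].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d/%d epochs with non-estimable features",
                    n_dropped, len(df))
    return df[keep].reset_index(drop=True)
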