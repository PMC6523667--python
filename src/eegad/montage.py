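"""Electrode montage, frequency bands and regional channel clusters.

The 19-channel 10–20 scalp montage, the five canonical EEG rhythms
(delta through gamma, with gamma capped at 60 Hz by the analysis
band limit), and the five anatomical electrode clusters used for
region-wise classification.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

#: Ordered 10–20 scalp montage used throughout the pipeline.
CHANNELS_1020: Tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Canonical EEG rhythms (Hz). Gamma is truncated at the 60 Hz analysis limit.
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 60.0),
}

BAND_NAMES: Tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Anatomical electrode clusters for region-wise analysis.
CLUSTERS: Dict[str, Tuple[str, ...]] = {
    "whole": CHANNELS_1020,
    "anterior": ("Fp1", "F3", "Fz", "Fp2", "F4"),
    "central": ("C3", "Cz", "C4"),
    "temporal_left": ("F7", "T3", "T5"),
    "temporal_right": ("F8", "T4", "T6"),
    "posterior": ("O1", "O2", "P3", "Pz", "P4"),
}

#: Cluster each electrode belongs to (excluding the whole-brain pseudo-cluster).
REGION_OF_CHANNEL: Dict[str, str] = {
    ch: name
    for name, chans in CLUSTERS.items()
    if name != "whole"
    for ch in chans
}

REGIONS: Tuple[str, ...] = (
    "anterior", "central", "temporal_left", "temporal_right", "posterior",
)


def cluster_channels(name: str) -> List[str]:
    """Return the ordered channel labels of a cluster.

    Channels are returned in montage order so that feature-column
    ordering is stable regardless of how the cluster is written down.
    """
    try:
        members = set(CLUSTERS[name])
    except KeyError:
        raise KeyError(
            f"unknown cluster {name!r}; expected one of {sorted(CLUSTERS)}"
        ) from None
    return [ch for ch in CHANNELS_1020 if ch in members]
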