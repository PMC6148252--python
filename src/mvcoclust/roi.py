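"""Static ROI inventory: 90 regions across 14 intrinsic connectivity networks.

The inventory follows the resting-state ICA-derived network parcellation in
which each network contributes a fixed number of regions (90 in total).
Cerebellum-related regions are unreliable in many acquisitions; analyses in
this package conventionally use a 78-region subset, but the subset choice is
a parameter of the caller, not of this table.
"""

from __future__ import annotations

# network name -> number of ROIs
NETWORK_ROI_COUNTS: dict[str, int] = {
    "Anterior_Salience": 7,
    "Auditory": 3,
    "Basal_Ganglia": 5,
    "Dorsal_DMN": 9,
    "Language": 7,
    "LECN": 6,
    "Precuneus": 4,
    "Posterior_Salience": 12,
    "RECN": 6,
    "Ventral_DMN": 10,
    "Visuospatial": 11,
    "Primary_Visual": 2,
    "Higher_Visual": 2,
    "Sensorimotor": 6,
}


def total_rois() -> int:
    """Total region count across all 14 networks (90)."""
    return sum(NETWORK_ROI_COUNTS.values())


def roi_names() -> list[str]:
    """Region identifiers ``<Network>.<index>``, numbered within network."""
    out = []
    for net, k in NETWORK_ROI_COUNTS.items():
        out.extend(f"{net}.{i + 1:02d}" for i in range(k))
    return out


def n_fc_features(n_rois: int) -> int:
    """Number of unordered ROI-pair correlation features, n*(n-1)/2."""
    return n_rois * (n_rois - 1) // 2
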