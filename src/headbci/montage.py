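"""The 32-channel 10-20 montage and the scalp weighting of the planted signal.

Channel names follow the Biosemi 32-electrode layout. Two weight maps are
defined for the synthetic generator:

``RP_WEIGHTS``
    Spatial profile of the non-lateralised slow pre-movement negativity
    (readiness-potential-like ramp), strongest at the vertex and
    fronto-central sites, zero at posterior/neck-adjacent electrodes.

``LATERAL_SIGNS``
    Sign map of the lateralised component: +1 over left-hemisphere
    frontal/central sites, -1 over the homologous right-hemisphere sites,
    0 on the midline and posteriorly. For a *left* rotation the lateral
    component is added with this sign; for a *right* rotation with the
    opposite sign, so hemispheric asymmetry flips with movement direction.
"""

from __future__ import annotations

CHANNELS_32: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

# Non-lateralised ramp topography (vertex / fronto-central maximum).
RP_WEIGHTS: dict[str, float] = {
    "Cz": 1.0, "FC1": 0.8, "FC2": 0.8, "Fz": 0.7, "C3": 0.6, "C4": 0.6,
    "CP1": 0.5, "CP2": 0.5, "F3": 0.4, "F4": 0.4, "FC5": 0.3, "FC6": 0.3,
}

# Lateralised component: + on the left hemisphere, - on the right,
# frontal/central only; nothing posterior or on the midline.
LATERAL_SIGNS: dict[str, float] = {
    "F3": 1.0, "FC1": 1.0, "C3": 1.0, "FC5": 0.7, "F7": 0.5, "AF3": 0.5,
    "F4": -1.0, "FC2": -1.0, "C4": -1.0, "FC6": -0.7, "F8": -0.5, "AF4": -0.5,
}

# Electrodes adjacent to the neck / posterior rim, used to verify that the
# generator plants no directional information there.
POSTERIOR_CHANNELS: tuple[str, ...] = ("O1", "Oz", "O2", "PO3", "PO4", "P7", "P8")


def channel_index(name: str, channels: tuple[str, ...] = CHANNELS_32) -> int:
    return channels.index(name)


def weight_vector(weights: dict[str, float], channels: tuple[str, ...] = CHANNELS_32):
    import numpy as np

    return np.array([weights.get(ch, 0.0) for ch in channels])
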