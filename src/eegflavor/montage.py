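"""38-channel scalp montage (10-10 system) used throughout the package.

The channel list, the region grouping and the flat 2-D layout used for
topography export are fixed here so that feature ordering is stable and
documented.  Coordinates are schematic head-circle positions (nose up,
x to the right), intended for tabular topography output, not rendering.
"""

from __future__ import annotations

# Channel order is the canonical feature ordering (channels-major).
CHANNELS_38: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF3", "AFz", "AF4",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CPz", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Occipital subset used for individual-alpha-frequency estimation.
OCCIPITAL: tuple[str, ...] = ("O1", "Oz", "O2")

REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fpz", "Fp2", "AF3", "AFz", "AF4", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("FC5", "FC1", "FC2", "FC6", "C3", "Cz", "C4"),
    "temporal": ("T7", "T8"),
    "parietal": ("CP5", "CP1", "CPz", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8"),
    "occipital": ("PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2"),
}

# (x, y) on the unit head circle; anterior y > 0.
LAYOUT_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fpz": (0.0, 1.0), "Fp2": (0.31, 0.95),
    "AF3": (-0.35, 0.75), "AFz": (0.0, 0.80), "AF4": (0.35, 0.75),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.55), "Fz": (0.0, 0.60),
    "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.70, 0.30), "FC1": (-0.25, 0.30), "FC2": (0.25, 0.30),
    "FC6": (0.70, 0.30),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.70, -0.30), "CP1": (-0.25, -0.30), "CPz": (0.0, -0.30),
    "CP2": (0.25, -0.30), "CP6": (0.70, -0.30),
    "P7": (-0.81, -0.59), "P3": (-0.45, -0.55), "Pz": (0.0, -0.60),
    "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO7": (-0.55, -0.78), "PO3": (-0.30, -0.78), "POz": (0.0, -0.80),
    "PO4": (0.30, -0.78), "PO8": (0.55, -0.78),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}


def region_channels(region: str) -> tuple[str, ...]:
    """Channel labels belonging to a named scalp region."""
    try:
        return REGIONS[region]
    except KeyError:
        raise KeyError(
            f"unknown region {region!r}; known regions: {sorted(REGIONS)}"
        ) from None
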