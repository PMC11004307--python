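"""Electrode montages and the 8-region scalp parcellation.

The analyses in this package operate on eight scalp regions — left/right
frontal (FL/FR), parietal (PL/PR), temporal (TL/TR) and occipital (OL/OR) —
obtained by pooling electrodes of a 10/20-style cap. The canonical 64-channel
assignment used throughout is the table ``MONTAGE64`` below; montages with
other channel counts divide their channels evenly over the same eight regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGIONS: tuple[str, ...] = ("FL", "FR", "PL", "PR", "TL", "TR", "OL", "OR")

# Canonical 64-channel cap: eight 10/10-style electrodes per region.
# Midline sites are split alternately between hemispheric regions so that
# every channel belongs to exactly one region.
MONTAGE64: dict[str, tuple[str, ...]] = {
    "FL": ("Fp1", "AF7", "AF3", "F7", "F5", "F3", "F1", "FC3"),
    "FR": ("Fp2", "AF8", "AF4", "F8", "F6", "F4", "F2", "FC4"),
    "PL": ("FC1", "C1", "C3", "CP1", "CP3", "P1", "P3", "P5"),
    "PR": ("FC2", "C2", "C4", "CP2", "CP4", "P2", "P4", "P6"),
    "TL": ("FT9", "FT7", "FC5", "T7", "C5", "TP7", "CP5", "TP9"),
    "TR": ("FT10", "FT8", "FC6", "T8", "C6", "TP8", "CP6", "TP10"),
    "OL": ("P7", "P9", "PO7", "PO3", "PO5", "O1", "I1", "Oz"),
    "OR": ("P8", "P10", "PO8", "PO4", "PO6", "O2", "I2", "POz"),
}


@dataclass(frozen=True)
class Montage:
    """Channel labels together with their region assignment.

    Parameters
    ----------
    channel_labels : list of str
        One label per channel, in data row order.
    region_of : dict
        Maps every channel label to one of the eight regions in ``REGIONS``.
    """

    channel_labels: tuple[str, ...]
    region_of: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        for ch in self.channel_labels:
            if ch not in self.region_of:
                raise ValueError(f"channel {ch!r} has no region assignment")
            if self.region_of[ch] not in REGIONS:
                raise ValueError(f"unknown region {self.region_of[ch]!r}")
        if self.n_channels >= 8:
            missing = set(REGIONS) - set(self.region_of.values())
            if missing:
                raise ValueError(f"empty regions: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def channels_in(self, region: str) -> list[str]:
        """Labels of the channels pooled into *region*, in montage order."""
        return [c for c in self.channel_labels if self.region_of[c] == region]

    def indices_in(self, region: str) -> list[int]:
        """Row indices of the channels pooled into *region*."""
        return [i for i, c in enumerate(self.channel_labels)
                if self.region_of[c] == region]


def make_montage(n_channels: int = 64) -> Montage:
    """Build the deterministic n-channel montage.

    ``n_channels`` must be at least 8 and divisible by 8 so the channels
    split evenly over the eight regions.  64 channels use the canonical
    ``MONTAGE64`` cap; other sizes get synthetic labels ``"<region><k>"``.
    """
    if n_channels < 8 or n_channels % 8 != 0:
        raise ValueError(
            f"n_channels must be >= 8 and divisible by 8, got {n_channels}")
    per_region = n_channels // 8
    labels: list[str] = []
    region_of: dict[str, str] = {}
    if n_channels == 64:
        for region in REGIONS:
            for ch in MONTAGE64[region]:
                labels.append(ch)
                region_of[ch] = region
    else:
        for region in REGIONS:
            for k in range(per_region):
                ch = f"{region}{k + 1}"
                labels.append(ch)
                region_of[ch] = region
    return Montage(tuple(labels), region_of)
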