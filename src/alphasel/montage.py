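"""64-channel extended 10/20 montage with homologous left/right pairing.

Lateralized analyses (contra/ipsi alpha power, PCN) need to know which
right-hemisphere electrode mirrors which left-hemisphere electrode across
the midline, and which electrodes sit on the midline and therefore carry no
lateralization.  Electrode side follows the 10/20 numbering convention:
odd = left hemisphere, even = right hemisphere, trailing ``z`` = midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Left-hemisphere labels in anterior-to-posterior order; each entry's right
# homologue is obtained by the odd->even digit map below.
_LATERAL_PAIRS: list[tuple[str, str]] = [
    ("Fp1", "Fp2"),
    ("AF7", "AF8"), ("AF3", "AF4"),
    ("F7", "F8"), ("F5", "F6"), ("F3", "F4"), ("F1", "F2"),
    ("FT9", "FT10"), ("FT7", "FT8"),
    ("FC5", "FC6"), ("FC3", "FC4"), ("FC1", "FC2"),
    ("T7", "T8"), ("C5", "C6"), ("C3", "C4"), ("C1", "C2"),
    ("TP7", "TP8"),
    ("CP5", "CP6"), ("CP3", "CP4"), ("CP1", "CP2"),
    ("P7", "P8"), ("P5", "P6"), ("P3", "P4"), ("P1", "P2"),
    ("PO7", "PO8"), ("PO3", "PO4"),
    ("O1", "O2"),
]

_MIDLINE: list[str] = ["Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz", "Iz"]

#: Posterior electrode cluster used for lateralized alpha-power analyses.
POSTERIOR_CLUSTER_PAIRS: list[tuple[str, str]] = [("PO7", "PO8"), ("PO3", "PO4"), ("O1", "O2")]

#: Electrode pair carrying the PCN (posterior contralateral negativity).
PCN_PAIR: tuple[str, str] = ("PO7", "PO8")


@dataclass(frozen=True)
class Montage:
    """Channel labels partitioned into homologous lateral pairs and midline."""

    channel_names: list[str]
    lateral_pairs: list[tuple[str, str]]
    midline: list[str]
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        paired = [ch for pair in self.lateral_pairs for ch in pair]
        covered = set(paired) | set(self.midline)
        if len(paired) + len(self.midline) != len(self.channel_names) or covered != set(
            self.channel_names
        ):
            raise ValueError(
                "every channel must appear in exactly one of lateral_pairs or midline"
            )
        object.__setattr__(
            self, "_index", {ch: i for i, ch in enumerate(self.channel_names)}
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, channel: str) -> int:
        """Position of ``channel`` in ``channel_names``."""
        try:
            return self._index[channel]
        except KeyError:
            raise KeyError(f"channel {channel!r} not in montage") from None

    def homologue(self, channel: str) -> str | None:
        """The mirror electrode across the midline, or None for midline sites."""
        for left, right in self.lateral_pairs:
            if channel == left:
                return right
            if channel == right:
                return left
        if channel in self.midline:
            return None
        raise KeyError(f"channel {channel!r} not in montage")

    def hemisphere(self, channel: str) -> str:
        """'left', 'right' or 'midline' for a montage channel."""
        for left, right in self.lateral_pairs:
            if channel == left:
                return "left"
            if channel == right:
                return "right"
        if channel in self.midline:
            return "midline"
        raise KeyError(f"channel {channel!r} not in montage")


def make_montage() -> Montage:
    """Build the 64-channel extended 10/20 montage used throughout the package.

    Returns a montage with 27 homologous left/right pairs and 10 midline
    electrodes, including the posterior sites PO7/PO8, PO3/PO4 and O1/O2 on
    which the lateralized analyses operate.
    """
    names: list[str] = []
    for left, right in _LATERAL_PAIRS:
        names.extend([left, right])
    names.extend(_MIDLINE)
    return Montage(channel_names=names, lateral_pairs=list(_LATERAL_PAIRS), midline=list(_MIDLINE))


def posterior_channels(montage: Montage) -> list[str]:
    """Parieto-occipital channels (P*, PO*, O*, Iz) carrying ongoing alpha."""
    out = []
    for ch in montage.channel_names:
        stem = ch.rstrip("0123456789z")
        if stem in {"P", "PO", "O", "I"}:
            out.append(ch)
    return out
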