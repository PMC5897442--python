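"""Electrode geometry, channel subsets, and Laplacian spatial filters.

The 64-channel layout is an idealized 10-10 grid on an azimuthal-equidistant
projection of the scalp: the vertex (Cz) sits at the origin, the head rim
(nasion/inion/preauricular level) at radius 1, and the standard 10%
circumference ring (Fpz, F7, T7, ..., Oz) at radius 0.8.  Only relative
distances matter downstream (source mixing, neighbor stencils, topography),
so this idealized geometry is used instead of digitized head coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "SpatialFilterMatrix",
    "standard_layout",
    "small_montage",
    "large_montage",
    "build_laplacian",
    "large_laplacian_matrix",
    "LAPLACIAN_STENCILS",
    "read_layout",
    "write_layout",
]

# Row letter -> anterior-posterior grid step (front positive), 18 deg each.
_ROW_STEP = {
    "Fp": 4, "AF": 3, "F": 2, "FC": 1, "FT": 1, "C": 0, "T": 0,
    "CP": -1, "TP": -1, "P": -2, "PO": -3, "O": -4,
}

# Azimuth (degrees, CCW from +x = right ear) of left-hemisphere electrodes on
# the 10% circumference ring; right hemisphere mirrors about the y axis.
_RIM_AZIMUTH_LEFT = {
    "Fp": 108.0, "AF": 126.0, "F": 144.0, "FT": 162.0, "T": 180.0,
    "TP": 198.0, "P": 216.0, "PO": 234.0, "O": 252.0,
}

_RIM_RADIUS = 0.8  # circumference ring on the unit-head projection

# 64 labels, front to back, left to right.
STANDARD_64 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
    "Iz",
]

# Interior 40-channel set used by the multichannel (CSP/L) pipeline: the full
# F/FC/C/CP rows plus P3/Pz/P4 and POz.  The cap periphery (fronto-polar,
# antero-frontal, lateral parietal, parieto-occipital and occipital rows) is
# excluded to avoid facial/neck muscle artifacts.  Overridable constant.
LARGE_40 = [
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P3", "Pz", "P4",
    "POz",
]

# Large-Laplacian (next-nearest-neighbor) stencils for the hand-area channels.
# Their union is the 9-channel small montage.
LAPLACIAN_STENCILS = {
    "C3": ["F3", "T7", "P3", "Cz"],
    "C4": ["F4", "T8", "P4", "Cz"],
}


@dataclass
class ElectrodeLayout:
    """Named scalp electrodes with 2-D positions on the unit head disc."""

    names: list[str]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.names), 2):
            raise ValueError("positions must be (n_channels, 2)")
        if np.any(np.linalg.norm(self.positions, axis=1) > 1.0 + 1e-9):
            raise ValueError("all positions must lie within the unit disc")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in layout") from None

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]

    def subset(self, names: list[str]) -> "ElectrodeLayout":
        idx = [self.index(n) for n in names]
        return ElectrodeLayout(list(names), self.positions[idx])

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class SpatialFilterMatrix:
    """Linear spatial filter: rows are output components, columns channels."""

    weights: np.ndarray  # (n_components, n_channels)
    in_channels: list[str]
    out_labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.weights.shape != (len(self.out_labels), len(self.in_channels)):
            raise ValueError("weights shape must be (out_labels, in_channels)")

    def apply(self, samples: np.ndarray, channel_names: list[str]) -> np.ndarray:
        """Apply to a (channels, time) array given its channel ordering."""
        idx = []
        for ch in self.in_channels:
            try:
                idx.append(channel_names.index(ch))
            except ValueError:
                raise KeyError(f"channel {ch!r} required by filter but absent") from None
        return self.weights @ samples[idx]


def _label_position(label: str) -> tuple[float, float]:
    """Idealized azimuthal-equidistant 2-D position of a 10-10 label."""
    if label == "Iz":
        return (0.0, -1.0)
    # split row letters / column designator
    i = 0
    while i < len(label) and not (label[i].isdigit() or label[i] == "z"):
        i += 1
    row, col = label[:i], label[i:]
    a = _ROW_STEP[row]
    midline = np.array([0.0, 0.2 * abs(a) * np.sign(a)])
    if col == "z":
        return tuple(midline)
    num = int(col)
    left = num % 2 == 1
    # rim endpoint of this row's coronal arc
    base_row = {"FC": "FT", "C": "T", "CP": "TP"}.get(row, row)
    az = np.deg2rad(_RIM_AZIMUTH_LEFT[base_row])
    rim = _RIM_RADIUS * np.array([np.cos(az), np.sin(az)])
    if not left:
        rim = rim * np.array([-1.0, 1.0])
    # lateral grid step: odd labels 1,3,5,7 sit at 1..4 steps of 4 toward rim;
    # rim electrodes themselves (7/8 on full rows, Fp1/2, O1/2) are handled by
    # their fraction reaching 1.
    frac = ((num + 1) // 2) / 4.0
    if row in ("Fp", "O"):
        frac = 1.0  # only rim electrodes exist on these rows
    pos = (1.0 - frac) * midline + frac * rim
    return (float(pos[0]), float(pos[1]))


def standard_layout(n_channels: int = 64) -> ElectrodeLayout:
    """The 64-channel 10-10 template layout.

    Only the 64-channel template is supported; other counts raise.
    """
    if n_channels != 64:
        raise ValueError(f"unsupported layout: {n_channels} channels (only 64)")
    pos = np.array([_label_position(l) for l in STANDARD_64])
    return ElectrodeLayout(list(STANDARD_64), pos)


def small_montage(layout: ElectrodeLayout) -> list[str]:
    """The 9-channel montage: union of the C3 and C4 large-Laplacian stencils."""
    labels = ["C3", "C4", "Cz", "F3", "F4", "T7", "T8", "P3", "P4"]
    for lab in labels:
        if lab not in layout.names:
            raise ValueError(f"layout is missing required channel {lab!r}")
    return labels


def large_montage(layout: ElectrodeLayout) -> list[str]:
    """The 40-channel interior montage used by the multichannel pipeline."""
    for lab in LARGE_40:
        if lab not in layout.names:
            raise ValueError(f"layout is missing required channel {lab!r}")
    return list(LARGE_40)


def build_laplacian(
    layout: ElectrodeLayout, center: str, neighbors: list[str]
) -> SpatialFilterMatrix:
    """Single-row Laplacian: +1 at center, -1/k at each of k neighbors."""
    if not neighbors:
        raise ValueError("neighbors must be non-empty")
    if center in neighbors:
        raise ValueError(f"center {center!r} cannot be its own neighbor")
    for lab in [center, *neighbors]:
        layout.index(lab)  # raises KeyError if absent
    chans = [center, *neighbors]
    w = np.zeros((1, len(chans)))
    w[0, 0] = 1.0
    w[0, 1:] = -1.0 / len(neighbors)
    return SpatialFilterMatrix(w, chans, [f"LAP-{center}"])


def large_laplacian_matrix(
    layout: ElectrodeLayout,
    channels: list[str] | None = None,
    target_dist: float = 0.4,
    dist_band: tuple[float, float] = (0.3, 0.5),
    max_neighbors: int = 4,
) -> SpatialFilterMatrix:
    """Large-Laplacian re-referencing for every channel of a montage.

    For each channel the (up to 4) neighbors closest to the next-nearest-
    neighbor ring distance (0.4 grid units, i.e. two 10-10 steps) are
    subtracted as a mean.  Channels with no neighbor in the distance band are
    left unreferenced (identity row) — these are rim channels where a large
    Laplacian is not defined.  The hand-area channels C3/C4 use the canonical
    stencils (F3/T7/P3/Cz and F4/T8/P4/Cz) when those neighbors are present.
    """
    if channels is None:
        channels = list(layout.names)
    sub = layout.subset(channels)
    d = np.linalg.norm(sub.positions[:, None] - sub.positions[None, :], axis=2)
    n = len(channels)
    w = np.eye(n)
    for i in range(n):
        stencil = LAPLACIAN_STENCILS.get(channels[i])
        if stencil is not None and all(s in channels for s in stencil):
            nb = [channels.index(s) for s in stencil]
            w[i, nb] = -1.0 / len(nb)
            continue
        cand = [
            (abs(d[i, j] - target_dist), j)
            for j in range(n)
            if j != i and dist_band[0] <= d[i, j] <= dist_band[1]
        ]
        cand.sort()
        nb = [j for _, j in cand[:max_neighbors]]
        if nb:
            w[i, nb] = -1.0 / len(nb)
    return SpatialFilterMatrix(w, list(channels), [f"LAP-{c}" for c in channels])


def write_layout(layout: ElectrodeLayout, path) -> None:
    """Plain-text montage table: label, x, y (tab separated)."""
    with open(path, "w") as fh:
        fh.write("label\tx\ty\n")
        for name, (x, y) in zip(layout.names, layout.positions):
            fh.write(f"{name}\t{x:.6f}\t{y:.6f}\n")


def read_layout(path) -> ElectrodeLayout:
    names, pos = [], []
    with open(path) as fh:
        header = fh.readline()
        if header.split() != ["label", "x", "y"]:
            raise ValueError("montage table must have header 'label x y'")
        for line in fh:
            lab, x, y = line.split()
            names.append(lab)
            pos.append((float(x), float(y)))
    return ElectrodeLayout(names, np.array(pos))
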