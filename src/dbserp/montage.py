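"""Electrode montages and the nine-ROI scalp parcellation.

The study's sensor nets are proprietary geodesic layouts; the montages built
here are synthetic stand-ins: channels are spread quasi-uniformly over the
upper hemisphere with a Fibonacci lattice and named E1..En in the geodesic-net
style.  They carry the geometric structure the pipeline needs (unique 3-D
positions, a left/medial/right x frontal/fronto-central/occipito-parietal
parcellation, a well-defined occipital electrode) without reproducing any
vendor coordinate file.
"""

from __future__ import annotations

import numpy as np

from .core import Montage, ROI_NAMES, ValidationError

# Anterior/posterior row boundaries and lateral column boundaries, in unit-sphere
# coordinates (+y anterior, +x right).  Chosen so both the 64- and 128-channel
# lattices populate all nine ROIs.
_Y_FRONTAL = 0.40
_Y_POSTERIOR = -0.25
_X_LATERAL = 0.30


def make_montage(n_channels: int) -> Montage:
    """Build a synthetic geodesic-style montage with ``n_channels`` electrodes.

    Channels sit on the unit sphere with z >= 0 (scalp above the equator),
    generated by a Fibonacci lattice so that spacing is quasi-uniform.
    """
    if n_channels < 9:
        raise ValidationError("need at least 9 channels to populate 9 ROIs")
    golden = (1.0 + 5.0**0.5) / 2.0
    i = np.arange(n_channels)
    # z from just above the equator to the vertex
    z = 0.02 + (1.0 - 0.02) * (i + 0.5) / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = 2.0 * np.pi * i / golden
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    names = [f"E{k + 1}" for k in range(n_channels)]
    positions = {n: (float(xi), float(yi), float(zi)) for n, xi, yi, zi in zip(names, x, y, z)}
    montage = Montage(
        positions=positions,
        montage_id=f"EGI{n_channels}",
    )
    montage.roi_map = default_roi_map(montage)
    montage.validate_rois()
    return montage


def default_roi_map(montage: Montage) -> dict[str, list[str]]:
    """Partition channels into the nine ROIs by scalp position.

    Rows (anterior->posterior): frontal, fronto-central, occipito-parietal;
    columns: left (x < -0.3), medial (|x| <= 0.3), right (x > 0.3).
    """
    roi_map: dict[str, list[str]] = {name: [] for name in ROI_NAMES}
    for name, (x, y, _z) in montage.positions.items():
        if y > _Y_FRONTAL:
            row = "frontal"
        elif y > _Y_POSTERIOR:
            row = "fronto_central"
        else:
            row = "occipital_parietal"
        if x < -_X_LATERAL:
            col = "left"
        elif x > _X_LATERAL:
            col = "right"
        else:
            col = "medial"
        roi_map[f"{col}_{row}"].append(name)
    return roi_map


def occipital_channel(montage: Montage) -> str:
    """The single most occipital midline electrode (the net's Oz analogue)."""
    best, best_score = None, -np.inf
    for name, (x, y, _z) in montage.positions.items():
        score = -y - abs(x)  # posterior and close to the midline
        if score > best_score:
            best, best_score = name, score
    assert best is not None
    return best


def roi_centroid(montage: Montage, roi: str) -> np.ndarray:
    pos = montage.position_array(montage.roi_map[roi])
    return pos.mean(axis=0)


def save_sfp(montage: Montage, path) -> None:
    """Write positions as whitespace-separated ``name x y z`` lines."""
    with open(path, "w") as fh:
        for name, (x, y, z) in montage.positions.items():
            fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def load_sfp(path, montage_id: str = "custom") -> Montage:
    """Read a ``name x y z`` position file; the ROI map is rebuilt by position."""
    positions: dict[str, tuple[float, float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 'name x y z'")
            name = parts[0]
            try:
                xyz = tuple(float(p) for p in parts[1:])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad coordinate") from exc
            positions[name] = xyz  # type: ignore[assignment]
    montage = Montage(positions=positions, montage_id=montage_id)
    montage.roi_map = default_roi_map(montage)
    return montage
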