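"""Scanner-resolution and partial-volume arithmetic.

Small helpers documenting why regional quantification at this scanner
resolution is safe from partial-volume effects: the smallest analysed
region must exceed the effective scanner sample volume by a large factor.
"""

from __future__ import annotations

#: Effective reconstructed resolution of the scanner, mm (x, y, z).
EFFECTIVE_RESOLUTION_MM = (1.1, 1.1, 1.2)

#: Conventional partial-volume safety factor, in effective-resolution voxels.
PARTIAL_VOLUME_FACTOR = 5

#: Volume of the smallest analysed region (fornix), mm^3.
SMALLEST_REGION_VOLUME_MM3 = 178.0


def effective_sample_volume(resolution_mm=EFFECTIVE_RESOLUTION_MM) -> float:
    """Effective scanner sample volume in mm^3 (product of the resolution)."""
    x, y, z = resolution_mm
    if min(x, y, z) <= 0:
        raise ValueError("resolution components must be positive")
    return x * y * z


def partial_volume_limit(
    n_voxels: int = PARTIAL_VOLUME_FACTOR, resolution_mm=EFFECTIVE_RESOLUTION_MM
) -> float:
    """Smallest resolvable effective volume (mm^3) at a partial-volume
    factor of ``n_voxels`` effective-resolution voxels."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    return n_voxels * effective_sample_volume(resolution_mm)


def region_volume_ratio(
    region_volume_mm3: float = SMALLEST_REGION_VOLUME_MM3,
    resolution_mm=EFFECTIVE_RESOLUTION_MM,
) -> float:
    """How many effective sample volumes fit in a region (>= ~123 for the
    fornix, the smallest region analysed)."""
    if region_volume_mm3 <= 0:
        raise ValueError("region volume must be positive")
    return region_volume_mm3 / effective_sample_volume(resolution_mm)
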