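"""Beer-Lambert stain separation for Masson's trichrome images.

Masson's trichrome combines three dyes: hematoxylin (nuclei), Biebrich
scarlet / acid fuchsin (cytoplasm and young matrix, red) and aniline blue
(mature collagen, blue).  Under the Beer-Lambert model the optical density
of a pixel is a non-negative linear combination of per-stain unit OD
vectors, so stain densities are recovered by inverting a 3x3 stain matrix
in OD space (Ruifrok-Johnston color deconvolution).  This module provides
the forward model (densities -> RGB), the inverse (RGB -> densities) and a
fixed density -> 8-bit grayscale mapping used by the texture panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "DensityChannels",
    "MASSON_TRICHROME",
    "rgb_to_od",
    "od_to_density",
    "density_to_rgb",
    "density_to_gray",
]

#: Default full-scale density used when mapping OD densities to 8-bit gray.
D_MAX_DEFAULT = 2.0

#: Maximum tolerated condition number for a stain matrix.
_COND_LIMIT = 1e8


class StainMatrixError(ValueError):
    """Raised for singular or otherwise invalid stain matrices."""


@dataclass(frozen=True)
class StainMatrix:
    """Unit OD vectors for a three-stain model.

    Parameters
    ----------
    vectors : (3, 3) array
        One row per stain, columns are (R, G, B) optical-density
        components.  Rows are normalized to unit Euclidean norm.
    names : tuple of str
        Stain names in row order.
    i0 : (3,) array
        Background (unstained) intensity per RGB channel, default 255.
    """

    vectors: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "aniline_blue", "biebrich_scarlet")
    i0: np.ndarray = field(default_factory=lambda: np.full(3, 255.0))

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise StainMatrixError(f"stain matrix must be 3x3, got {v.shape}")
        if np.any(v < 0):
            raise StainMatrixError("stain OD components must be non-negative")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise StainMatrixError("stain vector with zero norm")
        v = v / norms[:, None]
        if np.linalg.cond(v) > _COND_LIMIT:
            raise StainMatrixError("stain matrix is singular or ill-conditioned")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "i0", np.asarray(self.i0, dtype=float).reshape(3))

    @property
    def inverse(self) -> np.ndarray:
        """Inverse of the mixing matrix V^T (od = V^T @ densities)."""
        return np.linalg.inv(self.vectors.T)

    def index(self, name: str) -> int:
        return self.names.index(name)


def _masson_preset() -> StainMatrix:
    # Documented package preset: OD vectors for hematoxylin, aniline blue
    # and Biebrich scarlet/acid fuchsin, normalized on construction.
    # Chosen so each stain renders its expected hue while the matrix stays
    # well conditioned (cond ~ 12), keeping deconvolution noise
    # amplification of 8-bit quantization small.
    return StainMatrix(
        vectors=np.array(
            [
                [0.590, 0.750, 0.300],  # hematoxylin: blue-purple nuclei
                [0.870, 0.460, 0.170],  # aniline blue: absorbs mostly red
                [0.100, 0.740, 0.670],  # Biebrich scarlet: absorbs green/blue
            ]
        )
    )


MASSON_TRICHROME: StainMatrix = _masson_preset()


@dataclass
class DensityChannels:
    """Per-pixel stain-density images (OD units) plus provenance.

    The blue (aniline blue) and red (Biebrich scarlet) channels feed the
    texture panel; the hematoxylin channel is retained for completeness
    but not analyzed.
    """

    blue: np.ndarray
    red: np.ndarray
    hematoxylin: np.ndarray
    stain_matrix: StainMatrix = field(default_factory=_masson_preset, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape


def rgb_to_od(tile: np.ndarray, i0: np.ndarray | float = 255.0) -> np.ndarray:
    """Convert an 8-bit RGB tile to optical density.

    OD_c = -log10(max(I_c, 1) / I0_c).  Intensities are clamped to >= 1
    before the log so the OD of a fully dark pixel stays finite
    (log10(255) ~ 2.4065 at the default background).
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB input, got shape {tile.shape}")
    i0 = np.broadcast_to(np.asarray(i0, dtype=float), (3,))
    intensity = np.clip(tile.astype(float), 1.0, None)
    return -np.log10(intensity / i0)


def od_to_density(od: np.ndarray, matrix: StainMatrix = MASSON_TRICHROME) -> DensityChannels:
    """Invert the stain-mixing model: densities = (V^T)^-1 @ od per pixel.

    Negative solutions (noise, off-model colors) are clipped to zero.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected HxWx3 OD input, got shape {od.shape}")
    dens = od @ matrix.inverse.T
    dens = np.clip(dens, 0.0, None)
    return DensityChannels(
        blue=dens[..., matrix.index("aniline_blue")],
        red=dens[..., matrix.index("biebrich_scarlet")],
        hematoxylin=dens[..., matrix.index("hematoxylin")],
        stain_matrix=matrix,
    )


def density_to_rgb(
    densities: np.ndarray | DensityChannels,
    matrix: StainMatrix = MASSON_TRICHROME,
    i0: np.ndarray | float | None = None,
) -> np.ndarray:
    """Forward stain model: I_c = I0_c * 10^-(V^T d)_c, rounded to 8 bits.

    ``densities`` is either an HxWx3 stack in the matrix's stain order or a
    :class:`DensityChannels` (hematoxylin/blue/red re-stacked in order).
    """
    if isinstance(densities, DensityChannels):
        stack = np.zeros(densities.blue.shape + (3,))
        stack[..., matrix.index("hematoxylin")] = densities.hematoxylin
        stack[..., matrix.index("aniline_blue")] = densities.blue
        stack[..., matrix.index("biebrich_scarlet")] = densities.red
        densities = stack
    densities = np.asarray(densities, dtype=float)
    if np.any(densities < 0):
        raise ValueError("stain densities must be non-negative")
    if i0 is None:
        i0 = matrix.i0
    i0 = np.broadcast_to(np.asarray(i0, dtype=float), (3,))
    od = densities @ matrix.vectors  # (V^T d)_c = sum_s d_s v_{s,c}
    rgb = i0 * np.power(10.0, -od)
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)


def density_to_gray(density: np.ndarray, d_max: float = D_MAX_DEFAULT) -> np.ndarray:
    """Map a density image to 8-bit gray on a fixed global scale.

    gray = round(255 * min(d, d_max) / d_max), round-half-up.  The scale is
    deliberately global (not per-image) so mean-intensity features remain
    comparable across tiles.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    d = np.clip(np.asarray(density, dtype=float), 0.0, d_max)
    return np.floor(255.0 * d / d_max + 0.5).astype(np.uint8)
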