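"""Gist perceptual representation: preprocessing, Gabor filter bank, pooled descriptor.

The descriptor summarizes oriented spatial-frequency energy: the image is
convolved with a bank of quadrature Gabor filters (``scales`` octave-spaced
center frequencies x ``orientations`` evenly spaced orientations), the
magnitude of each complex response is averaged within the cells of a coarse
spatial grid, and the cell means are concatenated in fixed
(scale, orientation, cell) order.  With the defaults (4 scales, 8
orientations, 4x4 grid) this yields a 512-dimensional feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

__all__ = [
    "ImageStimulus",
    "GistDescriptor",
    "GaborBank",
    "preprocess",
    "gabor_bank",
    "gist",
]

#: side of a preprocessed image, pixels
IMAGE_SIZE = 256
#: intensity range of preprocessed images
INTENSITY_RANGE = (0.0, 255.0)

# Luma weights (ITU-R BT.709, as used by scikit-image's rgb2gray).
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class ImageStimulus:
    """A labeled grayscale image after standard preprocessing."""

    id: str
    pixels: np.ndarray
    basic_category: str = ""
    superordinate_category: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)


@dataclass
class GistDescriptor:
    """Pooled oriented-energy feature vector for one image."""

    values: np.ndarray
    scale_count: int = 4
    orientation_count: int = 8
    grid: tuple[int, int] = (4, 4)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_cells = self.grid[0] * self.grid[1]
        expected = self.scale_count * self.orientation_count * n_cells
        if self.values.shape != (expected,):
            raise ValueError(
                f"descriptor length {self.values.shape} != "
                f"{self.scale_count} x {self.orientation_count} x {n_cells}"
            )

    def band(self, scale: int, orientation: int) -> np.ndarray:
        """The grid-cell values for one (scale, orientation) band."""
        n_cells = self.grid[0] * self.grid[1]
        start = (scale * self.orientation_count + orientation) * n_cells
        return self.values[start : start + n_cells]


def preprocess(
    image: np.ndarray,
    target_mean: float = 128.0,
    *,
    id: str = "",
    basic_category: str = "",
    superordinate_category: str = "",
    size: int = IMAGE_SIZE,
) -> ImageStimulus:
    """Convert to grayscale, central-square crop, resize, fix mean brightness.

    The brightness normalization is an additive shift to ``target_mean``
    (preserving contrast), with values clipped to the valid intensity range
    and the shift re-applied once after clipping.

    Parameters
    ----------
    image
        2-D grayscale or 3-D (H, W, 3|4) color intensity array, values on the
        0..255 scale.
    target_mean
        Session-constant mean brightness imposed on the output.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D image, got ndim={arr.ndim}")
    if min(arr.shape) < 2:
        raise ValueError(f"degenerate image side in shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite pixel values")
    lo, hi = INTENSITY_RANGE
    if not (lo <= target_mean <= hi):
        raise ValueError(f"target_mean {target_mean} outside [{lo}, {hi}]")

    # central square crop
    h, w = arr.shape
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    arr = arr[r0 : r0 + side, c0 : c0 + side]

    if side != size:
        from skimage.transform import resize

        arr = resize(
            arr,
            (size, size),
            order=1,
            mode="reflect",
            anti_aliasing=side > size,
            preserve_range=True,
        )

    # additive brightness normalization; re-center once after clipping
    arr = np.clip(arr + (target_mean - arr.mean()), lo, hi)
    arr = np.clip(arr + (target_mean - arr.mean()), lo, hi)

    return ImageStimulus(
        id=id,
        pixels=arr,
        basic_category=basic_category,
        superordinate_category=superordinate_category,
    )


def _gabor_kernel(frequency: float, theta: float, sigma: float) -> np.ndarray:
    """Zero-mean complex (quadrature-pair) Gabor kernel.

    The DC component is removed inside the Gaussian window
    (g = w * (carrier - c) with c = sum(w * carrier) / sum(w)), so the
    coefficient sum is exactly zero and the envelope shape is preserved.
    """
    half = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    window = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    carrier = np.exp(2j * np.pi * frequency * (x * np.cos(theta) + y * np.sin(theta)))
    dc = (window * carrier).sum() / window.sum()
    return window * (carrier - dc)


@dataclass
class GaborBank:
    """Bank of ``scales x orientations`` zero-mean quadrature Gabor filters.

    Center frequencies are octave-spaced from ``max_frequency`` downward;
    orientation spacing is pi/orientations.  ``bandwidth_factor`` sets the
    Gaussian envelope via sigma = bandwidth_factor / frequency (the default
    0.56 corresponds to a ~1-octave half-amplitude bandwidth).
    """

    scales: int = 4
    orientations: int = 8
    max_frequency: float = 1.0 / 8.0
    bandwidth_factor: float = 0.56
    kernels: list[list[np.ndarray]] = field(init=False, repr=False)
    frequencies: np.ndarray = field(init=False)
    thetas: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.scales < 1 or self.orientations < 1:
            raise ValueError("scales and orientations must be >= 1")
        self.frequencies = self.max_frequency / (2.0 ** np.arange(self.scales))
        self.thetas = np.pi * np.arange(self.orientations) / self.orientations
        self.kernels = [
            [
                _gabor_kernel(f, t, self.bandwidth_factor / f)
                for t in self.thetas
            ]
            for f in self.frequencies
        ]
        self._spectra_cache: dict[tuple[int, int], np.ndarray] = {}

    def __len__(self) -> int:
        return self.scales * self.orientations

    @property
    def pad(self) -> int:
        """Half-size of the largest kernel (padding needed for convolution)."""
        return max(k.shape[0] // 2 for row in self.kernels for k in row)

    def spectra(self, fft_shape: tuple[int, int]) -> np.ndarray:
        """Stacked kernel FFTs at ``fft_shape`` (complex64, cached)."""
        if fft_shape not in self._spectra_cache:
            out = np.empty((len(self), *fft_shape), dtype=np.complex64)
            i = 0
            for row in self.kernels:
                for k in row:
                    half = k.shape[0] // 2
                    padded = np.zeros(fft_shape, dtype=np.complex64)
                    padded[: k.shape[0], : k.shape[1]] = k
                    # center the kernel at the origin (circular shift)
                    padded = np.roll(padded, (-half, -half), axis=(0, 1))
                    out[i] = scipy.fft.fft2(padded)
                    i += 1
            self._spectra_cache[fft_shape] = out
        return self._spectra_cache[fft_shape]


def gabor_bank(scales: int = 4, orientations: int = 8, **kwargs) -> GaborBank:
    """Build the default filter bank (see :class:`GaborBank`)."""
    return GaborBank(scales=scales, orientations=orientations, **kwargs)


def gist(
    stimulus: ImageStimulus,
    bank: GaborBank | None = None,
    *,
    boundary: str = "symmetric",
    grid: tuple[int, int] = (4, 4),
) -> GistDescriptor:
    """Compute the pooled oriented-energy descriptor of a preprocessed image.

    For each filter the image is convolved (FFT-based, with ``boundary``
    padding: "symmetric" or "wrap"), the complex response magnitude is taken
    (quadrature energy), and magnitudes are averaged within each grid cell.

    Returns a :class:`GistDescriptor` whose values are ordered by
    (scale, orientation, cell), cells in row-major raster order.
    """
    if bank is None:
        bank = gabor_bank()
    img = np.asarray(stimulus.pixels, dtype=np.float32)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(f"expected square preprocessed image, got {img.shape}")
    n = img.shape[0]
    gh, gw = grid
    if n % gh or n % gw:
        raise ValueError(f"grid {grid} does not tile image side {n}")

    pad = bank.pad
    # removing the image mean is a no-op through zero-mean filters but keeps
    # single-precision FFT round-off away from the (large) DC component
    padded = np.pad(img - img.mean(), pad, mode=boundary)
    fast = scipy.fft.next_fast_len(padded.shape[0])
    fft_shape = (fast, fast)
    spec = bank.spectra(fft_shape)

    img_f = scipy.fft.fft2(padded.astype(np.complex64), fft_shape)
    resp = scipy.fft.ifft2(img_f[None, :, :] * spec, axes=(-2, -1))
    energy = np.abs(resp[:, pad : pad + n, pad : pad + n]).astype(np.float64)

    # pool: mean magnitude within each grid cell, row-major cell order
    pooled = energy.reshape(len(bank), gh, n // gh, gw, n // gw).mean(axis=(2, 4))
    values = pooled.reshape(len(bank) * gh * gw)
    return GistDescriptor(
        values=values,
        scale_count=bank.scales,
        orientation_count=bank.orientations,
        grid=grid,
    )
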