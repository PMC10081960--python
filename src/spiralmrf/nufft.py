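"""In-plane non-uniform discrete Fourier transform and density compensation.

The in-plane transform maps an M x M image to samples at arbitrary k-space
coordinates (cycles/FOV on a unit pixel grid, so +-0.5 is Nyquist):

    s(k_q) = sum_r  img(r) * exp(-2*pi*i * k_q . r),

with r the integer pixel offsets from the matrix center.  At desk-scale
matrix sizes this is evaluated exactly as a dense matrix product (BLAS),
which also makes the adjoint exact (the conjugate transpose), so the
operator passes adjoint dot-tests at machine precision.  Gridding-based
approximations would only pay off at much larger problem sizes.

The adjoint reconstruction weights samples by a density-compensation
function (DCF); for a spiral arm the analytic radius-times-arc-length
weights are a good quadrature rule for the sampled disc.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DirectNUFFT", "ndft_matrix", "radial_density_weights"]


def _bilinear(img: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear sampling of a 2D array at fractional indices (clamped)."""
    M, N = img.shape
    x = np.clip(x, 0, M - 1.0 - 1e-9)
    y = np.clip(y, 0, N - 1.0 - 1e-9)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    return (
        img[x0, y0] * (1 - fx) * (1 - fy)
        + img[x0 + 1, y0] * fx * (1 - fy)
        + img[x0, y0 + 1] * (1 - fx) * fy
        + img[x0 + 1, y0 + 1] * fx * fy
    )


def ndft_matrix(coords: np.ndarray, M: int, dtype=np.complex128) -> np.ndarray:
    """Dense forward NDFT matrix of shape ``(Q, M*M)``.

    Pixel positions are integer offsets from the matrix center ``M // 2``,
    row-major with the first image axis varying slowest.
    """
    coords = np.asarray(coords, dtype=float)
    x = np.arange(M) - M // 2
    X, Y = np.meshgrid(x, x, indexing="ij")
    phase = np.outer(coords[:, 0], X.ravel()) + np.outer(coords[:, 1], Y.ravel())
    return np.exp(-2j * np.pi * phase).astype(dtype, copy=False)


def radial_density_weights(coords: np.ndarray, n_arms: int = 1) -> np.ndarray:
    """Analytic DCF for interleaved constant-pitch (Archimedean) spirals.

    The area element of such a trajectory is (arc spacing) x (winding
    gap): the gap between adjacent windings of the interleaved set is the
    constant ``k_max / (turns * n_arms)`` (estimated here from the
    unwrapped azimuth of the first arm), and the along-track spacing
    ``ds_i`` already grows linearly with radius for uniform-parameter
    sampling.  Weights taper linearly inside one winding gap of the
    center, where the converging arms oversample, and are normalized so
    their sum equals the area of the sampled disc, ``pi * k_max^2``.

    ``coords`` may hold ``n_arms`` equal-length arms concatenated; arc
    lengths are computed per arm so joints do not leak into the spacing
    estimate.  For quantitative reconstructions refine these with
    :meth:`DirectNUFFT.density_weights`, which corrects the residual
    low-frequency density error of the analytic rule.
    """
    coords = np.asarray(coords, dtype=float)
    Q = coords.shape[0]
    if Q % n_arms != 0:
        raise ValueError("coords length must be divisible by n_arms")
    arms = coords.reshape(n_arms, Q // n_arms, 2)
    radii = np.linalg.norm(arms, axis=2)
    # central-difference arc length per point, one-sided at arm ends
    diffs = np.linalg.norm(np.diff(arms, axis=1), axis=2)
    ds = np.empty_like(radii)
    ds[:, 1:-1] = 0.5 * (diffs[:, 1:] + diffs[:, :-1])
    ds[:, 0] = diffs[:, 0]
    ds[:, -1] = diffs[:, -1]
    k_max = radii.max()
    phi = np.unwrap(np.arctan2(arms[0, 1:, 1], arms[0, 1:, 0]))
    turns = max((phi[-1] - phi[0]) / (2.0 * np.pi), 0.5)
    gap = k_max / (turns * n_arms)
    w = ds * gap * np.minimum(radii / gap, 1.0)
    w = np.maximum(w, 1e-12 * gap**2)
    w *= np.pi * k_max**2 / w.sum()
    return w.ravel()


class DirectNUFFT:
    """Exact type-2 (forward) / type-1 (adjoint) NDFT for one coordinate set.

    Parameters
    ----------
    coords:
        ``(Q, 2)`` sample coordinates in cycles/FOV.
    M:
        Image matrix size (square).
    dtype:
        ``np.complex128`` (default) or ``np.complex64`` for speed.
    """

    def __init__(self, coords: np.ndarray, M: int, dtype=np.complex128):
        self.coords = np.asarray(coords, dtype=float)
        self.M = int(M)
        self.dtype = np.dtype(dtype)
        self._mat = ndft_matrix(self.coords, self.M, dtype)

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    def forward(self, img: np.ndarray) -> np.ndarray:
        """Sample image(s) at the non-uniform coordinates.

        ``img`` has shape ``(M, M, ...)``; returns ``(Q, ...)``.
        """
        if img.shape[:2] != (self.M, self.M):
            raise ValueError(f"image must start with shape ({self.M}, {self.M})")
        flat = img.reshape(self.M * self.M, -1).astype(self.dtype, copy=False)
        out = self._mat @ flat
        return out.reshape((self.n_samples,) + img.shape[2:])

    def density_weights(self, n_arms: int = 1, n_refine: int = 3) -> np.ndarray:
        """Density-compensation weights for this trajectory.

        Starts from the analytic spiral rule
        (:func:`radial_density_weights`) and applies ``n_refine`` rounds of
        gridded-density correction: the weighted sampling function is
        gridded onto the image matrix, Fourier-transformed to the actual
        spectral density, and each sample's weight is divided by that
        density at its own location.  This removes the residual
        low-spatial-frequency error (e.g. double-counted arm origins near
        the k-space center) that a purely geometric rule leaves behind.
        """
        w = radial_density_weights(self.coords, n_arms=n_arms)
        M = self.M
        for _ in range(n_refine):
            psf = self.adjoint(w.astype(self.dtype))
            spec = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(psf))))
            idx = self.coords * M + M // 2
            dens = _bilinear(spec, idx[:, 0], idx[:, 1])
            w = w / np.maximum(dens, 1e-8)
            w *= np.pi * np.linalg.norm(self.coords, axis=1).max() ** 2 / w.sum()
        return w

    def adjoint(self, samples: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        """Adjoint transform, optionally density-compensated.

        Without ``weights`` this is the exact adjoint of :meth:`forward`
        (conjugate-transpose); with DCF weights it approximates the inverse
        for fully sampled trajectories.  ``samples`` has shape ``(Q, ...)``;
        returns ``(M, M, ...)``.
        """
        if samples.shape[0] != self.n_samples:
            raise ValueError("sample count mismatch")
        flat = samples.reshape(self.n_samples, -1).astype(self.dtype, copy=False)
        if weights is not None:
            flat = flat * np.asarray(weights, dtype=self.dtype)[:, None]
        out = self._mat.conj().T @ flat
        return out.reshape((self.M, self.M) + samples.shape[1:])
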