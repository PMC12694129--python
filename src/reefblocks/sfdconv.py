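"""Stochastic Fourier dynamic downsampling convolution.

The downsampling kernel is synthesized per input sample as the inverse FFT
of an alpha-weighted sum of K learnable low-frequency basis spectra,
supported on the central 8x8 block of a 16x16 frequency grid (64 active
coordinates).  Because a real kernel needs a Hermitian spectrum, the
synthesized spectrum is symmetrized before inversion; the 16x16 spatial map
is fftshift-centered, cropped to a 4x4 stride-2 kernel, and normalized by
its absolute sum.  The kernel is applied depthwise (one kernel per sample,
shared across channels) followed by a pointwise 1x1 channel-mixing
convolution.

alpha is a softmax of i.i.d. standard-normal logits per sample during
training, and the fixed uniform vector (1/K, ..., 1/K) at evaluation so that
inference is deterministic; a content-conditioned alpha head is available as
a configuration switch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConfigurationError
from .nn import Conv2d, Linear, Module, Parameter, Tensor, functional as F

__all__ = ["SFDConvConfig", "SFDConv", "omega_low_coords",
           "synthesize_spectrum", "spectrum_to_kernel"]


@dataclasses.dataclass(frozen=True)
class SFDConvConfig:
    K: int = 16
    omega_block: int = 8
    spectrum_size: int = 16
    kernel_size: int = 4
    stride: int = 2
    alpha_mode: str = "random"  # "random" or "content"

    def validate(self):
        if self.K < 1 or self.stride < 1:
            raise ConfigurationError("K and stride must be >= 1")
        if self.omega_block > self.spectrum_size:
            raise ConfigurationError("omega block must fit inside the spectrum grid")
        if self.alpha_mode not in ("random", "content"):
            raise ConfigurationError(f"unknown alpha_mode {self.alpha_mode!r}")

    @property
    def n_freq(self) -> int:
        return self.omega_block**2


def omega_low_coords(cfg: SFDConvConfig) -> np.ndarray:
    """(N_f, 2) array of (u, v) coordinates, standard FFT layout, that form
    the central omega_block x omega_block square after fftshift."""
    s, b = cfg.spectrum_size, cfg.omega_block
    lo = s // 2 - b // 2
    shifted = [(i, j) for i in range(lo, lo + b) for j in range(lo, lo + b)]
    # undo the fftshift: shifted index i corresponds to frequency i - s//2
    return np.array([((i - s // 2) % s, (j - s // 2) % s) for i, j in shifted])


def synthesize_spectrum(alpha: np.ndarray, w_freq: np.ndarray,
                        cfg: SFDConvConfig) -> np.ndarray:
    """Complex (S, S) spectrum: alpha-weighted basis sum on the low-frequency
    support, zero elsewhere, Hermitian-symmetrized for a real kernel.

    alpha: (K,); w_freq: (K, N_f, 2) real/imaginary pairs.
    """
    cfg.validate()
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (cfg.K,):
        raise ConfigurationError(f"alpha must have length K={cfg.K}")
    s = cfg.spectrum_size
    coords = omega_low_coords(cfg)
    vals = np.tensordot(alpha, w_freq, axes=(0, 0))  # (N_f, 2)
    spec = np.zeros((s, s), dtype=complex)
    spec[coords[:, 0], coords[:, 1]] = vals[:, 0] + 1j * vals[:, 1]
    conj_flip = np.conj(spec[(-np.arange(s)) % s][:, (-np.arange(s)) % s])
    return 0.5 * (spec + conj_flip)


def spectrum_to_kernel(spectrum: np.ndarray, cfg: SFDConvConfig | None = None
                       ) -> np.ndarray:
    """Inverse FFT of a (Hermitian) spectrum; the imaginary residue must be
    below 1e-6 and is discarded.  Returns the full (S, S) real spatial map."""
    spatial = np.fft.ifft2(spectrum)
    resid = np.abs(spatial.imag).max()
    if resid > 1e-6:
        raise ConfigurationError(
            f"spectrum is not Hermitian (imaginary residue {resid:.2e})")
    return spatial.real


def _synthesis_matrix(cfg: SFDConvConfig) -> np.ndarray:
    """Linear map from the (N_f*2,) real coefficient vector of a spectrum to
    the fftshift-centered, cropped (k*k,) spatial kernel.  Built column by
    column through the reference synthesis path."""
    nf, s, k = cfg.n_freq, cfg.spectrum_size, cfg.kernel_size
    coords = omega_low_coords(cfg)
    lo = s // 2 - k // 2
    cols = []
    for idx in range(nf * 2):
        vals = np.zeros((nf, 2))
        vals[idx // 2, idx % 2] = 1.0
        spec = np.zeros((s, s), dtype=complex)
        spec[coords[:, 0], coords[:, 1]] = vals[:, 0] + 1j * vals[:, 1]
        conj_flip = np.conj(spec[(-np.arange(s)) % s][:, (-np.arange(s)) % s])
        spatial = np.fft.ifft2(0.5 * (spec + conj_flip)).real
        centered = np.fft.fftshift(spatial)
        cols.append(centered[lo:lo + k, lo:lo + k].ravel())
    return np.stack(cols, axis=1).astype(np.float32)  # (k*k, N_f*2)


class SFDConv(Module):
    """Dynamic downsampling: per-sample Fourier-synthesized depthwise kernel
    followed by a pointwise channel-mixing convolution."""

    def __init__(self, cin: int, cout: int, cfg: SFDConvConfig | None = None, *,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg or SFDConvConfig()
        self.cfg.validate()
        nf = self.cfg.n_freq
        self.w_freq = Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(nf), size=(self.cfg.K, nf * 2)))
        self._syn = _synthesis_matrix(self.cfg)  # fixed (k*k, N_f*2)
        self.pointwise = Conv2d(cin, cout, k=1, rng=rng)
        if self.cfg.alpha_mode == "content":
            self.alpha_head = Linear(cin, self.cfg.K, rng=rng)

    def sample_alpha(self, x: Tensor, rng: np.random.Generator | None):
        b = x.shape[0]
        if self.cfg.alpha_mode == "content":
            ctx = x.mean(axis=(2, 3))
            return F.softmax(self.alpha_head(ctx), axis=-1)
        if self.training:
            if rng is None:
                raise ConfigurationError("training-mode SFDConv requires an rng")
            logits = rng.standard_normal((b, self.cfg.K))
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            return Tensor((e / e.sum(axis=1, keepdims=True)).astype(np.float32))
        return Tensor(np.full((b, self.cfg.K), 1.0 / self.cfg.K, dtype=np.float32))

    def kernels_for_alpha(self, alpha: Tensor) -> Tensor:
        """(B, k, k) normalized spatial kernels, differentiable in the basis."""
        k = self.cfg.kernel_size
        mix = alpha @ self.w_freq  # (B, N_f*2)
        flat = mix @ Tensor(self._syn.T)  # (B, k*k)
        kern = flat.reshape(flat.shape[0], k, k)
        norm = F.abs_(kern).sum(axis=(1, 2), keepdims=True) + 1e-6
        return kern / norm

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        b, c, h, w = x.shape
        if h % 2:  # right/bottom zero pad to even spatial dims
            x = F.concatenate([x, Tensor(np.zeros((b, c, 1, w), dtype=np.float32))], axis=2)
            h += 1
        if w % 2:
            x = F.concatenate([x, Tensor(np.zeros((b, c, h, 1), dtype=np.float32))], axis=3)
        alpha = self.sample_alpha(x, rng)
        kernels = self.kernels_for_alpha(alpha)
        pad = (self.cfg.kernel_size - self.cfg.stride) // 2
        y = F.depthwise_persample_conv2d(x, kernels, stride=self.cfg.stride,
                                         padding=pad)
        return self.pointwise(y)
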