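"""Decoder-encoder swap: turning Gaussian noise into informative noise.

After the VAE is trained its two halves are applied in reverse order:
a standard-normal draw z is pushed through the decoder to an image-like
reconstruction x~, and x~ is re-encoded to z~, the posterior mean.  The
resulting vectors live on (a Gaussian-smoothed image of) the latent
manifold the VAE learned, rather than being isotropic noise — they are
the "informative noise" a downstream GAN samples instead of N(0, I).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

__all__ = ["NoiseBatch", "informative_noise", "noise_source", "NoiseStream"]


@dataclass
class NoiseBatch:
    """n x d matrix of informative-noise vectors with provenance."""

    vectors: np.ndarray
    provenance_seed: Optional[int] = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError(f"need an n x d matrix with n >= 1, got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("noise vectors must be finite")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def save(self, path) -> None:
        np.savez_compressed(path, vectors=self.vectors,
                            provenance_seed=np.int64(self.provenance_seed or -1))

    @classmethod
    def load(cls, path) -> "NoiseBatch":
        with np.load(path) as data:
            seed = int(data["provenance_seed"])
            return cls(data["vectors"], None if seed < 0 else seed)


def _swap_once(vae, z: np.ndarray) -> np.ndarray:
    """z -> decode -> x~ -> encode -> posterior mean z~."""
    x_tilde = vae.decode(z)
    mu, _ = vae.encode(x_tilde)
    return mu


def informative_noise(vae, n: int, rng=None, sample_posterior: bool = False) -> NoiseBatch:
    """Draw ``n`` informative-noise vectors from a (trained) VAE.

    Each row: z ~ N(0, I_d), x~ = decode(z), z~ = encoder posterior mean
    of x~ (or a reparameterized sample when ``sample_posterior``).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    z = rng.standard_normal((n, vae.latent_dim))
    if sample_posterior:
        mu, log_var = vae.encode(vae.decode(z))
        out = vae.reparameterize(mu, log_var, rng)
    else:
        out = _swap_once(vae, z)
    return NoiseBatch(out, provenance_seed=seed)


class NoiseStream:
    """Inexhaustible seeded stream of noise vectors.

    ``mode='gaussian'`` emits raw N(0, I_d) draws (the baseline-GAN
    ablation); ``mode='informative'`` pushes each draw through the
    decoder-encoder swap.  Vectors are produced in chunks internally but
    the stream is consumed per vector or per batch.
    """

    def __init__(self, dim: int, mode: str = "gaussian", vae=None,
                 rng=None, chunk: int = 256):
        if mode not in ("gaussian", "informative"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "informative" and vae is None:
            raise ValueError("informative mode needs a VAE (or decode/encode stub)")
        self.dim = dim
        self.mode = mode
        self.vae = vae
        self.rng = np.random.default_rng(rng)
        self.chunk = chunk
        self._buffer = np.empty((0, dim))

    def _refill(self, at_least: int) -> None:
        need = max(at_least - self._buffer.shape[0], self.chunk)
        z = self.rng.standard_normal((need, self.dim))
        if self.mode == "informative":
            z = _swap_once(self.vae, z)
        self._buffer = np.concatenate([self._buffer, z], axis=0)

    def next_batch(self, n: int) -> np.ndarray:
        if n < 1:
            raise ValueError("batch size must be >= 1")
        if self._buffer.shape[0] < n:
            self._refill(n)
        out, self._buffer = self._buffer[:n], self._buffer[n:]
        return out

    def __iter__(self) -> Iterator[np.ndarray]:
        return self

    def __next__(self) -> np.ndarray:
        return self.next_batch(1)[0]


def noise_source(vae, mode: str = "informative", rng=None, dim: Optional[int] = None) -> NoiseStream:
    """Seeded stream of generator input noise.

    ``informative`` streams decoder-encoder swapped vectors from ``vae``;
    ``gaussian`` ignores the VAE weights and streams N(0, I_d).
    """
    if dim is None:
        if vae is None:
            raise ValueError("need a VAE or an explicit dim")
        dim = vae.latent_dim
    return NoiseStream(dim, mode=mode, vae=vae if mode == "informative" else None, rng=rng)
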