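"""Correlated pre/post measurement pairs from a bivariate normal model."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = ["BivariateSpec", "PairedSample", "sample_bivariate"]


@dataclass(frozen=True)
class BivariateSpec:
    """Parameters (mu_x, mu_y, sigma_x, sigma_y, rho) of the bivariate normal."""

    mu_pre: float
    mu_post: float
    sd_pre: float
    sd_post: float
    rho: float

    def __post_init__(self) -> None:
        if self.sd_pre <= 0 or self.sd_post <= 0:
            raise ValueError("standard deviations must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1 (positive-definite covariance)")

    @property
    def diff_mean(self) -> float:
        """Mean of post - pre."""
        return self.mu_post - self.mu_pre

    @property
    def diff_sd(self) -> float:
        """SD of post - pre: sqrt(sx^2 + sy^2 - 2 rho sx sy)."""
        return float(
            np.sqrt(
                self.sd_pre**2 + self.sd_post**2 - 2 * self.rho * self.sd_pre * self.sd_post
            )
        )


@dataclass(frozen=True)
class PairedSample:
    """n independent (pre, post) draws."""

    pre: np.ndarray
    post: np.ndarray
    n: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.pre) != self.n or len(self.post) != self.n:
            raise ValueError("pre and post must both have length n")

    def summary(self) -> dict:
        """Sample moments of each margin and the sample correlation."""
        return {
            "n": self.n,
            "pre_mean": float(self.pre.mean()),
            "pre_sd": float(self.pre.std(ddof=1)),
            "post_mean": float(self.post.mean()),
            "post_sd": float(self.post.std(ddof=1)),
            "rho": float(np.corrcoef(self.pre, self.post)[0, 1]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pre": self.pre, "post": self.post})


def sample_bivariate(
    spec: BivariateSpec,
    n: int,
    seed: int = 0,
    *,
    rng: np.random.Generator | None = None,
    truncate: tuple[float, float] | None = None,
    stream: str = "mri",
) -> PairedSample:
    """Draw n correlated (pre, post) pairs.

    Uses the conditional (Cholesky) construction
    ``post = mu_y + rho*sd_y/sd_x*(pre - mu_x) + sd_y*sqrt(1-rho^2)*z``,
    which is exact for the bivariate normal.

    Parameters
    ----------
    truncate
        Optional (low, high) clipping bounds, off by default.  Percent-type
        measurands can in principle be clipped to [0, 100], but the model is
        an untruncated normal: clipping biases the sample moments, so a
        warning is issued.
    rng
        Explicit generator; when omitted one is derived from ``(seed, stream)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = substream(seed, stream)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    pre = spec.mu_pre + spec.sd_pre * z1
    post = (
        spec.mu_post
        + spec.rho * spec.sd_post * z1
        + spec.sd_post * np.sqrt(1.0 - spec.rho**2) * z2
    )
    if truncate is not None:
        warnings.warn(
            "truncating a bivariate-normal sample breaks moment recovery",
            UserWarning,
            stacklevel=2,
        )
        lo, hi = truncate
        pre = np.clip(pre, lo, hi)
        post = np.clip(post, lo, hi)
    return PairedSample(pre=pre, post=post, n=n, seed=int(seed))
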