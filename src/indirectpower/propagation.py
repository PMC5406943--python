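"""Two-stage uncertainty propagation into the novel biomarker's change.

Every bootstrap regression fit j is crossed with every simulated MRI pair i:

    yhat_pre[j, i]  = a_j + b_j * x_pre[i]
    yhat_post[j, i] = a_j + b_j * x_post[i]

yielding B x n predicted pairs (5,000,000 at the default B = 500, n = 10,000).
Two conventions then turn predictions into realized measurement pairs:

``per_pair_residual`` (default)
    Each predicted pair receives its own bivariate-normal residual
    (SD ``residual_sd`` on both margins, correlation ``rho_dosi``).  This
    keeps the regression-transfer uncertainty of each (replicate, pair)
    combination intact.

``aggregate_moments``
    The marginal means/SDs of the B x n predicted pre and post values are
    collapsed into a single bivariate normal with correlation ``rho_dosi``,
    from which B x n fresh pairs are redrawn.  This discards the coupling
    between a replicate's pre and post predictions and consequently
    understates the change SD; it is retained as an alternative convention.

Results are accumulated in one pass over replicate blocks; the residual
stream is laid out per replicate so summaries are bit-identical for any
block size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .anchors import AnchorSet
from .bivariate import PairedSample
from .regression import BootstrapEnsemble

__all__ = ["PropagationResult", "predicted_pairs", "propagate", "summarize_changes"]

MODES = ("per_pair_residual", "aggregate_moments")


@dataclass(frozen=True)
class PropagationResult:
    """Summaries of the B x n simulated biomarker pairs.

    ``predicted_*`` moments describe the noise-free regression predictions;
    ``realized_*`` SDs include the residual noise.  ``change_*`` summarize
    post minus pre of the realized pairs.
    """

    biomarker_name: str
    rho_mri: float
    rho_dosi: float
    predicted_pre_mean: float
    predicted_pre_sd: float
    predicted_post_mean: float
    predicted_post_sd: float
    realized_pre_sd: float
    realized_post_sd: float
    realized_rho: float
    change_mean: float
    change_sd: float
    n_pairs: int
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; valid modes: {MODES}")


class _Accumulator:
    """One-pass sums for means, SDs and one cross-moment."""

    __slots__ = ("n", "s_pre", "s_post", "ss_pre", "ss_post", "s_cross", "s_d", "ss_d")

    def __init__(self) -> None:
        self.n = 0
        self.s_pre = self.s_post = 0.0
        self.ss_pre = self.ss_post = 0.0
        self.s_cross = 0.0
        self.s_d = self.ss_d = 0.0

    def add(self, pre: np.ndarray, post: np.ndarray) -> None:
        self.n += pre.size
        self.s_pre += float(pre.sum())
        self.s_post += float(post.sum())
        self.ss_pre += float((pre * pre).sum())
        self.ss_post += float((post * post).sum())
        self.s_cross += float((pre * post).sum())
        d = post - pre
        self.s_d += float(d.sum())
        self.ss_d += float((d * d).sum())

    def _sd(self, s: float, ss: float) -> float:
        var = (ss - s * s / self.n) / (self.n - 1)
        return math.sqrt(max(var, 0.0))

    def moments(self) -> dict:
        n = self.n
        pre_sd = self._sd(self.s_pre, self.ss_pre)
        post_sd = self._sd(self.s_post, self.ss_post)
        cov = (self.s_cross - self.s_pre * self.s_post / n) / (n - 1)
        rho = cov / (pre_sd * post_sd) if pre_sd > 0 and post_sd > 0 else 0.0
        return {
            "pre_mean": self.s_pre / n,
            "pre_sd": pre_sd,
            "post_mean": self.s_post / n,
            "post_sd": post_sd,
            "rho": rho,
            "d_mean": self.s_d / n,
            "d_sd": self._sd(self.s_d, self.ss_d),
        }


def predicted_pairs(ensemble: BootstrapEnsemble, mri_pairs: PairedSample):
    """Noise-free predicted (pre, post) biomarker values, shape (B, n).

    Row j crosses bootstrap fit j with all simulated MRI pairs.  Used by the
    streamed propagation one block at a time; exposed for direct inspection
    at small sizes.
    """
    a = ensemble.intercepts[:, None]
    b = ensemble.slopes[:, None]
    return a + b * mri_pairs.pre[None, :], a + b * mri_pairs.post[None, :]


def _block_slices(B: int, block_size: int):
    for j0 in range(0, B, block_size):
        yield slice(j0, min(j0 + block_size, B))


def propagate(
    ensemble: BootstrapEnsemble,
    mri_pairs: PairedSample,
    anchors: AnchorSet,
    rho_dosi: float,
    mode: str = "per_pair_residual",
    seed: int = 0,
    block_size: int = 100,
) -> PropagationResult:
    """Cross the bootstrap ensemble with the simulated MRI pairs and
    summarize the distribution of within-subject biomarker change.

    The post-treatment transfer uses the same fitted regression as baseline
    (the cross-sectional link is assumed stable over treatment).

    Parameters
    ----------
    rho_dosi
        Pre/post correlation of the residual (or redrawn) biomarker noise.
    mode
        ``per_pair_residual`` or ``aggregate_moments`` (see module docstring).
    block_size
        Number of bootstrap replicates processed per block.  Affects memory
        only: summaries are identical for any block size.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; valid modes: {MODES}")
    if not abs(rho_dosi) < 1:
        raise ValueError("|rho_dosi| must be < 1")
    if ensemble.B < 1 or mri_pairs.n < 1:
        raise ValueError("ensemble and MRI sample must be non-empty")

    B, n = ensemble.B, mri_pairs.n
    sigma = anchors.residual_sd
    rho_mri = float(np.corrcoef(mri_pairs.pre, mri_pairs.post)[0, 1]) if n > 2 else float("nan")

    pred_acc = _Accumulator()
    real_acc = _Accumulator()
    rng = substream(
        seed, f"residuals:{anchors.biomarker_name}:{rho_dosi}"
    )
    c = math.sqrt(1.0 - rho_dosi**2)

    for sl in _block_slices(B, block_size):
        a = ensemble.intercepts[sl, None]
        b = ensemble.slopes[sl, None]
        pred_pre = a + b * mri_pairs.pre[None, :]
        pred_post = a + b * mri_pairs.post[None, :]
        pred_acc.add(pred_pre, pred_post)
        if mode == "per_pair_residual":
            # (nb, 2, n) keeps the stream order per replicate, so results do
            # not depend on block_size.
            z = rng.standard_normal((pred_pre.shape[0], 2, n))
            e_pre = sigma * z[:, 0, :]
            e_post = sigma * (rho_dosi * z[:, 0, :] + c * z[:, 1, :])
            real_acc.add(pred_pre + e_pre, pred_post + e_post)

    pred = pred_acc.moments()

    if mode == "aggregate_moments":
        # Redraw B*n pairs from the collapsed predicted moments.
        rng2 = substream(seed, f"aggregate:{anchors.biomarker_name}:{rho_dosi}")
        remaining = B * n
        chunk = max(block_size, 1) * n
        while remaining > 0:
            m = min(chunk, remaining)
            z = rng2.standard_normal((m, 2))
            pre = pred["pre_mean"] + pred["pre_sd"] * z[:, 0]
            post = pred["post_mean"] + pred["post_sd"] * (
                rho_dosi * z[:, 0] + c * z[:, 1]
            )
            real_acc.add(pre, post)
            remaining -= m

    real = real_acc.moments()
    return PropagationResult(
        biomarker_name=anchors.biomarker_name,
        rho_mri=rho_mri,
        rho_dosi=float(rho_dosi),
        predicted_pre_mean=pred["pre_mean"],
        predicted_pre_sd=pred["pre_sd"],
        predicted_post_mean=pred["post_mean"],
        predicted_post_sd=pred["post_sd"],
        realized_pre_sd=real["pre_sd"],
        realized_post_sd=real["post_sd"],
        realized_rho=real["rho"],
        change_mean=real["d_mean"],
        change_sd=real["d_sd"],
        n_pairs=B * n,
        mode=mode,
    )


def summarize_changes(result: PropagationResult) -> tuple[str, str, str]:
    """Format the change row: (N with thousands separators, mean to 1 dp,
    SD to 2 dp), rounding half up as in the published tables."""
    from ._format import round_half_up

    n = f"{result.n_pairs:,}"
    mean = f"{round_half_up(result.change_mean, 1):.1f}"
    sd = f"{round_half_up(result.change_sd, 2):.2f}"
    return n, mean, sd
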