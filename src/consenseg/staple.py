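"""Consensus ground-truth estimation from multiple annotators (STAPLE).

Given R binary expert segmentations D_ij (rater j's decision at pixel i),
STAPLE treats the unknown true segmentation T_i as a latent variable and
jointly estimates, by expectation-maximization,

* the posterior foreground probability W_i = P(T_i = 1 | D, p, q), and
* each rater's sensitivity p_j = P(D_ij = 1 | T_i = 1) and specificity
  q_j = P(D_ij = 0 | T_i = 0).

E-step (spatially uniform foreground prior g):

    W_i = g * prod_j p_j^D_ij (1-p_j)^(1-D_ij)
          / [ that  +  (1-g) * prod_j (1-q_j)^D_ij q_j^(1-D_ij) ]

M-step:

    p_j = sum_i W_i D_ij / sum_i W_i
    q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i)

iterated until the mean absolute change of W falls below ``tol``.  The
binarized W (strictly > 0.5 by default) is the estimated ground truth
("est. GT") used as training target and evaluation reference everywhere
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LabelMask, connected_components, filter_min_size

__all__ = [
    "RaterPerformance",
    "ConsensusEstimate",
    "Staple",
    "estimate_ground_truth",
    "binarize_consensus",
]

_EPS = 1e-7  # probability floor/cap inside the E-step (log-domain safety)


@dataclass
class RaterPerformance:
    sensitivity: float
    specificity: float
    rater_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity/specificity must lie in [0, 1]")


@dataclass
class ConsensusEstimate:
    """EM fit result: posterior map, rater performances and diagnostics."""

    posterior: np.ndarray
    performances: list[RaterPerformance]
    iterations: int
    converged: bool
    prior: float
    log_likelihood: list[float] = field(default_factory=list)

    def binarize(self, threshold: float = 0.5, min_size: int = 1) -> LabelMask:
        return binarize_consensus(self, threshold=threshold, min_size=min_size)

    def summary(self) -> str:
        lines = [
            "STAPLE consensus estimate",
            "=" * 54,
            f"raters: {len(self.performances)}   prior g: {self.prior:.4f}",
            f"iterations: {self.iterations}   converged: {self.converged}",
            f"{'rater':<16}{'sensitivity p_j':>18}{'specificity q_j':>18}",
            "-" * 54,
        ]
        for perf in self.performances:
            lines.append(
                f"{perf.rater_id:<16}{perf.sensitivity:>18.4f}{perf.specificity:>18.4f}"
            )
        return "\n".join(lines)


class Staple:
    """STAPLE model over a set of same-shape binary annotator masks.

    Parameters
    ----------
    masks : list of LabelMask
        At least one annotator mask; instance labels are reduced to binary.
    prior : float or "auto"
        Foreground prior g.  "auto" uses the mean foreground fraction over
        all raters' masks.  EM runs on the full pixel grid so g reflects the
        true class imbalance of the scene.
    """

    def __init__(self, masks: list[LabelMask], prior: float | str = "auto"):
        if len(masks) < 1:
            raise ValueError("need at least one annotator mask")
        shapes = {m.shape for m in masks}
        if len(shapes) != 1:
            raise ValueError(f"masks disagree in shape: {shapes}")
        self.shape = masks[0].shape
        self.rater_ids = [m.annotator_id or f"rater{j}" for j, m in enumerate(masks)]
        self.D = np.stack([m.binary().ravel() for m in masks]).astype(np.float64)
        if prior == "auto":
            self.prior = float(self.D.mean())
        else:
            self.prior = float(prior)
            if not 0.0 <= self.prior <= 1.0:
                raise ValueError("prior must lie in [0, 1]")

    def fit(
        self,
        tol: float = 1e-7,
        max_iter: int = 100,
        init_sensitivity: float = 0.99,
        init_specificity: float = 0.99,
    ) -> ConsensusEstimate:
        D = self.D
        R, n = D.shape
        g = self.prior

        if g == 0.0 or g == 1.0:
            # unanimous all-background / all-foreground: nothing to estimate
            warnings.warn(
                "unanimous constant masks: returning them as consensus without EM",
                stacklevel=2,
            )
            W = np.full(n, g)
            perfs = [RaterPerformance(1.0, 1.0, rid) for rid in self.rater_ids]
            return ConsensusEstimate(
                W.reshape(self.shape), perfs, iterations=0, converged=True, prior=g
            )

        p = np.full(R, init_sensitivity)
        q = np.full(R, init_specificity)
        W = np.full(n, g)
        log_g, log_1mg = np.log(g), np.log1p(-g)
        loglik: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            pc = np.clip(p, _EPS, 1 - _EPS)
            qc = np.clip(q, _EPS, 1 - _EPS)
            # log P(D_i | T=1), log P(D_i | T=0) summed over raters
            la = log_g + np.log(pc) @ D + np.log1p(-pc) @ (1 - D)
            lb = log_1mg + np.log1p(-qc) @ D + np.log(qc) @ (1 - D)
            if not (np.isfinite(la).all() and np.isfinite(lb).all()):
                raise FloatingPointError("non-finite E-step despite probability floor")
            m = np.maximum(la, lb)
            ea, eb = np.exp(la - m), np.exp(lb - m)
            W_new = ea / (ea + eb)
            loglik.append(float((m + np.log(ea + eb)).sum()))
            delta = float(np.abs(W_new - W).mean())
            W = W_new
            sw = W.sum()
            swc = n - sw
            p = (D @ W) / sw
            q = ((1 - D) @ (1 - W)) / swc
            if delta < tol:
                converged = True
                break

        perfs = [
            RaterPerformance(float(np.clip(p[j], 0, 1)), float(np.clip(q[j], 0, 1)), rid)
            for j, rid in enumerate(self.rater_ids)
        ]
        return ConsensusEstimate(
            W.reshape(self.shape),
            perfs,
            iterations=it,
            converged=converged,
            prior=g,
            log_likelihood=loglik,
        )


def estimate_ground_truth(
    masks: list[LabelMask],
    prior: float | str = "auto",
    tol: float = 1e-7,
    max_iter: int = 100,
    seed: int | None = None,  # noqa: ARG001 - EM is deterministic; kept for interface symmetry
) -> ConsensusEstimate:
    """Convenience wrapper: ``Staple(masks, prior).fit(tol, max_iter)``."""
    return Staple(masks, prior=prior).fit(tol=tol, max_iter=max_iter)


def binarize_consensus(
    estimate: ConsensusEstimate, threshold: float = 0.5, min_size: int = 1
) -> LabelMask:
    """Threshold the posterior (strict ``W > threshold``), component-label with
    8-connectivity and apply the dataset minimum object size."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    binary = estimate.posterior > threshold
    mask = connected_components(binary, annotator_id="est_gt")
    return filter_min_size(mask, min_size) if min_size > 1 else mask
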