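"""Hybrid segmentation loss family for binary foreground/background.

Deterministic numeric losses of a predicted foreground-probability
volume ŷ against a binary target y, combining distribution-based terms
(cross-entropy, TopK, focal) with region-based terms (soft Dice,
Tversky).  Aneurysm voxels are a vanishing fraction of a TOF-MRA
volume, so compounds of the two families are the practical choice; the
eight preset combinations L1–L8 are provided.

Conventions: probabilities are clipped to [ε, 1−ε] with ε = 1e−7 inside
every logarithm (0·log 0 := 0); cross-entropy-family terms reduce by the
unweighted voxel mean while Dice/Tversky use volume-global sums, as
their defining formulas do.  All losses are ≥ 0 and exactly 0 at a
perfect binary prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .io import GridMismatchError, ParameterError

__all__ = [
    "CLIP_EPS",
    "DICE_SMOOTH",
    "LossTerm",
    "CompoundLossSpec",
    "PRESETS",
    "preset",
    "ce_loss",
    "dice_loss",
    "topk_loss",
    "focal_loss",
    "tversky_loss",
    "compound_loss",
]

CLIP_EPS = 1e-7  # probability clipping inside logarithms
DICE_SMOOTH = 1e-5  # soft-Dice smoothing (numerator and denominator)


def _flat(pred, target):
    p = np.asarray(getattr(pred, "data", pred), dtype=np.float64).ravel()
    t = np.asarray(getattr(target, "data", target), dtype=np.float64).ravel()
    if p.shape != t.shape:
        raise GridMismatchError(f"prediction size {p.size} != target size {t.size}")
    if p.min() < 0 or p.max() > 1:
        raise ParameterError("predicted probabilities must lie in [0, 1]")
    if not np.isin(t, (0.0, 1.0)).all():
        raise ParameterError("target must be binary {0, 1}")
    return p, t


def _log(p):
    # lower clip keeps log finite on confident mistakes; log(1) = 0 stays
    # exact so every loss is exactly 0 at a perfect binary prediction
    return np.log(np.clip(p, CLIP_EPS, 1.0))


def ce_loss(pred, target) -> float:
    """Binary cross-entropy, mean over voxels: −[y log ŷ + (1−y) log(1−ŷ)]."""
    p, t = _flat(pred, target)
    return float(np.mean(-(t * _log(p) + (1.0 - t) * _log(1.0 - p))))


def dice_loss(pred, target) -> float:
    """Soft Dice with squared denominator: 1 − 2Σyŷ / Σ(y² + ŷ²).

    A small smoothing term stabilises the empty-foreground case; it
    leaves volume-sized worked values unchanged to ≥ 6 decimals.
    """
    p, t = _flat(pred, target)
    num = 2.0 * float(np.sum(t * p)) + DICE_SMOOTH
    den = float(np.sum(t * t) + np.sum(p * p)) + DICE_SMOOTH
    return 1.0 - num / den


def _ce_per_voxel(p, t):
    # cross-entropy of the true-class probability at each voxel
    p_true = np.where(t == 1.0, p, 1.0 - p)
    return -_log(p_true), p_true


def topk_loss(pred, target, mode: str = "fraction", t: float = 0.5, k_percent: float = 10.0) -> float:
    """TopK loss: cross-entropy restricted to hard voxels.

    ``threshold`` mode averages CE over voxels whose predicted
    probability for the *true* class falls below ``t`` (the indicator
    form); ``fraction`` mode averages CE over the
    ``⌈k_percent·N/100⌉`` voxels with the highest CE (the common
    training convention).  An empty threshold selection — every voxel
    confidently correct — yields 0.
    """
    p, y = _flat(pred, target)
    ce, p_true = _ce_per_voxel(p, y)
    if mode == "threshold":
        if not (0.0 < t < 1.0):
            raise ParameterError(f"threshold t must be in (0,1), got {t}")
        sel = p_true < t
        return float(ce[sel].mean()) if sel.any() else 0.0
    if mode == "fraction":
        if not (0.0 < k_percent <= 100.0):
            raise ParameterError(f"k_percent must be in (0,100], got {k_percent}")
        k = ceil(k_percent * ce.size / 100.0)
        hardest = np.partition(ce, ce.size - k)[ce.size - k :]
        return float(hardest.mean())
    raise ParameterError(f"mode must be 'threshold' or 'fraction', got {mode!r}")


def focal_loss(pred, target, alpha: float = 0.25, gamma: float = 2.0, variant: str = "squared") -> float:
    """Focal loss down-weighting easy voxels; mean over voxels.

    The default ``"squared"`` variant evaluates
    −[α(1−ŷ)^γ y log ŷ + (1+α) ŷ² (1−y) log(1−ŷ)] exactly as the hybrid
    loss family defines it; note its background term uses a fixed square
    and an (1+α) weight.  The ``"canonical"`` variant is the standard
    α(1−ŷ)^γ y CE₊ + (1−α) ŷ^γ (1−y) CE₋ form from the object-detection
    literature, kept for comparison.
    """
    if gamma < 0 or alpha <= 0:
        raise ParameterError(f"need gamma >= 0 and alpha > 0, got gamma={gamma} alpha={alpha}")
    p, y = _flat(pred, target)
    if variant == "squared":
        term = alpha * (1.0 - p) ** gamma * y * _log(p) + (1.0 + alpha) * p**2 * (1.0 - y) * _log(1.0 - p)
    elif variant == "canonical":
        term = alpha * (1.0 - p) ** gamma * y * _log(p) + (1.0 - alpha) * p**gamma * (1.0 - y) * _log(1.0 - p)
    else:
        raise ParameterError(f"variant must be 'squared' or 'canonical', got {variant!r}")
    return float(np.mean(-term))


def tversky_loss(pred, target, alpha: float = 0.3, beta: float = 0.7, classes: str = "foreground") -> float:
    """Tversky loss 1 − TI with TI = Σp₀g₀ / (Σp₀g₀ + αΣp₀g₁ + βΣp₁g₀).

    α penalises false positives and β false negatives; with α = β = 0.5
    and binary predictions, 1 − TI reduces to the linear-denominator
    Dice-overlap complement.  ``classes="both"`` adds the background
    class with p₁ = 1 − p₀, g₁ = 1 − g₀.
    """
    if alpha < 0 or beta < 0:
        raise ParameterError(f"alpha and beta must be >= 0, got {alpha}, {beta}")
    if classes not in ("foreground", "both"):
        raise ParameterError(f"classes must be 'foreground' or 'both', got {classes!r}")
    p0, g0 = _flat(pred, target)

    def one_minus_ti(p_fg, g_fg):
        p_bg, g_bg = 1.0 - p_fg, 1.0 - g_fg
        tp = float(np.sum(p_fg * g_fg))
        fp = float(np.sum(p_fg * g_bg))
        fn = float(np.sum(p_bg * g_fg))
        den = tp + alpha * fp + beta * fn
        if den == 0.0:  # class absent and never predicted: perfect
            return 0.0
        return 1.0 - tp / den

    loss = one_minus_ti(p0, g0)
    if classes == "both":
        loss += one_minus_ti(1.0 - p0, 1.0 - g0)
    return loss


# ---------------------------------------------------------------------------
# Compound losses


@dataclass(frozen=True)
class LossTerm:
    name: str
    weight: float = 1.0
    params: dict = field(default_factory=dict)


_TERM_FUNCS = {
    "ce": ce_loss,
    "dice": dice_loss,
    "topk": topk_loss,
    "focal": focal_loss,
    "tversky": tversky_loss,
}


@dataclass
class CompoundLossSpec:
    """An ordered, weighted combination of loss terms.

    The compound value is Σ weightᵢ · termᵢ(pred, target); it is linear
    in the weights and 0 at a perfect binary prediction.
    """

    terms: tuple

    def __post_init__(self):
        self.terms = tuple(
            t if isinstance(t, LossTerm) else LossTerm(*t) for t in self.terms
        )
        if not self.terms:
            raise ParameterError("a compound loss needs at least one term")
        for term in self.terms:
            if term.name not in _TERM_FUNCS:
                raise ParameterError(
                    f"unknown loss term {term.name!r}; choose from {sorted(_TERM_FUNCS)}"
                )
            if term.weight < 0:
                raise ParameterError(f"term {term.name!r} has negative weight {term.weight}")
        if all(t.weight == 0 for t in self.terms):
            raise ParameterError("at least one term must have positive weight")


#: The eight studied combinations. L7/L8 are the *weighted* variants whose
#: per-term weights were never published; they must be supplied explicitly.
PRESETS = {
    "L1": ("dice", "ce"),
    "L2": ("dice", "topk"),
    "L3": ("dice", "ce", "topk"),
    "L4": ("dice", "focal"),
    "L5": ("dice", "topk", "focal"),
    "L6": ("dice", "topk", "focal", "tversky", "ce"),
    "L7": ("dice", "topk", "ce"),
    "L8": ("dice", "topk", "focal", "tversky", "ce"),
}
_WEIGHTED_PRESETS = {"L7", "L8"}


def preset(name: str, weights=None, params: dict | None = None) -> CompoundLossSpec:
    """Build one of the preset compounds L1–L8.

    Unweighted presets (L1–L6) default to unit weights.  The weighted
    presets L7/L8 require an explicit weight per term since no canonical
    values exist for them.  ``params`` optionally maps a term name to
    its keyword parameters (e.g. ``{"topk": {"k_percent": 10}}``).
    """
    key = name.upper()
    if key not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    names = PRESETS[key]
    if weights is None:
        if key in _WEIGHTED_PRESETS:
            raise ParameterError(
                f"preset {key} is a weighted compound: pass one weight per term {names}"
            )
        weights = (1.0,) * len(names)
    if len(weights) != len(names):
        raise ParameterError(f"preset {key} has {len(names)} terms, got {len(weights)} weights")
    params = params or {}
    return CompoundLossSpec(
        tuple(LossTerm(n, float(w), dict(params.get(n, {}))) for n, w in zip(names, weights))
    )


def compound_loss(pred, target, spec: CompoundLossSpec) -> float:
    """Evaluate a weighted compound: Σ weight·term(pred, target)."""
    total = 0.0
    for term in spec.terms:
        total += term.weight * _TERM_FUNCS[term.name](pred, target, **term.params)
    return float(total)
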