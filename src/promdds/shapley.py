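"""From-scratch Shapley-value attribution for the promoter classifier.

Two engines share one masking convention (a coalition takes the explained
instance's value where present and a background reference where absent):

* :func:`exact_shapley` — brute-force enumeration of all 2^M coalitions,
  weighting marginal contributions by |S|!(M−|S|−1)!/M!.  Feasible for
  M ≤ 15; it is the oracle for everything else.
* :func:`kernel_shap` — the weighted-least-squares estimator: coalitions
  are sampled, each weighted by the Shapley kernel
  (M−1) / (C(M,|z|)·|z|·(M−|z|)), and the attributions solve the weighted
  regression with the efficiency identity φ₀ + Σφ = f(x) enforced as an
  equality constraint.  With all 2^M coalitions included it reproduces the
  exact values.

Positional summaries translate attributions of the 99 dinucleotide
features back to TSS-relative promoter coordinates: global mean-|φ|
rankings, directional (high-vs-low feature value) summaries, AT-class
versus GC-class dinucleotide impact, and per-instance top-k reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import TrainedModel
from .dds import DimensionError, FeatureMatrix

AT_DINUCLEOTIDES = frozenset({"AA", "AT", "TA", "TT"})
GC_DINUCLEOTIDES = frozenset({"GG", "GC", "CG", "CC"})

MAX_EXACT_FEATURES = 15


@dataclass(frozen=True)
class ShapExplanation:
    """Per-feature attributions φ plus the base value φ₀ for one instance."""

    phi: np.ndarray
    base_value: float
    model_output: float
    instance_id: str = ""
    position_labels: np.ndarray | None = None
    n_coalitions: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        if self.position_labels is not None:
            object.__setattr__(
                self, "position_labels", np.asarray(self.position_labels, dtype=int)
            )
            if self.position_labels.size != self.phi.size:
                raise DimensionError("position labels do not match phi length")

    @property
    def n_features(self) -> int:
        return self.phi.size

    def efficiency_gap(self) -> float:
        """|φ₀ + Σφ − f(x)|; zero up to solver tolerance by construction."""
        return abs(self.base_value + float(self.phi.sum()) - self.model_output)


def eq2_weight(n_size: int, s_size: int) -> float:
    """Shapley enumeration weight |S|!(N−|S|−1)!/N! for one subset size."""
    if n_size < 1:
        raise ValueError("N must be at least 1")
    if not 0 <= s_size <= n_size - 1:
        raise ValueError(f"|S|={s_size} outside [0, {n_size - 1}]")
    return factorial(s_size) * factorial(n_size - s_size - 1) / factorial(n_size)


def shapley_kernel_weight(M: int, z_size: int) -> float:
    """Kernel-SHAP coalition weight (M−1)/(C(M,|z|)·|z|·(M−|z|))."""
    if not 1 <= z_size <= M - 1:
        raise ValueError("kernel weight defined only for 1 <= |z| <= M-1")
    return (M - 1) / (comb(M, z_size) * z_size * (M - z_size))


def masked_inputs(x: np.ndarray, background: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Hybrid inputs taking ``x`` where the coalition is 1, else background."""
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    Z = np.asarray(Z)
    if x.shape != background.shape or (Z.ndim and Z.shape[-1] != x.size):
        raise DimensionError("x, background and coalitions disagree in width")
    Z = Z.astype(bool)
    return np.where(Z, x, background)


def masked_model(
    model_fn: Callable[[np.ndarray], np.ndarray] | TrainedModel,
    x: np.ndarray,
    background: np.ndarray,
    z: np.ndarray,
) -> float:
    """Model output on the coalition-masked hybrid of ``x`` and background."""
    fn = model_fn.decision_scores if isinstance(model_fn, TrainedModel) else model_fn
    hybrid = masked_inputs(x, background, np.atleast_2d(z))
    return float(np.asarray(fn(hybrid)).ravel()[0])


def _model_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(model, TrainedModel):
        return lambda X: model.decision_scores(X)
    return model


def _all_masks(M: int) -> np.ndarray:
    """All 2^M coalitions as a (2^M, M) boolean array (bit i = feature i)."""
    ints = np.arange(2**M, dtype=np.uint32)
    return (ints[:, None] >> np.arange(M, dtype=np.uint32)[None, :]) & 1 == 1


def exact_shapley(
    model_fn,
    x,
    background,
    position_labels=None,
    instance_id: str = "",
) -> ShapExplanation:
    """Exact Shapley values by enumerating every coalition (M ≤ 15)."""
    fn = _model_fn(model_fn)
    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float).ravel()
    M = x.size
    if M > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration over 2^{M} coalitions refused (M > "
            f"{MAX_EXACT_FEATURES}); use kernel_shap for wide inputs"
        )
    Z = _all_masks(M)
    f = np.asarray(fn(masked_inputs(x, background, Z)), dtype=float).ravel()
    sizes = Z.sum(axis=1)
    weights_by_size = np.array([eq2_weight(M, s) for s in range(M)])
    phi = np.zeros(M)
    masks_int = np.arange(2**M, dtype=np.uint32)
    for i in range(M):
        bit = np.uint32(1 << i)
        without = (masks_int & bit) == 0
        s_idx = masks_int[without]
        phi[i] = np.sum(
            weights_by_size[sizes[s_idx]] * (f[s_idx | bit] - f[s_idx])
        )
    base = float(f[0])
    return ShapExplanation(
        phi=phi,
        base_value=base,
        model_output=float(f[-1]),
        instance_id=instance_id,
        position_labels=position_labels,
        n_coalitions=2**M,
    )


def _sample_coalitions(
    M: int, n_interior: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Interior coalitions with sizes drawn ∝ (M−1)/(s(M−s)) and uniform
    membership given size; returns (Z, kernel weights)."""
    sizes = np.arange(1, M)
    p = (M - 1) / (sizes * (M - sizes))
    p = p / p.sum()
    drawn = rng.choice(sizes, size=n_interior, p=p)
    Z = np.zeros((n_interior, M), dtype=bool)
    for row, s in enumerate(drawn):
        Z[row, rng.choice(M, size=s, replace=False)] = True
    # size bias is already in the sampling distribution; residual weight is
    # uniform over subsets of a size, i.e. proportional to the kernel weight
    # times C(M, s) — constant, so equal weights are correct for sampled rows
    w = np.ones(n_interior)
    return Z, w


def kernel_shap(
    model_fn,
    x,
    background,
    n_coalitions: int | None = None,
    seed: int = 0,
    exhaustive: bool = False,
    position_labels=None,
    instance_id: str = "",
) -> ShapExplanation:
    """Kernel-SHAP estimate of the Shapley values of one instance.

    Steps: sample coalitions z′ ∈ {0,1}^M (the all-zeros and all-ones
    coalitions are always included), evaluate the model on each masked
    hybrid, weight by the Shapley kernel, and fit the weighted linear
    model whose coefficients are the attributions, with efficiency
    (φ₀ + Σφ = f(x)) as an equality constraint.  ``exhaustive=True``
    enumerates all 2^M coalitions instead of sampling, which reproduces
    :func:`exact_shapley` up to solver round-off.
    """
    fn = _model_fn(model_fn)
    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float).ravel()
    M = x.size
    if M < 2:
        raise ValueError("kernel SHAP needs at least two features")
    if exhaustive:
        Z_all = _all_masks(M)
        interior = Z_all[(Z_all.sum(axis=1) > 0) & (Z_all.sum(axis=1) < M)]
        w = np.array([shapley_kernel_weight(M, int(z.sum())) for z in interior])
        n_used = 2**M
    else:
        if n_coalitions is None:
            n_coalitions = 2 * M + 2048
        if n_coalitions < M + 2:
            raise ValueError(f"n_coalitions must be at least M+2 = {M + 2}")
        rng = np.random.default_rng(seed)
        interior, w = _sample_coalitions(M, n_coalitions - 2, rng)
        n_used = n_coalitions

    f0 = float(np.asarray(fn(background[None, :])).ravel()[0])
    fx = float(np.asarray(fn(x[None, :])).ravel()[0])
    f_int = np.asarray(fn(masked_inputs(x, background, interior)), dtype=float).ravel()

    # Weighted least squares with phi0 fixed at f0 and efficiency enforced
    # by eliminating the last coefficient:
    #   phi_M = (fx - f0) - sum_{i<M} phi_i
    Zf = interior.astype(float)
    A = Zf[:, :-1] - Zf[:, -1:]
    b = f_int - f0 - Zf[:, -1] * (fx - f0)
    sw = np.sqrt(w)
    sol, *_ = np.linalg.lstsq(A * sw[:, None], b * sw, rcond=None)
    if not np.all(np.isfinite(sol)):
        raise RuntimeError(
            "degenerate coalition design; increase n_coalitions"
        )
    phi = np.empty(M)
    phi[:-1] = sol
    phi[-1] = (fx - f0) - sol.sum()
    return ShapExplanation(
        phi=phi,
        base_value=f0,
        model_output=fx,
        instance_id=instance_id,
        position_labels=position_labels,
        n_coalitions=n_used,
        seed=None if exhaustive else seed,
    )


# ---------------------------------------------------------------------------
# batch explanation and positional summaries
# ---------------------------------------------------------------------------

def background_reference(X, size: int = 100, seed: int = 0) -> np.ndarray:
    """Feature-wise mean of a seeded background sample of training rows."""
    X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    take = min(size, X.shape[0])
    idx = rng.choice(X.shape[0], size=take, replace=False)
    return X[idx].mean(axis=0)


def explain_sample(
    model,
    pool: FeatureMatrix,
    background: np.ndarray,
    n_explain: int = 100,
    n_coalitions: int | None = None,
    seed: int = 0,
) -> list[ShapExplanation]:
    """Explain a without-replacement sample of instances from a pool.

    Mirrors the analysis design of explaining 100 non-repeated random
    promoters; deterministic under the seed.
    """
    if n_explain > pool.n_sequences:
        raise ValueError(
            f"requested {n_explain} instances from a pool of {pool.n_sequences}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(pool.n_sequences, size=n_explain, replace=False))
    fn = _model_fn(model)
    out = []
    for rank, i in enumerate(idx):
        out.append(
            kernel_shap(
                fn,
                pool.values[i],
                background,
                n_coalitions=n_coalitions,
                seed=int((seed * 100003 + rank) % 2**31),
                position_labels=pool.position_labels,
                instance_id=pool.ids[i],
            )
        )
    return out


def align_matrix(pool: FeatureMatrix, explanations: Sequence[ShapExplanation]) -> FeatureMatrix:
    """Rows of ``pool`` in the order of the given explanations' instance ids."""
    index = {rid: i for i, rid in enumerate(pool.ids)}
    try:
        rows = [index[e.instance_id] for e in explanations]
    except KeyError as exc:
        raise ValueError(f"explanation id {exc} not found in the pool") from exc
    return FeatureMatrix(
        values=pool.values[rows],
        position_labels=pool.position_labels,
        ids=tuple(pool.ids[i] for i in rows),
    )


@dataclass(frozen=True)
class GlobalImportance:
    """Positional importance summary across many explanations."""

    position_labels: np.ndarray
    mean_abs_phi: np.ndarray
    mean_phi_high: np.ndarray  # mean phi where feature value > its median
    mean_phi_low: np.ndarray

    def ranking(self) -> np.ndarray:
        """Positions sorted by mean |φ| descending (ties: upstream first)."""
        order = np.lexsort((np.arange(self.position_labels.size), -self.mean_abs_phi))
        return self.position_labels[order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.position_labels,
                "mean_abs_phi": self.mean_abs_phi,
                "mean_phi_high_value": self.mean_phi_high,
                "mean_phi_low_value": self.mean_phi_low,
            }
        )


def global_importance(
    explanations: Sequence[ShapExplanation], X: np.ndarray | FeatureMatrix
) -> GlobalImportance:
    """Mean |φ| per position plus a directional high/low-value summary."""
    if not explanations:
        raise ValueError("no explanations supplied")
    X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    Phi = np.vstack([e.phi for e in explanations])
    if X.shape != Phi.shape:
        raise DimensionError("explanations and feature values are misaligned")
    labels = explanations[0].position_labels
    if labels is None:
        labels = np.arange(Phi.shape[1])
    med = np.median(X, axis=0)
    high = X > med
    n_high = high.sum(axis=0)
    n_low = (~high).sum(axis=0)
    mean_high = np.divide(
        (Phi * high).sum(axis=0), n_high, out=np.zeros(Phi.shape[1]), where=n_high > 0
    )
    mean_low = np.divide(
        (Phi * ~high).sum(axis=0), n_low, out=np.zeros(Phi.shape[1]), where=n_low > 0
    )
    return GlobalImportance(
        position_labels=np.asarray(labels, dtype=int),
        mean_abs_phi=np.abs(Phi).mean(axis=0),
        mean_phi_high=mean_high,
        mean_phi_low=mean_low,
    )


def dinucleotide_class_impact(
    explanations: Sequence[ShapExplanation], sequences: Sequence[str]
) -> pd.DataFrame:
    """Mean φ of AT-composed vs GC-composed (vs mixed) dinucleotide features.

    AT stacks destabilize the duplex (less negative ΔG) and GC stacks
    stabilize it, so a promoter-predicting model is expected to credit the
    two classes in opposite directions.
    """
    if len(explanations) != len(sequences):
        raise DimensionError(
            f"{len(explanations)} explanations vs {len(sequences)} sequences"
        )
    sums = {"AT": 0.0, "GC": 0.0, "mixed": 0.0}
    counts = {"AT": 0, "GC": 0, "mixed": 0}
    for expl, seq in zip(explanations, sequences):
        seq = (seq.sequence if hasattr(seq, "sequence") else str(seq)).upper()
        if len(seq) - 1 != expl.n_features:
            raise DimensionError(
                f"sequence of length {len(seq)} does not yield {expl.n_features} features"
            )
        for j in range(expl.n_features):
            dinuc = seq[j : j + 2]
            cls = "AT" if dinuc in AT_DINUCLEOTIDES else "GC" if dinuc in GC_DINUCLEOTIDES else "mixed"
            sums[cls] += expl.phi[j]
            counts[cls] += 1
    rows = [
        {"class": cls, "mean_phi": (sums[cls] / counts[cls]) if counts[cls] else 0.0,
         "n_features": counts[cls]}
        for cls in ("AT", "GC", "mixed")
    ]
    return pd.DataFrame(rows)


def explain_instance_topk(
    explanation: ShapExplanation, sequence: str | None = None, k: int = 9
) -> pd.DataFrame:
    """Top-k positions of one explanation by |φ| (ties: upstream first)."""
    M = explanation.n_features
    if k > M:
        raise ValueError(f"k={k} exceeds the {M} available features")
    labels = explanation.position_labels
    if labels is None:
        labels = np.arange(M)
    order = np.lexsort((np.arange(M), -np.abs(explanation.phi)))[:k]
    rows = []
    for rank, j in enumerate(order, start=1):
        row = {
            "rank": rank,
            "position": int(labels[j]),
            "phi": float(explanation.phi[j]),
        }
        if sequence is not None:
            row["dinucleotide"] = sequence.upper()[j : j + 2]
        rows.append(row)
    return pd.DataFrame(rows)


def export_explanations(
    explanations: Sequence[ShapExplanation], X, path
) -> None:
    """Long-format TSV: instance id, position, feature value, φ."""
    X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    frames = []
    for i, e in enumerate(explanations):
        labels = e.position_labels if e.position_labels is not None else np.arange(e.n_features)
        frames.append(
            pd.DataFrame(
                {
                    "instance_id": e.instance_id or str(i),
                    "position": labels,
                    "feature_value": X[i],
                    "phi": e.phi,
                    "base_value": e.base_value,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
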