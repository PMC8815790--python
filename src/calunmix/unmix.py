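"""Targeted non-negative matrix factorization unmixing (stage 4).

The measured matrix F_meas (target neuron, neighbors, outside region) is
modeled as F_meas = M · F_sep with a square non-negative mixing matrix M
whose off-diagonal entry m_ij is the contamination of component j in
measured trace i.  There is no dimensionality reduction: the component
count equals the row count.  L1/L2 regularization (ratio l1 = 0.5)
precludes the trivial solution M = I, and a "floating" strategy halves
the regularization weight α until no separated trace is identically
zero.  After factorization a five-step greedy matching permutes the
components back onto the input rows and normalizes the diagonal of M to
one, all while preserving the product M · F_sep exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .datatypes import (
    NeuronMasks,
    RunConfig,
    TraceMatrix,
    UnmixResult,
    VideoStack,
)
from .noise_stats import quantile_std
from .regions import build_regions
from .traces import assemble_F_meas, compute_trace_bundles

__all__ = [
    "normalize_input",
    "nmf_cost",
    "nmf_decompose",
    "match_components",
    "floating_alpha_unmix",
    "rescale_output",
    "downsample_unmix",
    "unmix_all",
    "NeuronUnmix",
]


def normalize_input(F_meas: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Scale F_meas so the target row has unit quantile-based standard
    deviation, then shift by the global minimum so all entries are >= 0.

    Returns ``(normalized, scale, offset)``; raises on a flat target
    trace (quantile std of row 0 is zero).
    """
    F_meas = np.asarray(F_meas, dtype=np.float64)
    scale = quantile_std(F_meas[0])
    if scale <= 0:
        raise ValueError("flat target trace: quantile std of row 0 is zero")
    scaled = F_meas / scale
    offset = float(scaled.min())
    return scaled - offset, float(scale), offset


def nmf_cost(
    F_meas: np.ndarray,
    M: np.ndarray,
    F_sep: np.ndarray,
    alpha: float,
    l1_ratio: float = 0.5,
) -> float:
    """Regularized factorization cost with half-sum norm conventions.

    ``E = ½‖F_meas − M·F_sep‖²_Fro + α·[l1(‖M‖₁+‖F_sep‖₁)
    + (1−l1)(‖M‖²_Fro+‖F_sep‖²_Fro)]`` where ``‖A‖²_Fro = ½ΣA²`` and
    ``‖A‖₁ = ½Σ|A|``.
    """
    F_meas = np.asarray(F_meas, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    F_sep = np.asarray(F_sep, dtype=np.float64)
    resid = F_meas - M @ F_sep
    fro2 = lambda a: 0.5 * float(np.sum(a * a))  # noqa: E731
    l1n = lambda a: 0.5 * float(np.sum(np.abs(a)))  # noqa: E731
    reg = (
        l1_ratio * (l1n(M) + l1n(F_sep))
        + (1.0 - l1_ratio) * (fro2(M) + fro2(F_sep))
    )
    return 0.5 * fro2(resid) + alpha * reg


def nmf_decompose(
    F_norm: np.ndarray,
    alpha: float,
    l1_ratio: float = 0.5,
    max_iter: int = 20000,
    tol: float = 1e-4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Square NMF of the normalized input via coordinate descent.

    Initialization is non-negative double SVD with zeros replaced by
    small random values (deterministic given ``seed``).  sklearn scales
    its penalties by the opposite dimension, so ``alpha_W = α/T`` and
    ``alpha_H = α/n`` recover a plain weight of α on every norm term.
    Returns ``(M_raw, F_sep_raw, n_iter)``.
    """
    F_norm = np.asarray(F_norm, dtype=np.float64)
    if not np.all(np.isfinite(F_norm)):
        raise ValueError("non-finite input to NMF")
    n, T = F_norm.shape
    model = NMF(
        n_components=n,
        init="nndsvdar",
        solver="cd",
        max_iter=max_iter,
        tol=tol,
        l1_ratio=l1_ratio,
        alpha_W=alpha / T,
        alpha_H=alpha / n,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        M_raw = model.fit_transform(F_norm)
    return M_raw, model.components_, int(model.n_iter_)


def match_components(
    M_raw: np.ndarray, F_sep_raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permute components onto input rows by greatest relative
    contribution; the product M·F_sep is preserved at every step.

    (1) column-normalize M to unit column sums, compensating the rows of
    F_sep; (2) init working copy M0 = M and indicator P = 0; (3)
    repeatedly take the largest element m0(i,j) of M0 (ties: smallest
    row, then column), set p_ij = 1, zero row i and column j of M0, and
    re-normalize the remaining non-zero columns; (4) M ← M·Pᵀ,
    F_sep ← P·F_sep; (5) divide column i of M by its diagonal element
    and multiply row i of F_sep by the same number, leaving a unit
    diagonal.  Returns ``(M_matched, F_sep_matched, P)``.
    """
    M = np.asarray(M_raw, dtype=np.float64).copy()
    S = np.asarray(F_sep_raw, dtype=np.float64).copy()
    n = M.shape[0]
    if M.shape != (n, n):
        raise ValueError("M must be square")
    col_sums = M.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError("degenerate component: all-zero column in M")
    M = M / col_sums
    S = S * col_sums[:, None]

    M0 = M.copy()
    P = np.zeros((n, n))
    free_rows = set(range(n))
    free_cols = set(range(n))
    while M0.any():
        i, j = np.unravel_index(int(np.argmax(M0)), M0.shape)  # row-major: ties → smallest i, then j
        P[i, j] = 1.0
        free_rows.discard(int(i))
        free_cols.discard(int(j))
        M0[i, :] = 0.0
        M0[:, j] = 0.0
        cs = M0.sum(axis=0)
        nz = cs > 0
        M0[:, nz] = M0[:, nz] / cs[nz]
    # exact zeros can exhaust M0 early; pair leftovers in ascending order
    for i, j in zip(sorted(free_rows), sorted(free_cols)):
        P[i, j] = 1.0

    M = M @ P.T
    S = P @ S
    diag = np.diag(M).copy()
    if np.any(diag == 0):
        raise ValueError("degenerate component: zero diagonal after matching")
    M = M / diag[None, :]
    S = S * diag[:, None]
    return M, S, P


def _floating_nmf(
    G: np.ndarray, alpha0: float, cfg: RunConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Floating-α loop on an already-normalized non-negative matrix.

    Runs NMF, and if any separated trace is identically zero (max
    absolute value below ε_zero, scaled by the unit quantile std of the
    target row) halves α and retries; below ``alpha_floor`` a final
    unregularized pass is accepted as-is.  Returns the *matched*
    ``(M, F_sep, alpha_final, n_iter)``.
    """
    eps_zero = cfg.epsilon_zero * max(quantile_std(G[0]), 1e-300)
    alpha = float(alpha0)
    while True:
        M_raw, S_raw, n_iter = nmf_decompose(
            G, alpha, cfg.l1_ratio, cfg.max_iter, cfg.tol, seed
        )
        zero_row = np.max(np.abs(S_raw), axis=1) < eps_zero
        zero_col = M_raw.sum(axis=0) == 0
        if not (zero_row.any() or zero_col.any()):
            M, S, _ = match_components(M_raw, S_raw)
            return M, S, alpha, n_iter
        if alpha == 0.0:
            # last resort: unregularized pass is accepted regardless
            M, S, _ = match_components(
                np.where(M_raw.sum(axis=0) == 0, 1e-12, M_raw), S_raw
            )
            return M, S, alpha, n_iter
        alpha = alpha / 2.0
        if alpha < cfg.alpha_floor:
            alpha = 0.0


def floating_alpha_unmix(
    F_meas: TraceMatrix | np.ndarray,
    alpha0: float,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> UnmixResult:
    """Normalize, factorize with floating α, and match components.

    ``F_sep`` in the result is at the normalized scale; feed it to
    :func:`rescale_output` to restore physical amplitudes.
    """
    if cfg is None:
        cfg = RunConfig()
    if seed is None:
        seed = cfg.seed
    rows = F_meas.rows if isinstance(F_meas, TraceMatrix) else np.asarray(F_meas)
    G, scale, offset = normalize_input(rows)
    M, S, alpha_final, n_iter = _floating_nmf(G, alpha0, cfg, seed)
    return UnmixResult(
        F_sep=S,
        M=M,
        alpha_final=alpha_final,
        alpha_initial=float(alpha0),
        n_iterations=n_iter,
        converged=n_iter < cfg.max_iter,
    )


def rescale_output(
    result: UnmixResult, F_meas: TraceMatrix | np.ndarray, scale: float
) -> np.ndarray:
    """Restore physical amplitudes: multiply every separated row by the
    target row's quantile std, then align each row's median with the
    median of the corresponding (background-subtracted) input row."""
    rows = F_meas.rows if isinstance(F_meas, TraceMatrix) else np.asarray(F_meas)
    S = result.F_sep * scale
    shift = np.median(rows, axis=1) - np.median(S, axis=1)
    return S + shift[:, None]


def downsample_unmix(
    F_meas: TraceMatrix | np.ndarray,
    ratio: int,
    alpha0: float,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> tuple[UnmixResult, np.ndarray]:
    """Unmix, estimating the mixing matrix from temporally decimated
    traces when ``ratio > 1``.

    The decimated matrix (every ``ratio``-th frame of the normalized
    input) passes through the floating-α factorization to give M'; the
    full-resolution separated traces then solve, per frame, the
    non-negative least-squares problem F_norm(:, t) ≈ M'·F_sep(:, t).
    Returns ``(UnmixResult, final_traces)`` with the final traces
    rescaled and median-aligned.  ``ratio == 1`` is exactly the direct
    path.
    """
    if cfg is None:
        cfg = RunConfig()
    if seed is None:
        seed = cfg.seed
    rows = F_meas.rows if isinstance(F_meas, TraceMatrix) else np.asarray(F_meas)
    T = rows.shape[1]
    if not 1 <= ratio < T:
        raise ValueError(f"downsample ratio must satisfy 1 <= ratio < T={T}")
    G, scale, offset = normalize_input(rows)
    if ratio == 1:
        result = floating_alpha_unmix(rows, alpha0, cfg, seed)
        return result, rescale_output(result, rows, scale)
    Gd = G[:, ::ratio]
    M, _, alpha_final, n_iter = _floating_nmf(Gd, alpha0, cfg, seed)
    S_full = np.empty_like(G)
    for t in range(T):
        S_full[:, t], _ = nnls(M, G[:, t])
    result = UnmixResult(
        F_sep=S_full,
        M=M,
        alpha_final=alpha_final,
        alpha_initial=float(alpha0),
        n_iterations=n_iter,
        converged=n_iter < cfg.max_iter,
    )
    return result, rescale_output(result, rows, scale)


class NeuronUnmix:
    """Per-neuron output of :func:`unmix_all`."""

    def __init__(
        self,
        neuron_id: int,
        row_labels: list[str],
        raw_trace: np.ndarray,
        bg_sub_trace: np.ndarray,
        unmixed_trace: np.ndarray | None,
        M: np.ndarray | None,
        alpha_final: float | None,
        error: str | None = None,
    ):
        self.neuron_id = neuron_id
        self.row_labels = row_labels
        self.raw_trace = raw_trace
        self.bg_sub_trace = bg_sub_trace
        self.unmixed_trace = unmixed_trace
        self.M = M
        self.alpha_final = alpha_final
        self.error = error

    @property
    def ok(self) -> bool:
        return self.error is None


def _unmix_one(F: TraceMatrix, cfg: RunConfig, raw: np.ndarray) -> NeuronUnmix:
    seed = cfg.seed + int(F.neuron_id)
    try:
        result, final = downsample_unmix(
            F, cfg.downsample_ratio, cfg.alpha_initial, cfg, seed
        )
    except ValueError as exc:
        return NeuronUnmix(
            F.neuron_id, F.row_labels, raw, F.rows[0], None, None, None, str(exc)
        )
    return NeuronUnmix(
        F.neuron_id,
        F.row_labels,
        raw,
        F.rows[0],
        final[0],
        result.M,
        result.alpha_final,
    )


def unmix_all(
    video: VideoStack, masks: NeuronMasks, cfg: RunConfig | None = None
) -> list[NeuronUnmix]:
    """Run the full per-neuron pipeline: regions → traces → unmixing.

    Neurons are processed independently (parallel when ``cfg.workers >
    1``); the per-neuron NMF seed is ``cfg.seed + neuron_id`` so results
    do not depend on the worker count.  A neuron whose unmixing fails
    (e.g. flat trace) is reported with its error; others proceed.
    """
    if cfg is None:
        cfg = RunConfig()
    regions = build_regions(masks)
    bundles = compute_trace_bundles(video, masks, regions)
    mats = [assemble_F_meas(regions, bundles, i) for i in range(len(regions))]
    raws = [bundles[r.neuron_id].raw_neuron for r in regions]
    if cfg.workers > 1:
        return Parallel(n_jobs=cfg.workers)(
            delayed(_unmix_one)(F, cfg, raw) for F, raw in zip(mats, raws)
        )
    return [_unmix_one(F, cfg, raw) for F, raw in zip(mats, raws)]
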