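"""Retention-index arithmetic against an n-alkane ladder.

The retention index (RI) places a compound on a dimensionless scale anchored
to n-alkanes: alkane C_n defines index 100*n, and a compound eluting between
the C_n and C_{n+1} alkanes is indexed by linear interpolation of its
retention time between the two alkane retention times,

    RI(t) = 100*n + 100 * (t - t_n) / (t_{n+1} - t_n),

the linear (van den Dool-Kratz) form appropriate for temperature-programmed
GC.  This module computes RIs from retention times, inverts the mapping to
predict retention times from database RIs, and reconstructs a ladder's node
retention times from observed (RI, RT) pairs when the alkane run itself is
not available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .errors import FitError, LadderError, RIRangeError

#: Default RI margin (in index units) beyond the terminal alkanes within
#: which linear extrapolation is still accepted, with a warning.
DEFAULT_EXTRAPOLATION_MARGIN = 50.0


class ExtrapolationWarning(UserWarning):
    """Raised when an RI/RT conversion leaves the ladder's span."""


@dataclass(frozen=True)
class AlkaneLadder:
    """An ordered set of (carbon number, retention time) calibration nodes.

    Parameters
    ----------
    nodes
        Sequence of ``(carbon_number, retention_time_min)`` tuples, with
        strictly increasing carbon numbers and strictly increasing retention
        times.  At least two nodes are required.
    """

    nodes: tuple[tuple[int, float], ...]

    def __init__(self, nodes: Iterable[tuple[int, float]]):
        nodes = tuple((int(c), float(t)) for c, t in nodes)
        if len(nodes) < 2:
            raise LadderError("an alkane ladder needs at least 2 nodes")
        carbons = np.array([c for c, _ in nodes])
        times = np.array([t for _, t in nodes])
        if np.any(np.diff(carbons) <= 0):
            raise LadderError("carbon numbers must be strictly increasing")
        if np.any(np.diff(times) <= 0):
            raise LadderError(
                "retention times must strictly increase with carbon number"
            )
        if np.any(times <= 0) or not np.all(np.isfinite(times)):
            raise LadderError("retention times must be positive and finite")
        object.__setattr__(self, "nodes", nodes)

    @property
    def carbons(self) -> np.ndarray:
        return np.array([c for c, _ in self.nodes])

    @property
    def times(self) -> np.ndarray:
        return np.array([t for _, t in self.nodes])

    @property
    def ri_nodes(self) -> np.ndarray:
        """Node positions on the RI scale (100 * carbon number)."""
        return 100.0 * self.carbons

    @property
    def span(self) -> tuple[float, float]:
        """(min, max) retention time covered by the ladder."""
        return self.nodes[0][1], self.nodes[-1][1]

    @property
    def ri_span(self) -> tuple[float, float]:
        return 100.0 * self.nodes[0][0], 100.0 * self.nodes[-1][0]

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlkaneLadder":
        """Read a ladder from a 2-column ``carbon,rt_min`` CSV file."""
        path = Path(path)
        lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        if not lines or lines[0].replace(" ", "") != "carbon,rt_min":
            raise LadderError(f"{path}: expected header 'carbon,rt_min'")
        nodes = []
        for i, ln in enumerate(lines[1:], start=2):
            parts = ln.split(",")
            if len(parts) != 2:
                raise LadderError(f"{path}:{i}: expected 2 columns")
            try:
                carbon = int(parts[0])
                rt = float(parts[1])
            except ValueError as exc:
                raise LadderError(f"{path}:{i}: {exc}") from exc
            nodes.append((carbon, rt))
        return cls(nodes)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        rows = ["carbon,rt_min"]
        rows += [f"{c},{t:.6f}" for c, t in self.nodes]
        path.write_text("\n".join(rows) + "\n")


def _check_ri_margin(ladder: AlkaneLadder, ri: float, margin: float) -> bool:
    """Return True if *ri* is outside the node span (extrapolating); raise
    beyond the accepted margin."""
    lo, hi = ladder.ri_span
    if ri < lo - margin or ri > hi + margin:
        raise RIRangeError(
            f"RI {ri:.1f} is beyond the ladder span [{lo:.0f}, {hi:.0f}] "
            f"± {margin:.0f} extrapolation margin"
        )
    return ri < lo or ri > hi


def compute_retention_index(
    ladder: AlkaneLadder,
    rt: float,
    extrapolation_margin: float = DEFAULT_EXTRAPOLATION_MARGIN,
) -> float:
    """Convert a retention time to a retention index.

    Piecewise-linear interpolation between ladder nodes; linear continuation
    of the terminal segments outside the node span, up to
    ``extrapolation_margin`` RI units (with an :class:`ExtrapolationWarning`).

    Parameters
    ----------
    ladder
        Calibration ladder.
    rt
        Retention time in minutes.

    Returns
    -------
    float
        Retention index on the 100*carbon scale; exactly ``100*n`` at the
        C_n node.
    """
    rt = float(rt)
    if not np.isfinite(rt) or rt <= 0:
        raise RIRangeError(f"retention time must be positive and finite, got {rt}")
    times = ladder.times
    ris = ladder.ri_nodes
    if times[0] <= rt <= times[-1]:
        return float(np.interp(rt, times, ris))
    # linear continuation of the terminal segment
    if rt < times[0]:
        slope = (ris[1] - ris[0]) / (times[1] - times[0])
        ri = ris[0] + slope * (rt - times[0])
    else:
        slope = (ris[-1] - ris[-2]) / (times[-1] - times[-2])
        ri = ris[-1] + slope * (rt - times[-1])
    _check_ri_margin(ladder, ri, extrapolation_margin)
    warnings.warn(
        f"retention time {rt:.3f} min is outside the ladder span; "
        f"RI {ri:.1f} obtained by extrapolation",
        ExtrapolationWarning,
        stacklevel=2,
    )
    return float(ri)


def predict_retention_time(
    ladder: AlkaneLadder,
    ri: float,
    extrapolation_margin: float = DEFAULT_EXTRAPOLATION_MARGIN,
) -> float:
    """Convert a retention index to a predicted retention time.

    Exact inverse of :func:`compute_retention_index` over the ladder span;
    returns the node retention time at ``ri = 100*n``.
    """
    ri = float(ri)
    if not np.isfinite(ri):
        raise RIRangeError(f"retention index must be finite, got {ri}")
    extrapolating = _check_ri_margin(ladder, ri, extrapolation_margin)
    times = ladder.times
    ris = ladder.ri_nodes
    if not extrapolating:
        return float(np.interp(ri, ris, times))
    if ri < ris[0]:
        slope = (times[1] - times[0]) / (ris[1] - ris[0])
        rt = times[0] + slope * (ri - ris[0])
    else:
        slope = (times[-1] - times[-2]) / (ris[-1] - ris[-2])
        rt = times[-1] + slope * (ri - ris[-1])
    warnings.warn(
        f"RI {ri:.1f} is outside the ladder span; predicted retention time "
        f"{rt:.3f} min obtained by extrapolation",
        ExtrapolationWarning,
        stacklevel=2,
    )
    return float(rt)


@dataclass
class LadderFit:
    """Result of :func:`fit_ladder_from_pairs`.

    Attributes
    ----------
    ladder
        The reconstructed ladder.
    ri, rt
        The (deduplicated) input pairs actually presented to the solver.
    residuals
        ``fitted_rt - rt`` per pair, in minutes.
    weights
        Robust weight given to each pair in the final solve (all 1.0 when
        ``robust=False``).
    used
        Boolean mask over the pairs: False for pairs rejected as outliers
        (robust weight 0).
    """

    ladder: AlkaneLadder
    ri: np.ndarray
    rt: np.ndarray
    residuals: np.ndarray
    weights: np.ndarray
    used: np.ndarray
    n_iterations: int = 1

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals[self.used])))


def _hat_weights(ri: np.ndarray, node_ris: np.ndarray) -> np.ndarray:
    """Design matrix mapping node retention times to pair retention times.

    Row i holds the piecewise-linear interpolation weights of pair i's RI
    over the ladder nodes (linear-extension weights outside the node span).
    """
    n_nodes = node_ris.size
    A = np.zeros((ri.size, n_nodes))
    seg = np.clip(np.searchsorted(node_ris, ri, side="right") - 1, 0, n_nodes - 2)
    f = (ri - node_ris[seg]) / (node_ris[seg + 1] - node_ris[seg])
    rows = np.arange(ri.size)
    A[rows, seg] = 1.0 - f
    A[rows, seg + 1] = f
    return A


def fit_ladder_from_pairs(
    pairs: Sequence[tuple[float, float]],
    robust: bool = False,
    carbons: Sequence[int] | None = None,
    smoothness: float = 1e-5,
    min_gap: float = 1e-3,
    robust_scale_floor: float = 0.003,
    max_iter: int = 20,
) -> LadderFit:
    """Reconstruct an alkane ladder from observed (RI, RT) pairs.

    Solves for node retention times minimising the squared residuals of the
    piecewise-linear RI -> RT map over the pairs, subject to strict
    monotonicity (node gaps >= ``min_gap`` min).  A small second-difference
    penalty (weight ``smoothness``) uniquely determines nodes in RI regions
    not covered by any pair, filling them by locally linear continuation; it
    is kept far below the data scale so that observed pairs dominate wherever
    they exist.

    With ``robust=True`` the fit is iteratively reweighted with Tukey's
    bisquare function on a MAD residual scale (floored at
    ``robust_scale_floor`` min, about the print precision of tabulated
    retention times).  Pairs whose residual exceeds ~4.7 robust standard
    deviations get zero weight; printed tables of measured RIs are known to
    contain occasional typographical inconsistencies and this rejects them
    without hand editing.

    Parameters
    ----------
    pairs
        ``(retention_index, retention_time_min)`` observations.  Duplicate
        RIs are averaged before fitting.
    carbons
        Carbon numbers of the nodes to reconstruct.  Default: the integer
        carbon range just covering the input RIs.

    Returns
    -------
    LadderFit
    """
    arr = np.asarray([(float(a), float(b)) for a, b in pairs], dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise FitError("need at least 2 (RI, RT) pairs")
    # average duplicate RIs
    order = np.argsort(arr[:, 0])
    ri_sorted, rt_sorted = arr[order, 0], arr[order, 1]
    uniq, inv = np.unique(ri_sorted, return_inverse=True)
    rt_mean = np.bincount(inv, weights=rt_sorted) / np.bincount(inv)
    ri, rt = uniq, rt_mean

    if carbons is None:
        lo = int(np.floor(ri.min() / 100.0))
        hi = int(np.ceil(ri.max() / 100.0))
        carbons = range(lo, hi + 1)
    carbons = np.asarray(sorted(set(int(c) for c in carbons)))
    if carbons.size < 2:
        raise FitError("ladder must contain at least 2 nodes")
    node_ris = 100.0 * carbons

    seg_of = np.clip(
        np.searchsorted(node_ris, ri, side="right") - 1, 0, carbons.size - 2
    )

    n = carbons.size
    A_data = _hat_weights(ri, node_ris)
    # parametrise node times as t_k = t_0 + sum of positive gaps so that
    # simple bounds enforce strict monotonicity
    T = np.zeros((n, n))
    T[:, 0] = 1.0
    for k in range(1, n):
        T[k, 1 : k + 1] = 1.0
    D = np.zeros((max(n - 2, 0), n))
    for j in range(n - 2):
        D[j, j + 1] = -1.0
        D[j, j + 2] = 1.0
    lb = np.full(n, min_gap)
    lb[0] = 1e-6
    ub = np.full(n, np.inf)

    def solve(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        active = w > 0
        if np.unique(seg_of[active]).size < 2:
            raise FitError(
                "pairs span a single ladder segment; the fit is degenerate"
            )
        sw = np.sqrt(w[active])[:, None]
        A = np.vstack([sw * (A_data[active] @ T), smoothness * D])
        b = np.concatenate([np.sqrt(w[active]) * rt[active], np.zeros(D.shape[0])])
        res = lsq_linear(A, b, bounds=(lb, ub), method="bvls")
        nodes_t = T @ res.x
        return nodes_t, A_data @ nodes_t - rt

    weights = np.ones(ri.size)
    nodes_t, resid = solve(weights)
    n_iter = 1
    if robust:
        c = 4.685  # Tukey bisquare tuning constant
        for _ in range(max_iter):
            scale = max(
                1.4826 * np.median(np.abs(resid - np.median(resid))),
                robust_scale_floor,
            )
            u = resid / (c * scale)
            new_w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
            if np.allclose(new_w, weights, atol=1e-6):
                break
            weights = new_w
            nodes_t, resid = solve(weights)
            n_iter += 1

    ladder = AlkaneLadder(list(zip(carbons.tolist(), nodes_t.tolist())))
    return LadderFit(
        ladder=ladder,
        ri=ri,
        rt=rt,
        residuals=resid,
        weights=weights,
        used=weights > 0,
        n_iterations=n_iter,
    )
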