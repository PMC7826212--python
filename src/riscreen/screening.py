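"""Prescreening of detected MRM peaks against a retention-annotated panel.

The screening rule is the heart of the retention-index workflow: a panel
entry is *hit* when a peak on its quantifier transition lies within a small
window of the entry's predicted retention time, and *confirmed* when the
qualifier transition shows a co-eluting peak as well (optionally also
requiring the qualifier/quantifier area ratio to match a reference).

Many entries share identical ion pairs (all cypermethrin and cyfluthrin
isomers, the DDT family, the BHC isomers ...), so transitions alone cannot
tell them apart; assignment within such a shared-transition group is a
global, order-preserving, minimum-total-deviation matching between the
predicted retention times and the observed apexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatogram import Peak
from .errors import PanelError, ScheduleError
from .pesticide_db import AnnotatedPanel, MRMTransition, PesticideRecord

DEFAULT_RT_WINDOW = 0.05  # min; ~2.5x the largest verified prediction deviation
DEFAULT_COELUTION_TOL = 0.01  # min; quantifier/qualifier apex agreement
SEGMENT_GRID = 0.01  # min; MRM segment boundaries snap to this grid


@dataclass(frozen=True)
class ScreenHit:
    """A panel entry matched to an observed peak."""

    entry_name: str
    base_name: str
    predicted_rt: float
    observed_rt: float
    quantifier_peak: Peak
    qualifier_peak: Peak | None
    ion_ratio: float | None
    confirmed: bool
    sample_id: str = ""

    @property
    def deviation(self) -> float:
        return abs(self.predicted_rt - self.observed_rt)


@dataclass(frozen=True)
class MRMSegment:
    """One acquisition time segment and the transitions monitored in it."""

    start_rt: float
    end_rt: float
    transitions: tuple[tuple[str, MRMTransition], ...]

    def __post_init__(self):
        if not self.start_rt < self.end_rt:
            raise ScheduleError("segment start must precede end")

    @property
    def n_concurrent(self) -> int:
        return len(self.transitions)


def assign_order_preserving(
    predicted: Sequence[float],
    observed: Sequence[float],
    window: float,
) -> list[tuple[int, int]]:
    """Order-preserving assignment of observed apexes to predictions.

    Maximises the number of matched pairs with |deviation| <= ``window``,
    then minimises the total absolute deviation; remaining ties are broken
    toward matching earlier predictions (and then earlier peaks).  Both
    inputs must be sorted ascending.  Returns ``(prediction_idx, peak_idx)``
    pairs.

    This is a classic monotone-alignment dynamic programme; it reproduces
    the brute-force optimum over all order-preserving matchings.
    """
    m, n = len(predicted), len(observed)
    # dp[i][j]: best (negative matches, total deviation, pred-index sum,
    # peak-index sum) using predictions[:i] and observed[:j]
    dp = [[None] * (n + 1) for _ in range(m + 1)]
    choice = [[None] * (n + 1) for _ in range(m + 1)]
    dp[0] = [(0, 0.0, 0, 0)] * (n + 1)
    for i in range(1, m + 1):
        dp[i][0] = (0, 0.0, 0, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best, how = (dp[i - 1][j], "skip_pred")
            cand = dp[i][j - 1]
            if cand < best:
                best, how = cand, "skip_peak"
            dev = abs(predicted[i - 1] - observed[j - 1])
            if dev <= window:
                prev = dp[i - 1][j - 1]
                cand = (prev[0] - 1, prev[1] + dev, prev[2] + (i - 1), prev[3] + (j - 1))
                if cand < best:
                    best, how = cand, "match"
            dp[i][j] = best
            choice[i][j] = how
    pairs = []
    i, j = m, n
    while i > 0 and j > 0:
        how = choice[i][j]
        if how == "match":
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif how == "skip_pred":
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def resolve_isomers(
    predicted_rts: Sequence[float],
    peak_rts: Sequence[float],
    window: float = DEFAULT_RT_WINDOW,
) -> list[tuple[int, int]]:
    """Elution-order assignment of k observed peaks to m isomer predictions
    sharing one transition set.  See :func:`assign_order_preserving`;
    unmatched predictions are reported absent (simply not returned)."""
    return assign_order_preserving(predicted_rts, peak_rts, window)


def _nearest_peak(peaks: Sequence[Peak], rt: float) -> Peak | None:
    if not peaks:
        return None
    return min(peaks, key=lambda p: abs(p.apex_rt - rt))


def screen_sample(
    peaks_by_transition: Mapping[MRMTransition, Sequence[Peak]],
    panel: AnnotatedPanel,
    rt_window: float = DEFAULT_RT_WINDOW,
    ion_ratio_tol: float | None = None,
    reference_ion_ratios: Mapping[str, float] | None = None,
    coelution_tol: float = DEFAULT_COELUTION_TOL,
    sample_id: str = "",
    include_internal_standard: bool = False,
) -> list[ScreenHit]:
    """Match detected peaks to panel entries by predicted RT and ion pairs.

    For each shared-quantifier-transition group of panel entries, the
    observed quantifier peaks within ``rt_window`` of the predicted RTs are
    assigned by order-preserving minimum-deviation matching (one peak
    satisfies at most one entry).  A hit is *confirmed* when a qualifier
    peak co-elutes with the quantifier apex (within ``coelution_tol``) and
    lies within the RT window of the prediction; if ``ion_ratio_tol`` is
    given, the qualifier/quantifier area ratio must additionally agree with
    the entry's reference ratio to within that relative tolerance.
    """
    if not isinstance(panel, AnnotatedPanel):
        raise PanelError("screen_sample requires an annotated panel")
    if rt_window <= 0:
        raise ValueError("rt_window must be positive")

    peaks_by_key: dict[tuple[float, float], list[Peak]] = {}
    for tr, pks in peaks_by_transition.items():
        peaks_by_key.setdefault(tr.key, []).extend(pks)
    for key in peaks_by_key:
        peaks_by_key[key] = sorted(peaks_by_key[key], key=lambda p: p.apex_rt)

    groups: dict[tuple[float, float], list[PesticideRecord]] = {}
    for rec in panel.records:
        if rec.is_internal_standard and not include_internal_standard:
            continue
        groups.setdefault(rec.quantifier.key, []).append(rec)

    hits: list[ScreenHit] = []
    for qkey, recs in groups.items():
        recs = sorted(recs, key=lambda r: panel.predicted_rt(r.entry_name))
        preds = [panel.predicted_rt(r.entry_name) for r in recs]
        qpeaks = peaks_by_key.get(qkey, [])
        for ip, jp in assign_order_preserving(preds, [p.apex_rt for p in qpeaks], rt_window):
            rec, quant = recs[ip], qpeaks[jp]
            qual_candidates = peaks_by_key.get(rec.qualifier.key, [])
            qual = _nearest_peak(qual_candidates, quant.apex_rt)
            confirmed = False
            ion_ratio = None
            if qual is not None:
                coelutes = abs(qual.apex_rt - quant.apex_rt) <= coelution_tol
                in_window = abs(qual.apex_rt - preds[ip]) <= rt_window
                if coelutes and in_window:
                    confirmed = True
                    ion_ratio = qual.area / quant.area if quant.area > 0 else None
                    if ion_ratio_tol is not None and reference_ion_ratios is not None:
                        ref = reference_ion_ratios.get(rec.entry_name)
                        if ref:
                            confirmed = abs(ion_ratio - ref) <= ion_ratio_tol * ref
                else:
                    qual = None
            hits.append(
                ScreenHit(
                    entry_name=rec.entry_name,
                    base_name=rec.base_name,
                    predicted_rt=preds[ip],
                    observed_rt=quant.apex_rt,
                    quantifier_peak=quant,
                    qualifier_peak=qual,
                    ion_ratio=ion_ratio,
                    confirmed=confirmed,
                    sample_id=sample_id,
                )
            )
    return sorted(hits, key=lambda h: h.predicted_rt)


def build_mrm_schedule(
    panel: AnnotatedPanel,
    window: float = 0.5,
    max_concurrent: int = 40,
    run_start: float = 5.0,
    run_end: float = 25.0,
) -> list[MRMSegment]:
    """Greedy left-to-right time segmentation of the MRM acquisition.

    Every transition's interval [predicted RT - window, predicted RT +
    window] must sit entirely inside one segment; overlapping intervals are
    therefore clustered, each cluster becomes a segment, and boundaries are
    placed midway between adjacent clusters (snapped to a 0.01-min grid).
    The outer segments are widened to cover the full ``run_start`` to
    ``run_end`` acquisition span.
    """
    if window <= 0:
        raise ScheduleError("window must be positive")
    items = []
    for rec in panel.records:
        rt = panel.predicted_rt(rec.entry_name)
        for tr in rec.transitions:
            items.append((rt - window, rt + window, rec.entry_name, tr))
    if not items:
        return []
    items.sort(key=lambda x: x[0])
    clusters: list[list] = [[items[0]]]
    reach = items[0][1]
    for it in items[1:]:
        if it[0] <= reach:
            clusters[-1].append(it)
            reach = max(reach, it[1])
        else:
            clusters.append([it])
            reach = it[1]
    # check concurrency cluster by cluster
    for cl in clusters:
        if len(cl) > max_concurrent:
            lo = min(x[0] for x in cl)
            hi = max(x[1] for x in cl)
            names = sorted({x[2] for x in cl})
            raise ScheduleError(
                f"cluster {lo:.2f}-{hi:.2f} min needs {len(cl)} concurrent "
                f"transitions (> {max_concurrent}): {', '.join(names)}"
            )

    def snap(x: float) -> float:
        return round(round(x / SEGMENT_GRID) * SEGMENT_GRID, 10)

    bounds = [min(run_start, snap(clusters[0][0][0]))]
    for a, b in zip(clusters, clusters[1:]):
        gap_mid = (max(x[1] for x in a) + min(x[0] for x in b)) / 2.0
        bounds.append(snap(gap_mid))
    bounds.append(max(run_end, snap(max(x[1] for x in clusters[-1]))))
    segments = []
    for (s, e), cl in zip(zip(bounds, bounds[1:]), clusters):
        segments.append(
            MRMSegment(
                start_rt=s,
                end_rt=e,
                transitions=tuple((name, tr) for _, _, name, tr in cl),
            )
        )
    return segments


def summarize_study(
    hits_by_sample: Mapping[str, Sequence[ScreenHit]],
    panel: AnnotatedPanel,
) -> pd.DataFrame:
    """Samples x pesticide detection matrix of confirmed hits.

    Cell values count confirmed hits of that base name in that sample
    (isomer entries pool into their base name).
    """
    bases = sorted(
        {r.base_name for r in panel.records if not r.is_internal_standard}
    )
    mat = pd.DataFrame(
        0, index=sorted(hits_by_sample.keys()), columns=bases, dtype=int
    )
    for sid, hits in hits_by_sample.items():
        for h in hits:
            if h.confirmed and h.base_name in mat.columns:
                mat.loc[sid, h.base_name] += 1
    return mat


def positive_counts(detection_matrix: pd.DataFrame) -> pd.Series:
    """Per-pesticide number of samples with at least one confirmed hit."""
    return (detection_matrix > 0).sum(axis=0)
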