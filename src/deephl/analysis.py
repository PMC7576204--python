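"""Attention analysis: layer ranking, trajectory screening, correlation with
handcrafted features and within-highlight distribution differences.

Layer score.  For layer *i* with attention-vector sets A_A (class A) and A_B
(class B), the score is s = s_fc + s_it where

    s_fc = sqrt( (1 / (|A| * mean_length(A))) * sum_{a in A} Var(a) ),
           A = A_A union A_B,

rewarding layers whose attention is concentrated on limited segments (the
softmax makes variance scale with 1/length, hence the length normalization),
and

    s_it = 1 - Intersect(h(A_A), h(A_B)),
    Intersect(H1, H2) = sum_i min(H1(i), H2(i)),

with h(.) a normalized 200-bin histogram over the pooled range of both
classes, rewarding layers that attend differently to the two classes.
Variance is the population variance over valid steps.

Trajectory screening uses V(a), the variance of a trajectory's attention: a
near-uniform vector means the layer found nothing localized there.

Highlight masks take a step as attended when its attention exceeds
c / (number of valid time slices) with c = 1.2; uniform attention (1/T) is
below this threshold everywhere, so such trajectories contribute no attended
steps.  The within-highlight distribution difference of a feature between
classes is 1 minus the histogram intersection of the feature values extracted
under those masks (200 bins over their pooled range); it is undefined when a
class has no attended step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FeatureSeriesSet, moving_stats, DEFAULT_WINDOW

__all__ = [
    "Histogram",
    "MaskRule",
    "make_histogram",
    "intersect",
    "score_fc",
    "score_it",
    "rank_layers",
    "trajectory_score",
    "trajectory_score_table",
    "highlight_mask",
    "correlate",
    "dist_diff",
    "dist_diff_table",
    "N_BINS",
    "DERIVATIONS",
]

N_BINS = 200
DERIVATIONS = ("raw", "moving_average", "moving_variance", "derivative")


@dataclass
class Histogram:
    frequencies: np.ndarray  # normalized, sums to 1
    edges: np.ndarray


@dataclass(frozen=True)
class MaskRule:
    """Attended-step rule: attention > c / (# valid time slices)."""

    c: float = 1.2

    def threshold(self, valid_length: int) -> float:
        return self.c / valid_length


def make_histogram(values: np.ndarray, value_range: tuple[float, float],
                   bins: int = N_BINS) -> Histogram:
    values = np.asarray(values, dtype=float)
    lo, hi = value_range
    if hi <= lo:  # degenerate support: widen so all mass lands in one bin
        lo, hi = lo - 0.5, lo + 0.5
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    freq = counts / counts.sum() if counts.sum() else counts.astype(float)
    return Histogram(frequencies=freq, edges=edges)


def intersect(h1: Histogram, h2: Histogram) -> float:
    """Histogram intersection: sum of binwise minima, in [0, 1]."""
    if h1.frequencies.shape != h2.frequencies.shape or not np.allclose(h1.edges, h2.edges):
        raise ValidationError("histograms must share binning")
    return float(np.minimum(h1.frequencies, h2.frequencies).sum())


def _variance(a: np.ndarray) -> float:
    return float(np.var(np.asarray(a, dtype=float)))  # population variance


def trajectory_score(a: np.ndarray) -> float:
    """V(a): variance of a trajectory's (valid-length) attention vector."""
    return _variance(a)


def score_fc(A_A: list[np.ndarray], A_B: list[np.ndarray]) -> float:
    """Length-normalized root-mean attention variance over both classes."""
    pool = list(A_A) + list(A_B)
    if not pool:
        raise ValidationError("empty attention sets")
    mean_len = float(np.mean([len(a) for a in pool]))
    return float(np.sqrt(sum(_variance(a) for a in pool) / (len(pool) * mean_len)))


def score_it(A_A: list[np.ndarray], A_B: list[np.ndarray]) -> float:
    """1 - intersection of the two classes' pooled attention histograms."""
    if not A_A or not A_B:
        raise ValidationError("both classes need attention vectors")
    pa = np.concatenate([np.asarray(a, dtype=float) for a in A_A])
    pb = np.concatenate([np.asarray(a, dtype=float) for a in A_B])
    rng = (float(min(pa.min(), pb.min())), float(max(pa.max(), pb.max())))
    return 1.0 - intersect(make_histogram(pa, rng), make_histogram(pb, rng))


def rank_layers(attention_sets: dict) -> pd.DataFrame:
    """Score every layer and sort descending by s = s_fc + s_it.

    ``attention_sets`` maps layer id -> (A_A, A_B), each a list of trimmed
    attention vectors.  Ties keep the architectural order (convolutional
    stacks first, shallow to deep), which is the insertion order of the dict.
    """
    rows = []
    for lid, (A_A, A_B) in attention_sets.items():
        fc = score_fc(A_A, A_B)
        it = score_it(A_A, A_B)
        rows.append({"layer": lid, "s_fc": fc, "s_it": it, "s": fc + it})
    df = pd.DataFrame(rows)
    df = df.sort_values("s", ascending=False, kind="stable").reset_index(drop=True)
    df.index.name = "rank"
    return df


def trajectory_score_table(attentions: dict) -> pd.DataFrame:
    """Per-trajectory screening scores V(a) for one layer, sorted descending.

    ``attentions`` maps trajectory id -> trimmed attention vector.
    """
    rows = [{"trajectory_id": tid, "V": trajectory_score(a)} for tid, a in attentions.items()]
    return pd.DataFrame(rows).sort_values("V", ascending=False, kind="stable").reset_index(drop=True)


def highlight_mask(a: np.ndarray, rule: MaskRule = MaskRule()) -> np.ndarray:
    """Boolean attended-step mask of a trimmed attention vector."""
    a = np.asarray(a, dtype=float)
    return a > rule.threshold(len(a))


def _derived(series: np.ndarray, derivation: str, window: int, dt: float) -> np.ndarray:
    if derivation == "raw":
        return np.asarray(series, dtype=float)
    mavg, mvar, deriv = moving_stats(series, window=window, dt=dt)
    return {"moving_average": mavg, "moving_variance": mvar, "derivative": deriv}[derivation]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")  # undefined, reported as NaN rather than raised
    return float(np.corrcoef(x, y)[0, 1])


def correlate(attentions: dict, feature_set: FeatureSeriesSet,
              derivations: tuple = DERIVATIONS, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Pearson correlation of attention with every (feature, derivation) pair.

    ``attentions`` maps trajectory id -> trimmed attention vector aligned with
    the feature series.  Values are pooled over the concatenated valid steps
    of all trajectories; per-class coefficients are reported alongside the
    overall one.  Rows are sorted by |r| (overall), the ranking used to pick
    the explanatory feature.
    """
    tids = [tid for tid in feature_set.series if tid in attentions]
    if not tids:
        raise ValidationError("no overlap between attention and feature trajectories")
    for tid in tids:
        n_att = len(attentions[tid])
        n_feat = len(next(iter(feature_set.series[tid].values())))
        if n_att != n_feat:
            raise ValidationError(
                f"trajectory {tid}: attention length {n_att} != feature length {n_feat}")
    classes = sorted(set(feature_set.labels[tid] for tid in tids))
    rows = []
    for ch in feature_set.channel_names:
        for der in derivations:
            pooled: dict[str, list] = {c: [] for c in classes}
            att_pooled: dict[str, list] = {c: [] for c in classes}
            for tid in tids:
                series = _derived(feature_set.series[tid][ch], der, window, feature_set.dt[tid])
                c = feature_set.labels[tid]
                pooled[c].append(series)
                att_pooled[c].append(np.asarray(attentions[tid], dtype=float))
            x_all = np.concatenate([v for c in classes for v in pooled[c]])
            a_all = np.concatenate([v for c in classes for v in att_pooled[c]])
            row = {"feature": ch, "derivation": der, "r": _pearson(x_all, a_all)}
            for c in classes:
                row[f"r_{c}"] = _pearson(np.concatenate(pooled[c]), np.concatenate(att_pooled[c]))
            rows.append(row)
    df = pd.DataFrame(rows)
    df["abs_r"] = df["r"].abs()
    return df.sort_values("abs_r", ascending=False, kind="stable").reset_index(drop=True)


def dist_diff(A_A: list[np.ndarray], F_A: list[np.ndarray],
              A_B: list[np.ndarray], F_B: list[np.ndarray],
              rule: MaskRule = MaskRule(), bins: int = N_BINS) -> float:
    """Distribution difference of a feature between classes within highlights.

    Returns ``1 - Intersect`` of the 200-bin histograms of the feature values
    at attended steps of each class, or NaN when either class has no attended
    step (e.g. uniform attention never exceeds 1.2/T).
    """
    def extract(atts, feats):
        vals = []
        for a, f in zip(atts, feats):
            a = np.asarray(a, dtype=float)
            f = np.asarray(f, dtype=float)
            if len(a) != len(f):
                raise ValidationError("attention/feature length mismatch")
            vals.append(f[highlight_mask(a, rule)])
        return np.concatenate(vals) if vals else np.array([])

    va, vb = extract(A_A, F_A), extract(A_B, F_B)
    if va.size == 0 or vb.size == 0:
        return float("nan")
    rng = (float(min(va.min(), vb.min())), float(max(va.max(), vb.max())))
    return 1.0 - intersect(make_histogram(va, rng, bins), make_histogram(vb, rng, bins))


def dist_diff_table(attentions: dict, feature_set: FeatureSeriesSet,
                    rule: MaskRule = MaskRule(), derivations: tuple = DERIVATIONS,
                    window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Within-highlight distribution difference for every feature/derivation."""
    tids = [tid for tid in feature_set.series if tid in attentions]
    classes = sorted(set(feature_set.labels[tid] for tid in tids))
    if len(classes) != 2:
        raise ValidationError("two classes required")
    rows = []
    for ch in feature_set.channel_names:
        for der in derivations:
            A, F = {c: [] for c in classes}, {c: [] for c in classes}
            for tid in tids:
                c = feature_set.labels[tid]
                A[c].append(attentions[tid])
                F[c].append(_derived(feature_set.series[tid][ch], der, window,
                                     feature_set.dt[tid]))
            d = dist_diff(A[classes[0]], F[classes[0]], A[classes[1]], F[classes[1]], rule)
            rows.append({"feature": ch, "derivation": der, "diff": d})
    return (pd.DataFrame(rows).sort_values("diff", ascending=False, kind="stable")
            .reset_index(drop=True))


def attention_sets_by_class(result_attentions: dict, tensors: list) -> dict:
    """Partition per-layer batch attentions into per-class trimmed vectors.

    ``result_attentions`` is ForwardResult.attentions (layer -> (B, T));
    ``tensors`` the FeatureTensor batch in the same order.  Returns
    layer -> (A_first, A_second) with class labels sorted.
    """
    classes = sorted({ft.label for ft in tensors})
    out = {}
    for lid, mat in result_attentions.items():
        per_class = {c: [] for c in classes}
        for k, ft in enumerate(tensors):
            per_class[ft.label].append(mat[k, :ft.valid_length])
        out[lid] = tuple(per_class[c] for c in classes)
    return out


def trimmed_attentions(result_attentions: dict, tensors: list, layer: str) -> dict:
    """trajectory id -> trimmed attention vector for one layer."""
    mat = result_attentions[layer]
    return {ft.trajectory_id: mat[k, :ft.valid_length] for k, ft in enumerate(tensors)}
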