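"""Occlusion relevance: which sequence windows drive the prediction.

For a trained model with prediction Y on the intact input, sliding
10-bp windows of the one-hot regulatory sequence are zeroed out and the
relevance of each window is (Y - Y_occluded) / Y. Per-position profiles
average over the windows covering the position; positions whose
relevance exceeds +/- 2 cohort-level standard deviations are flagged as
significant. Profiles can be grouped by consensus clustering (PAM on
1 - Pearson r, repeated on 80% subsamples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import REGULATORY_REGIONS, RegionLengths


@dataclass
class RelevanceProfile:
    gene_id: str
    values: dict[str, np.ndarray]  # region -> per-position relevance
    y_intact: float
    window: int = 10
    unscaled: bool = False  # |Y| < eps: values are Y - Y_occluded
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    #: optional (region, start, width, relevance) per occlusion window
    window_relevance: list[tuple[str, int, int, float]] | None = None

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[r] for r in REGULATORY_REGIONS])


def occlude(onehot: np.ndarray, start: int, width: int) -> np.ndarray:
    """Return a copy with columns [start, start+width) zeroed."""
    L = onehot.shape[1]
    if start < 0 or width < 0 or start + width > L:
        raise ValueError(f"window [{start}, {start + width}) outside length {L}")
    out = onehot.copy()
    out[:, start : start + width] = 0.0
    return out


def relevance_profile(
    model,
    x_seq: np.ndarray,
    x_num: np.ndarray,
    gene_id: str,
    lengths: RegionLengths,
    window: int = 10,
    stride: int = 1,
    eps: float = 1e-6,
    whole_regions: bool = False,
    batch: int = 512,
    y_offset: float = 0.0,
    fast: bool = True,
    keep_window_relevance: bool = False,
) -> RelevanceProfile:
    """Occlusion relevance profile for one gene.

    ``x_seq`` is the 4 x L concatenated one-hot; numeric features are
    held at their true values throughout (sequence attribution only).
    ``whole_regions=True`` occludes each region in one block instead of
    sliding windows. ``y_offset`` shifts predictions onto the positive
    (pre-length-correction) Box-Cox scale before the ratio is taken,
    so the denominator Y stays away from zero for length-residual
    targets; pass the gene's fitted length term.
    """
    y = float(model.predict(x_seq[None], x_num[None])[0]) + y_offset
    spans = lengths.offsets()

    starts: list[tuple[str, int, int]] = []  # (region, start, width)
    for region in REGULATORY_REGIONS:
        lo, hi = spans[region]
        if whole_regions:
            starts.append((region, lo, hi - lo))
        else:
            w = min(window, hi - lo)
            for s in range(lo, hi - w + 1, stride):
                starts.append((region, s, w))

    preds = None
    if fast and not whole_regions:
        preds = fast_window_predictions(model, x_seq, x_num, starts)
    if preds is None:
        occluded = np.empty((len(starts), *x_seq.shape), dtype=x_seq.dtype)
        for i, (_, s, w) in enumerate(starts):
            occluded[i] = x_seq
            occluded[i][:, s : s + w] = 0.0
        preds = np.concatenate(
            [
                model.predict(occluded[i : i + batch],
                              np.repeat(x_num[None], min(batch, len(starts) - i), axis=0))
                for i in range(0, len(starts), batch)
            ]
        )
    preds = preds + y_offset

    unscaled = abs(y) < eps
    window_rel = (y - preds) if unscaled else (y - preds) / y

    values: dict[str, np.ndarray] = {}
    for region in REGULATORY_REGIONS:
        lo, hi = spans[region]
        acc = np.zeros(hi - lo)
        cnt = np.zeros(hi - lo)
        for (reg, s, w), rel in zip(starts, window_rel):
            if reg != region:
                continue
            acc[s - lo : s - lo + w] += rel
            cnt[s - lo : s - lo + w] += 1
        with np.errstate(invalid="ignore"):
            values[region] = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    per_window = (
        [(reg, s, w, float(rel))
         for (reg, s, w), rel in zip(starts, window_rel)]
        if keep_window_relevance else None
    )
    return RelevanceProfile(gene_id, values, y, window, unscaled,
                            window_relevance=per_window)


def significant_positions(
    profiles: list[RelevanceProfile], cutoff_sd: float = 2.0
) -> dict[str, dict[str, np.ndarray]]:
    """Mask positions whose relevance is >= ``cutoff_sd`` cohort SDs from
    the cohort mean, z-scored per region across all genes. Masks are
    also written back onto each profile."""
    import warnings

    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    masks: dict[str, dict[str, np.ndarray]] = {}
    stats = {}
    for region in REGULATORY_REGIONS:
        pooled = np.concatenate([p.values[region] for p in profiles])
        mu, sd = float(pooled.mean()), float(pooled.std())
        stats[region] = (mu, sd)
        if sd == 0:
            warnings.warn(f"zero relevance variance in {region}; empty masks")
    for p in profiles:
        masks[p.gene_id] = {}
        for region in REGULATORY_REGIONS:
            mu, sd = stats[region]
            if sd == 0:
                m = np.zeros_like(p.values[region], dtype=bool)
            else:
                m = np.abs((p.values[region] - mu) / sd) >= cutoff_sd
            masks[p.gene_id][region] = m
            p.mask[region] = m
    return masks


def average_profiles(
    profile_sets: list[list[RelevanceProfile]],
) -> list[RelevanceProfile]:
    """Element-wise mean of aligned relevance profiles from several
    models (same genes, same order)."""
    out = []
    for group in zip(*profile_sets):
        first = group[0]
        vals = {r: np.mean([p.values[r] for p in group], axis=0)
                for r in first.values}
        out.append(RelevanceProfile(
            first.gene_id, vals, float(np.mean([p.y_intact for p in group])),
            first.window))
    return out


def ensemble_masks(
    profile_sets: list[list[RelevanceProfile]],
    cutoff_sd: float = 2.0,
) -> tuple[dict, dict]:
    """Two-tier significance from an ensemble of attribution models.

    Each model's profiles are masked at ``cutoff_sd`` separately; the
    *reproducible* set is their intersection (a position must be
    significant in every model), the *candidate* set their union.
    Reproducible calls are what we report as significant; candidate
    calls feed motif discovery, whose clustering and minimum cluster
    size control the extra noise downstream.
    """
    per_model = [significant_positions(p, cutoff_sd) for p in profile_sets]
    genes = per_model[0].keys()
    reproducible, candidate = {}, {}
    for g in genes:
        reproducible[g], candidate[g] = {}, {}
        for region in per_model[0][g]:
            stack = [m[g][region] for m in per_model]
            reproducible[g][region] = np.logical_and.reduce(stack)
            candidate[g][region] = np.logical_or.reduce(stack)
    return reproducible, candidate


# ---------------------------------------------------------------------------
# fast occlusion for conv + global-max-pool sequence branches


def _fast_layout(model):
    """Return (net, conv, head_layers, scale) when the model's sequence
    branch is exactly Conv1D -> ReLU -> global MaxPool -> Flatten and
    the head is batch-norm/dropout-free; otherwise None."""
    from . import nn as _nn
    from .models import RegressionModel, SequenceView

    if isinstance(model, SequenceView):
        base = model.model
        weights = base.warmup_weights
    elif isinstance(model, RegressionModel):
        base = model
        weights = None
    else:
        return None
    layers = base.net.seq_branch.layers
    if not (len(layers) == 4
            and isinstance(layers[0], _nn.Conv1D)
            and isinstance(layers[1], _nn.ReLU)
            and isinstance(layers[2], _nn.MaxPool1D)
            and isinstance(layers[3], _nn.Flatten)):
        return None
    for l in base.net.head.layers:
        if not isinstance(l, (_nn.Dense, _nn.ReLU)):
            return None
    return base, weights


def fast_window_predictions(
    model, x_seq: np.ndarray, x_num: np.ndarray,
    starts: list[tuple[str, int, int]],
) -> np.ndarray | None:
    """Occluded-window predictions via incremental convolution.

    Zeroing columns [s, s+w) only changes conv outputs in
    [s-K+1, s+w-1]; with global max pooling the new pooled feature is
    the max of cached prefix/suffix maxima and the recomputed stripe.
    Returns None when the architecture does not admit the fast path.
    """
    from .models import SequenceView

    layout = _fast_layout(model)
    if layout is None:
        return None
    base, swap_weights = layout
    net = base.net
    saved = None
    if swap_weights is not None:
        saved = net.get_weights()
        net.set_weights(swap_weights)
    try:
        conv = net.seq_branch.layers[0]
        W, b = conv.W, conv.b  # (F, C, K), (F,)
        F, C, K = W.shape
        L = x_seq.shape[1]
        Lc = L - K + 1
        if net.seq_branch.layers[2].width != Lc:
            return None
        x32 = x_seq.astype(np.float32)
        if isinstance(model, SequenceView):
            xn_std = np.zeros(base.n_numeric, dtype=np.float32)
        else:
            xn_std = ((x_num - base.num_mean) / base.num_sd).astype(np.float32)

        cols = np.lib.stride_tricks.sliding_window_view(x32, K, axis=1)
        cols = cols.transpose(1, 0, 2).reshape(Lc, C * K)
        A = np.maximum(cols @ W.reshape(F, -1).T + b, 0.0)  # (Lc, F) post-ReLU
        prefix = np.maximum.accumulate(A, axis=0)
        suffix = np.maximum.accumulate(A[::-1], axis=0)[::-1]

        feats = np.empty((len(starts), F), dtype=np.float32)
        for i, (_, s, w) in enumerate(starts):
            lo = max(0, s - K + 1)
            hi = min(Lc, s + w)  # affected conv columns [lo, hi)
            xo = x32[:, lo : hi + K - 1].copy()
            z0 = max(0, s - lo)
            xo[:, z0 : z0 + w] = 0.0
            sub = np.lib.stride_tricks.sliding_window_view(xo, K, axis=1)
            sub = sub.transpose(1, 0, 2).reshape(hi - lo, C * K)
            stripe = np.maximum(sub @ W.reshape(F, -1).T + b, 0.0)
            m = stripe.max(axis=0)
            if lo > 0:
                m = np.maximum(m, prefix[lo - 1])
            if hi < Lc:
                m = np.maximum(m, suffix[hi])
            feats[i] = m
        z = np.concatenate(
            [feats, np.tile(xn_std, (len(starts), 1))], axis=1)
        out = net.head.forward(z, False)[:, 0]
        return out * base.y_sd + base.y_mean
    finally:
        if saved is not None:
            net.set_weights(saved)


# ---------------------------------------------------------------------------
# consensus clustering of relevance profiles


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    sd[sd == 0] = 1.0
    corr = (Xc @ Xc.T) / np.outer(sd, sd)
    return 1.0 - np.clip(corr, -1.0, 1.0)


def pam(dist: np.ndarray, k: int, rng: np.random.Generator,
        max_iter: int = 50) -> np.ndarray:
    """Partition around medoids on a precomputed distance matrix
    (alternating assignment / medoid-update)."""
    n = dist.shape[0]
    medoids = list(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = []
        for c in range(k):
            members = np.where(labels == c)[0]
            if members.size == 0:
                new_medoids.append(medoids[c])
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[np.argmin(within)]))
        if new_medoids == medoids:
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)


def consensus_cluster(
    profiles: list[RelevanceProfile] | np.ndarray,
    k_range: tuple[int, int] = (2, 6),
    reps: int = 50,
    subsample: float = 0.8,
    seed: int = 0,
    gain_threshold: float = 0.10,
) -> dict:
    """Consensus clustering of relevance profiles.

    For each k, PAM is run ``reps`` times on 1 - Pearson r distances of
    an 80% subsample; consensus(i, j) is the co-clustering frequency
    over runs sampling both i and j. The selected k is the smallest k
    whose relative gain in mean consensus over k-1 falls below
    ``gain_threshold``. Final labels come from PAM on (1 - consensus).
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    X = (np.stack([p.concat() for p in profiles])
         if not isinstance(profiles, np.ndarray) else profiles)
    n = X.shape[0]
    dist = _pearson_distance(X)
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))

    results = {}
    for k in range(k_range[0], k_range[1] + 1):
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            labels = pam(dist[np.ix_(idx, idx)], k, rng)
            same = labels[:, None] == labels[None, :]
            sampled[np.ix_(idx, idx)] += 1
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2
        results[k] = consensus

    # mean within-pair consensus as the stability statistic
    scores = {k: float(np.mean(c[np.triu_indices(n, 1)] ** 2)) for k, c in results.items()}
    selected = k_range[1]
    prev = None
    for k in sorted(results):
        if prev is not None:
            gain = (scores[k] - prev) / max(abs(prev), 1e-12)
            if gain < gain_threshold:
                selected = k - 1 if k > k_range[0] else k
                break
        prev = scores[k]
    else:
        selected = max(results)

    labels = pam(1.0 - results[selected], selected, np.random.default_rng(seed + 1))
    return {
        "k": selected,
        "labels": labels,
        "consensus": results,
        "scores": scores,
    }
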