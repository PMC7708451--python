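"""From relevant sequence windows to position weight matrices.

Significant relevance positions are tiled into fixed-width windows,
clustered by greedy sequence identity (CD-HIT-like, ungapped, with a
small +/-2 bp alignment drift), and each cluster of at least 5 members
becomes a PWM. Columns get a 0.25 pseudocount per base; information
content is computed against a uniform background and edges below
0.2 bits are trimmed. PWM pairs are compared by the best ungapped
column-correlation overlap with a column-shuffling permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import BASES, REGULATORY_REGIONS
from .relevance import RelevanceProfile


@dataclass
class RelevantWindow:
    gene_id: str
    region: str
    offset: int
    sequence: str
    mean_relevance: float


@dataclass
class Motif:
    motif_id: str
    region: str
    pwm: np.ndarray  # 4 x w probability matrix
    members: list[RelevantWindow]
    member_shifts: list[int] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    def information_content(self) -> np.ndarray:
        p = np.clip(self.pwm, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=0)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.pwm, axis=0))


# ---------------------------------------------------------------------------
# window extraction


def extract_windows(
    profiles: list[RelevanceProfile],
    masks: dict[str, dict[str, np.ndarray]],
    sequences: dict[str, dict[str, str]],
    window: int = 10,
) -> list[RelevantWindow]:
    """Tile maximal significant runs into ``window``-bp sequences.

    Runs longer than the window are tiled left to right with a final
    right-aligned window covering any remainder; shorter runs are
    centred and extended to the window size within region bounds.
    ``sequences`` maps gene_id -> region -> unpadded region sequence
    aligned with the relevance coordinates.
    """
    out: list[RelevantWindow] = []
    for p in profiles:
        gene_masks = masks.get(p.gene_id, {})
        for region in REGULATORY_REGIONS:
            m = gene_masks.get(region)
            if m is None or not m.any():
                continue
            seq = sequences[p.gene_id][region]
            L = len(seq)
            vals = p.values[region]
            runs = _runs(m)
            for start, end in runs:
                for ws in _tile(start, end, window, L):
                    sub = seq[ws : ws + window]
                    if len(sub) < window or "N" in sub:
                        continue
                    out.append(
                        RelevantWindow(
                            p.gene_id, region, ws, sub,
                            float(vals[ws : ws + window].mean()),
                        )
                    )
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def _tile(start: int, end: int, window: int, L: int) -> list[int]:
    length = end - start
    if length < window:
        centre = (start + end) // 2
        s = max(0, min(centre - window // 2, L - window))
        return [s] if L >= window else []
    starts = list(range(start, end - window + 1, window))
    if start + ((length // window) * window) < end and (end - window) not in starts:
        starts.append(end - window)  # right-aligned remainder window
    return starts


# ---------------------------------------------------------------------------
# greedy identity clustering


def _identity(a: str, b: str, max_shift: int = 2) -> float:
    """Best ungapped identity (matches / overlap length) over shifts
    within +/- ``max_shift``, requiring overlap >= len - max_shift."""
    best = 0.0
    n = len(a)
    for shift in range(-max_shift, max_shift + 1):
        lo = max(0, shift)
        hi = min(n, n + shift)
        if hi - lo < n - max_shift:
            continue
        matches = sum(1 for i in range(lo, hi) if a[i] == b[i - shift])
        best = max(best, matches / (hi - lo))
    return best


def _best_shift(a: str, b: str, max_shift: int = 2) -> tuple[float, int]:
    best, arg = -1.0, 0
    n = len(a)
    for shift in range(-max_shift, max_shift + 1):
        lo = max(0, shift)
        hi = min(n, n + shift)
        if hi - lo < n - max_shift:
            continue
        ident = sum(1 for i in range(lo, hi) if a[i] == b[i - shift]) / (hi - lo)
        if ident > best:
            best, arg = ident, shift
    return best, arg


def identity_cluster(
    windows: list[RelevantWindow],
    identity_cutoff: float = 0.8,
    min_cluster: int = 5,
    max_shift: int = 2,
) -> list[tuple[RelevantWindow, list[RelevantWindow], list[int]]]:
    """Greedy incremental clustering.

    Windows are sorted by mean relevance (descending, sequence as
    tie-break) and each joins the first cluster whose representative
    matches at >= ``identity_cutoff``; otherwise it founds a cluster.
    Clusters below ``min_cluster`` members are discarded. Returns
    (representative, members, shifts) triples; shifts place each member
    in the representative's coordinates.
    """
    if not windows:
        return []
    lengths = {len(w.sequence) for w in windows}
    if len(lengths) > 1:
        raise ValueError("windows must have equal length")
    word = {0.8: 4, 0.85: 5, 0.9: 6}.get(identity_cutoff, 4)
    ordered = sorted(windows, key=lambda w: (-w.mean_relevance, w.sequence))
    reps: list[RelevantWindow] = []
    rep_words: list[set[str]] = []
    members: list[list[RelevantWindow]] = []
    shifts: list[list[int]] = []
    for w in ordered:
        words = {w.sequence[i : i + word] for i in range(len(w.sequence) - word + 1)}
        placed = False
        for ci, rep in enumerate(reps):
            if not (words & rep_words[ci]):
                continue  # speed prefilter; cannot reach cutoff without a shared word
            ident, shift = _best_shift(rep.sequence, w.sequence, max_shift)
            if ident >= identity_cutoff:
                members[ci].append(w)
                shifts[ci].append(shift)
                placed = True
                break
        if not placed:
            reps.append(w)
            rep_words.append(words)
            members.append([w])
            shifts.append([0])
    return [
        (reps[i], members[i], shifts[i])
        for i in range(len(reps))
        if len(members[i]) >= min_cluster
    ]


# ---------------------------------------------------------------------------
# PWM construction


def build_pwm(
    representative: RelevantWindow,
    members: list[RelevantWindow],
    shifts: list[int],
    motif_id: str,
    min_cluster: int = 5,
    trim_bits: float = 0.2,
    pseudocount: float = 0.25,
) -> Motif | None:
    """Counts -> probabilities with per-base pseudocount, then trim edge
    columns below ``trim_bits`` of information. Returns None when
    trimming consumes every column."""
    if len(members) < min_cluster:
        raise ValueError(f"cluster below minimum size {min_cluster}")
    width = len(representative.sequence)
    counts = np.zeros((4, width))
    for w, shift in zip(members, shifts):
        for i, ch in enumerate(w.sequence):
            j = i + shift
            if 0 <= j < width and ch in BASES:
                counts[BASES.index(ch), j] += 1
    n = counts.sum(axis=0)
    pwm = (counts + pseudocount) / (n + 4 * pseudocount)
    info = 2.0 + (np.clip(pwm, 1e-12, 1) * np.log2(np.clip(pwm, 1e-12, 1))).sum(axis=0)
    lo, hi = 0, width
    while lo < hi and info[lo] < trim_bits:
        lo += 1
    while hi > lo and info[hi - 1] < trim_bits:
        hi -= 1
    if hi <= lo:
        return None
    region = representative.region
    return Motif(motif_id, region, pwm[:, lo:hi], members, list(shifts))


def cluster_to_motifs(
    windows: list[RelevantWindow],
    identity_cutoff: float = 0.8,
    min_cluster: int = 5,
    trim_bits: float = 0.2,
) -> list[Motif]:
    """identity_cluster + build_pwm, discarding fully trimmed clusters."""
    motifs = []
    for i, (rep, members, shifts) in enumerate(
        identity_cluster(windows, identity_cutoff, min_cluster)
    ):
        m = build_pwm(rep, members, shifts, f"dm_{i:03d}", min_cluster, trim_bits)
        if m is not None:
            motifs.append(m)
    return motifs


# ---------------------------------------------------------------------------
# PWM comparison


def _column_corr_score(a: np.ndarray, b: np.ndarray, min_overlap: int = 4) -> float:
    """Max over ungapped offsets of the mean per-column Pearson r."""
    wa, wb = a.shape[1], b.shape[1]
    if min(wa, wb) < min_overlap:
        raise ValueError("overlap impossible: motif narrower than minimum overlap")
    best = -np.inf
    for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a, hi_a = max(0, offset), min(wa, offset + wb)
        if hi_a - lo_a < min_overlap:
            continue
        cols_a = a[:, lo_a:hi_a]
        cols_b = b[:, lo_a - offset : hi_a - offset]
        ac = cols_a - cols_a.mean(axis=0)
        bc = cols_b - cols_b.mean(axis=0)
        denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
        denom[denom == 0] = 1.0
        best = max(best, float(np.mean((ac * bc).sum(axis=0) / denom)))
    return best


def compare_pwms(
    a: Motif | np.ndarray,
    b: Motif | np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    min_overlap: int = 4,
) -> tuple[float, float]:
    """Similarity score and permutation p-value between two PWMs.

    The null shuffles b's columns; p = (1 + #{perm >= observed}) /
    (1 + n_permutations). Benjamini-Hochberg correction over many
    comparisons is the caller's job. The null is evaluated through a
    precomputed column-correlation matrix, so permutations reduce to
    index gathers and large permutation counts stay cheap.
    """
    pa = a.pwm if isinstance(a, Motif) else np.asarray(a)
    pb = b.pwm if isinstance(b, Motif) else np.asarray(b)
    wa, wb = pa.shape[1], pb.shape[1]
    if min(wa, wb) < min_overlap:
        raise ValueError("overlap impossible: motif narrower than minimum overlap")

    an = pa - pa.mean(axis=0)
    bn = pb - pb.mean(axis=0)
    an /= np.where(np.linalg.norm(an, axis=0) == 0, 1, np.linalg.norm(an, axis=0))
    bn /= np.where(np.linalg.norm(bn, axis=0) == 0, 1, np.linalg.norm(bn, axis=0))
    C = an.T @ bn  # (wa, wb) column-correlation matrix

    offsets = []
    for off in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a, hi_a = max(0, off), min(wa, off + wb)
        if hi_a - lo_a >= min_overlap:
            offsets.append((np.arange(lo_a, hi_a),
                            np.arange(lo_a - off, hi_a - off)))
    # offset selection and the null use the SUMMED column correlation:
    # a mean-based statistic lets a minimal-overlap chance alignment of
    # sharp columns tie a full-length match, degenerating the null
    sums = [float(C[ia, ib].sum()) for ia, ib in offsets]
    best = int(np.argmax(sums))
    obs_sum = sums[best]
    ia, ib = offsets[best]
    score = float(C[ia, ib].mean())

    # shuffle the wider motif: a narrow PWM has too few distinct column
    # orders for the permutation p-value to resolve small tail areas
    rng = np.random.default_rng(seed)
    null = np.full(n_permutations, -np.inf)
    if wa >= wb:
        perms = np.stack([rng.permutation(wa) for _ in range(n_permutations)])
        for ia_o, ib_o in offsets:
            null = np.maximum(null, C[perms[:, ia_o], ib_o[None, :]].sum(axis=1))
    else:
        perms = np.stack([rng.permutation(wb) for _ in range(n_permutations)])
        for ia_o, ib_o in offsets:
            null = np.maximum(null, C[ia_o[None, :], perms[:, ib_o]].sum(axis=1))
    p = (1 + int((null >= obs_sum - 1e-12).sum())) / (1 + n_permutations)
    return score, p


def match_motifs(
    discovered: list[Motif],
    references: list[tuple[str, np.ndarray, str] | tuple[str, np.ndarray]],
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    same_region_only: bool = True,
) -> pd.DataFrame:
    """Reference-vs-discovered PWM comparisons, BH-corrected.

    References are (id, pwm) or (id, pwm, region) tuples; when regions
    are given and ``same_region_only`` is set, a reference is only
    compared with motifs discovered in its own region (regulatory
    motifs are region-specific, and restricting the family keeps the
    multiple-testing burden proportionate)."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for ref in references:
        ref_id, ref_pwm = ref[0], ref[1]
        ref_region = ref[2] if len(ref) > 2 else None
        for m in discovered:
            if (same_region_only and ref_region is not None
                    and m.region != ref_region):
                continue
            score, p = compare_pwms(ref_pwm, m, n_permutations, seed)
            rows.append({"reference": ref_id, "motif_id": m.motif_id,
                         "score": score, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=[], recovered=[])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["recovered"] = df["q"] < alpha
    return df


# ---------------------------------------------------------------------------
# occurrences


def _corr_matrix(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    an = pa - pa.mean(axis=0)
    bn = pb - pb.mean(axis=0)
    an /= np.where(np.linalg.norm(an, axis=0) == 0, 1, np.linalg.norm(an, axis=0))
    bn /= np.where(np.linalg.norm(bn, axis=0) == 0, 1, np.linalg.norm(bn, axis=0))
    return an.T @ bn


def _offset_pairs(wa: int, wb: int, min_overlap: int):
    out = []
    for off in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a, hi_a = max(0, off), min(wa, off + wb)
        if hi_a - lo_a >= min_overlap:
            out.append((np.arange(lo_a, hi_a), np.arange(lo_a - off, hi_a - off)))
    return out


def match_references(
    discovered: list[Motif],
    references: list[tuple[str, np.ndarray, str]],
    alpha: float = 0.05,
    n_permutations: int = 2000,
    seed: int = 0,
    min_overlap: int = 4,
    same_region_only: bool = True,
) -> pd.DataFrame:
    """Is each reference PWM matched by the discovered collection?

    Statistic per reference: the maximum (over same-region discovered
    motifs and ungapped offsets) summed column correlation. The
    permutation null shuffles the reference's columns and recomputes the
    same maximum, so the selection over motifs and offsets is built into
    the null. Benjamini-Hochberg across references."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    rows = []
    for ref_id, ref_pwm, ref_region in references:
        cands = [m for m in discovered
                 if not same_region_only or m.region == ref_region]
        cands = [m for m in cands if m.width >= min_overlap]
        if not cands or ref_pwm.shape[1] < min_overlap:
            rows.append({"reference": ref_id, "best_motif": None,
                         "score": np.nan, "p": 1.0})
            continue
        wa = ref_pwm.shape[1]
        perms = np.stack([rng.permutation(wa) for _ in range(n_permutations)])
        obs_best, obs_motif, obs_score = -np.inf, None, np.nan
        null = np.full(n_permutations, -np.inf)
        for m in cands:
            C = _corr_matrix(ref_pwm, m.pwm)
            for ia, ib in _offset_pairs(wa, m.width, min_overlap):
                s = float(C[ia, ib].sum())
                if s > obs_best:
                    obs_best, obs_motif = s, m.motif_id
                    obs_score = float(C[ia, ib].mean())
                null = np.maximum(null, C[perms[:, ia], ib[None, :]].sum(axis=1))
        p = (1 + int((null >= obs_best - 1e-12).sum())) / (1 + n_permutations)
        rows.append({"reference": ref_id, "best_motif": obs_motif,
                     "score": obs_score, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["recovered"] = df["q"] < alpha
    return df


def occurrence_matrix(
    motifs: list[Motif], gene_ids: list[str]
) -> pd.DataFrame:
    """Boolean genes x motifs matrix from member-window membership."""
    mat = pd.DataFrame(False, index=gene_ids,
                       columns=[m.motif_id for m in motifs])
    for m in motifs:
        for w in m.members:
            if w.gene_id in mat.index:
                mat.at[w.gene_id, m.motif_id] = True
    return mat


def occurrence_regions(motifs: list[Motif]) -> dict[str, set[str]]:
    """Regions of origin of each motif's member windows."""
    return {m.motif_id: {w.region for w in m.members} for m in motifs}


def scan_occurrence_matrix(
    motifs: list[Motif],
    sequences: dict[str, dict[str, str]],
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Alternative occurrence definition: PWM scan of each gene's own
    region sequences (sensitivity analysis mode)."""
    from .synth import plant_threshold, scan_pwm

    gene_ids = list(sequences)
    mat = pd.DataFrame(False, index=gene_ids,
                       columns=[m.motif_id for m in motifs])
    for m in motifs:
        thr = plant_threshold(m.pwm, score_fraction)
        for g in gene_ids:
            seq = sequences[g].get(m.region, "")
            if seq and scan_pwm(m.pwm, seq, thr):
                mat.at[g, m.motif_id] = True
    return mat


# ---------------------------------------------------------------------------
# minimal MEME text format


def write_meme(
    motifs: list[tuple[str, np.ndarray, int]] | list[Motif],
    path: str | Path,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: +", "",
             "Background letter frequencies",
             "A {:.5f} C {:.5f} G {:.5f} T {:.5f}".format(*background), ""]
    for m in motifs:
        if isinstance(m, Motif):
            name, pwm, nsites = m.motif_id, m.pwm, len(m.members)
        else:
            name, pwm, nsites = m
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.shape[1]} "
            f"nsites= {nsites} E= 0"
        )
        for col in pwm.T:
            lines.append(" ".join(f"{v:.6f}" for v in col))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Parse a minimal MEME motif file into (name, 4 x w matrix) pairs."""
    out = []
    name, rows = None, []
    for line in Path(path).read_text().splitlines() + ["MOTIF _end"]:
        line = line.strip()
        if line.startswith("MOTIF"):
            if name is not None and rows:
                out.append((name, np.array(rows).T))
            name, rows = line.split()[1], []
        elif name is not None and line and line[0].isdigit() or (
            name is not None and line.startswith("0")
        ):
            try:
                rows.append([float(x) for x in line.split()])
            except ValueError:
                pass
    return out
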