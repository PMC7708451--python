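"""Sequence featurization for expression modelling.

Genes are represented by their five-region regulatory structure
(promoter, 5'UTR, CDS, 3'UTR, terminator). The sequence branch of the
model consumes one-hot encoded regulatory regions (the CDS enters only
through numeric summaries); the numeric branch consumes 64 codon
probabilities plus 8 mRNA-stability covariates.

All sequences are handled 5'->3' on the coding strand. Regions upstream
of the CDS (promoter, 5'UTR) are anchored at their 3' end, regions
downstream (3'UTR, terminator) at their 5' end, so zero-padding always
sits at the end distal to the CDS.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: the 64 codons in lexicographic order (AAA ... TTT)
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS = ("TAA", "TAG", "TGA")

#: regulatory regions fed to the sequence branch, in genomic order
REGULATORY_REGIONS = ("promoter", "utr5", "utr3", "terminator")

#: regions whose CDS-proximal edge is their 3' end (pad/truncate on the left)
_UPSTREAM = frozenset({"promoter", "utr5"})


@dataclass
class RegionLengths:
    """Configured one-hot lengths (bp) for the four regulatory regions.

    The full-model default splits the 2150 bp of regulatory sequence as
    1000/300/350/500; the constricted preset uses the printed
    400/100/250/250 split; synthetic cohorts default to a scaled-down
    200/50/50/100 layout.
    """

    promoter: int = 1000
    utr5: int = 300
    utr3: int = 350
    terminator: int = 500

    def as_dict(self) -> dict[str, int]:
        return {r: getattr(self, r) for r in REGULATORY_REGIONS}

    @property
    def total(self) -> int:
        return sum(self.as_dict().values())

    @classmethod
    def constricted(cls) -> "RegionLengths":
        return cls(promoter=400, utr5=100, utr3=250, terminator=250)

    @classmethod
    def scaled(cls) -> "RegionLengths":
        return cls(promoter=200, utr5=50, utr3=50, terminator=100)

    def offsets(self) -> dict[str, tuple[int, int]]:
        """Half-open [start, end) column spans of each region in the
        concatenated one-hot tensor."""
        out, pos = {}, 0
        for r in REGULATORY_REGIONS:
            length = getattr(self, r)
            out[r] = (pos, pos + length)
            pos += length
        return out


@dataclass
class FeatureBundle:
    """Model inputs for one gene."""

    gene_id: str
    onehot_regions: dict[str, np.ndarray]  # region -> 4 x L binary
    codon_probs: np.ndarray  # (64,), sums to 1
    stability: np.ndarray  # (8,)
    flags: dict = field(default_factory=dict)

    @property
    def numeric(self) -> np.ndarray:
        """The 72 numeric features (codon probabilities + stability)."""
        return np.concatenate([self.codon_probs, self.stability])

    def concat_onehot(self) -> np.ndarray:
        """4 x total one-hot of the regulatory regions in genomic order."""
        return np.concatenate(
            [self.onehot_regions[r] for r in REGULATORY_REGIONS], axis=1
        )


def _validate(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid character {ch!r} at offset {i}")


def one_hot(seq: str, target_len: int, region: str = "utr3") -> np.ndarray:
    """One-hot encode ``seq`` into a 4 x ``target_len`` matrix.

    Rows are A, C, G, T; ``N`` maps to an all-zero column, as does
    padding. Padding (and truncation) keep the CDS-proximal side of the
    region: upstream regions are right-aligned, downstream regions
    left-aligned.
    """
    seq = seq.upper()
    _validate(seq)
    upstream = region in _UPSTREAM
    if len(seq) > target_len:
        seq = seq[-target_len:] if upstream else seq[:target_len]
    mat = np.zeros((4, target_len), dtype=np.float32)
    offset = target_len - len(seq) if upstream else 0
    for j, ch in enumerate(seq):
        if ch != "N":
            mat[BASE_INDEX[ch], offset + j] = 1.0
    return mat


def decode_onehot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot` on unpadded A/C/G/T input."""
    out = []
    for col in mat.T:
        if col.sum() == 0:
            out.append("N")
        else:
            out.append(BASES[int(np.argmax(col))])
    return "".join(out)


def codon_probs(cds: str) -> np.ndarray:
    """64-vector of codon probabilities in lexicographic codon order.

    Codons containing ``N`` are skipped from the count.
    """
    cds = cds.upper()
    _validate(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    counts = np.zeros(64, dtype=np.float64)
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" not in codon:
            counts[CODON_INDEX[codon]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable codons in CDS")
    return counts / total


def _gc(seq: str) -> tuple[float, bool]:
    seq = seq.upper()
    n = sum(1 for c in seq if c != "N")
    if n == 0:
        return 0.0, True
    return sum(1 for c in seq if c in "GC") / n, False


def stability_vars(utr5: str, cds: str, utr3: str) -> tuple[np.ndarray, dict]:
    """8 mRNA-stability covariates.

    Order: len(5'UTR), len(ORF), len(3'UTR) in bp; GC of 5'UTR and
    3'UTR; GC at codon positions 1, 2, 3 of the ORF. Empty regions get
    GC = 0 with a flag.
    """
    _validate(utr5.upper())
    codon_probs(cds)  # validates the CDS
    gc5, f5 = _gc(utr5)
    gc3, f3 = _gc(utr3)
    pos = [_gc(cds[i::3])[0] for i in range(3)]
    vec = np.array(
        [len(utr5), len(cds), len(utr3), gc5, gc3, *pos], dtype=np.float64
    )
    return vec, {"empty_utr5": f5, "empty_utr3": f3}


def bundle_features(
    gene_id: str,
    regions: dict[str, str],
    lengths: RegionLengths,
) -> FeatureBundle:
    """Build the full :class:`FeatureBundle` for one gene.

    ``regions`` must provide promoter, utr5, cds, utr3, terminator.
    """
    onehots = {
        r: one_hot(regions[r], getattr(lengths, r), region=r)
        for r in REGULATORY_REGIONS
    }
    probs = codon_probs(regions["cds"])
    stab, flags = stability_vars(regions["utr5"], regions["cds"], regions["utr3"])
    return FeatureBundle(gene_id, onehots, probs, stab, flags)


def kmer_features(
    region_seqs: dict[str, list[str]],
    k_range: tuple[int, int] = (4, 6),
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Overlapping k-mer counts per region, concatenated across regions.

    ``region_seqs`` maps region label -> one sequence per gene. Columns
    are named ``<region>:<kmer>``; only k-mers observed in the cohort
    get a column (the alphabet bound 4^4+4^5+4^6 = 5376 per region is
    the worst case).
    """
    kmin, kmax = k_range
    if kmin < 1:
        raise ValueError("k must be >= 1")
    frames = []
    for region, seqs in region_seqs.items():
        rows = []
        for seq in seqs:
            seq = seq.upper()
            counts: dict[str, int] = {}
            for k in range(kmin, kmax + 1):
                for i in range(len(seq) - k + 1):
                    kmer = seq[i : i + k]
                    if "N" not in kmer:
                        counts[kmer] = counts.get(kmer, 0) + 1
            rows.append(counts)
        df = pd.DataFrame(rows).fillna(0.0)
        df.columns = [f"{region}:{c}" for c in df.columns]
        frames.append(df)
    out = pd.concat(frames, axis=1)
    if gene_ids is not None:
        out.index = gene_ids
    return out
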