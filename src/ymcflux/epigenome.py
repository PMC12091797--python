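"""Promoter-window enrichment of sequencing signal and time-grid alignment.

Promoters are +/- half_width bp around the strand-aware transcription start
site (gene start on +, gene end on -), in 0-based half-open coordinates,
clipped at chromosome boundaries.  Enrichment is length-normalized mean
coverage over the window: sum(value x overlap) / window width.  Assay time
series sampled on different grids are aligned by averaging designated
column sets (e.g. RNA t10+t11, ChIP t13+t14 -> 15 matched points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "SignalTrack",
    "EnrichmentMatrix",
    "promoter_window",
    "promoter_enrichment",
    "align_timepoints",
    "read_bed6",
    "read_gff3",
    "read_bedgraph",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: id, chromosome, strand and span (0-based half-open)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: invalid span")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site."""
        return self.start if self.strand == "+" else self.end


@dataclass
class SignalTrack:
    """Per-chromosome sorted, non-overlapping (start, end, value) intervals."""

    intervals: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (s, e, v) in self.intervals.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(e <= s):
                raise ValueError(f"{chrom}: empty or inverted interval")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: overlapping intervals")
            if np.any(v < 0):
                raise ValueError(f"{chrom}: negative signal values")
            clean[chrom] = (s, e, v)
        self.intervals = clean

    @property
    def chromosomes(self) -> List[str]:
        return list(self.intervals)

    def total_signal(self) -> float:
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.intervals.values())
        )


@dataclass
class EnrichmentMatrix:
    """Genes x timepoints enrichment (or expression) values for one assay."""

    values: pd.DataFrame
    assay: str  # RNA | H3K9Ac | H3K4me3 | ATAC

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in enrichment matrix")
        if self.values.isna().any().any():
            raise ValueError("enrichment matrix contains missing cells")


def promoter_window(
    gene: GeneAnnotation,
    half_width: int = 500,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> Tuple[int, int]:
    """Half-open promoter window [TSS - half_width, TSS + half_width),
    clipped at chromosome boundaries."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    start = gene.tss - half_width
    end = gene.tss + half_width
    start = max(0, start)
    if chrom_lengths is not None:
        if gene.chromosome not in chrom_lengths:
            raise KeyError(f"unknown chromosome {gene.chromosome!r}")
        end = min(end, chrom_lengths[gene.chromosome])
    return start, end


def promoter_enrichment(
    track: SignalTrack,
    genes: Sequence[GeneAnnotation],
    half_width: int = 500,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    scale_per_million: bool = False,
) -> pd.Series:
    """Length-normalized signal over each gene's promoter window.

    Per gene: sum(value x overlap length) / window width.  Genes on
    chromosomes absent from the track score 0 with a warning.  With
    ``scale_per_million`` the track is depth-normalized to 1e6 total signal
    first.
    """
    if not genes:
        raise ValueError("no genes supplied")
    track_chroms = set(track.chromosomes)
    gene_chroms = {g.chromosome for g in genes}
    if track_chroms and not (gene_chroms & track_chroms):
        raise ValueError(
            f"no chromosome shared between annotation ({sorted(gene_chroms)}) "
            f"and signal track ({sorted(track_chroms)}); naming scheme mismatch?"
        )
    scale = 1.0
    if scale_per_million:
        total = track.total_signal()
        if total > 0:
            scale = 1e6 / total

    out = {}
    missing: List[str] = []
    for g in genes:
        w_start, w_end = promoter_window(g, half_width, chrom_lengths)
        width = w_end - w_start
        if g.chromosome not in track.intervals:
            missing.append(g.chromosome)
            out[g.gene_id] = 0.0
            continue
        s, e, v = track.intervals[g.chromosome]
        lo = np.searchsorted(e, w_start, side="right")
        hi = np.searchsorted(s, w_end, side="left")
        overlap = np.minimum(e[lo:hi], w_end) - np.maximum(s[lo:hi], w_start)
        out[g.gene_id] = float((overlap * v[lo:hi]).sum()) * scale / width
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) on chromosomes absent from the signal "
            f"track ({sorted(set(missing))}); scored 0",
            stacklevel=2,
        )
    return pd.Series(out, name="enrichment")


def align_timepoints(
    matrix: EnrichmentMatrix,
    merge_rules: Sequence[Tuple[str, Sequence[str]]],
) -> EnrichmentMatrix:
    """Average designated column sets onto a common time grid.

    Each rule ``(assay, labels)`` applying to this matrix's assay replaces
    its label set by a single column holding the arithmetic mean, placed at
    the position of the first merged label.
    """
    df = matrix.values
    for assay, labels in merge_rules:
        if assay != matrix.assay:
            continue
        labels = list(labels)
        missing = [l for l in labels if l not in df.columns]
        if missing:
            raise KeyError(
                f"merge rule for assay {assay!r} references missing column(s) {missing}"
            )
        merged = df[labels].mean(axis=1)
        first = df.columns.get_loc(labels[0])
        keep = [c for c in df.columns if c not in labels]
        new_label = "+".join(labels)
        df = df[keep].copy()
        df.insert(min(first, df.shape[1]), new_label, merged)
    return replace(matrix, values=df)


# ---------------------------------------------------------------------------
# Readers (BED6 / GFF3 annotation, bedGraph / bigWig signal)
# ---------------------------------------------------------------------------

def read_bed6(path) -> List[GeneAnnotation]:
    """BED6 annotation (0-based half-open, native coordinates)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        GeneAnnotation(r.name, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def read_gff3(path, feature: str = "gene", id_attr: str = "ID") -> List[GeneAnnotation]:
    """GFF3 annotation; 1-based closed coordinates converted to 0-based
    half-open on read."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get(id_attr, f"{f[0]}:{f[3]}-{f[4]}")
            genes.append(
                GeneAnnotation(gid, f[0], int(f[3]) - 1, int(f[4]), f[6])
            )
    if not genes:
        raise ValueError(f"no {feature!r} features found in {path}")
    return genes


def read_bedgraph(path) -> SignalTrack:
    """bedGraph coverage (chrom, start, end, value; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    intervals = {
        chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
        for chrom, g in df.groupby("chrom", sort=False)
    }
    return SignalTrack(intervals)


def read_bigwig(path) -> SignalTrack:
    """bigWig coverage, if the optional pyBigWig reader is available."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional reader
        raise ImportError("reading bigWig requires pyBigWig") from exc
    bw = pyBigWig.open(str(path))
    intervals = {}
    for chrom in bw.chroms():
        ivals = bw.intervals(chrom) or []
        if ivals:
            s, e, v = map(np.asarray, zip(*ivals))
            intervals[chrom] = (s, e, v)
    bw.close()
    return SignalTrack(intervals)
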